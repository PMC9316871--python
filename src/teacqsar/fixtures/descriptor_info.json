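{
  "C-018": {
    "definition": "=CHX",
    "family": "Atom-centred fragments",
    "models": [1, 2, 3, 4, 5, 6, 7, 8]
  },
  "H7s": {
    "definition": "H autocorrelation of lag 7/weighted by I-state",
    "family": "GETAWAY descriptors",
    "models": [2, 6, 7, 8]
  },
  "CATS2D_06_AL": {
    "definition": "CATS2D Acceptor-Lipophilic at lag 06",
    "family": "CATS 2D",
    "models": [3, 4, 5]
  },
  "Mor24e": {
    "definition": "signal 24/weighted by Sanderson electronegativity",
    "family": "3D-MoRSE descriptors",
    "models": [3]
  },
  "Mor16e": {
    "definition": "signal 16/weighted by Sanderson electronegativity",
    "family": "3D-MoRSE descriptors",
    "models": [4, 5, 6]
  },
  "RDF145p": {
    "definition": "Radial Distribution Function—145/weighted by polarizability",
    "family": "RDF descriptors",
    "models": [4, 5, 6, 7, 8]
  },
  "RCI": {
    "definition": "ring complexity index",
    "family": "Ring descriptors",
    "models": [5, 6, 7, 8]
  },
  "CATS2D_04_AL": {
    "definition": "CATS2D Acceptor-Lipophilic at lag 04",
    "family": "CATS 2D",
    "models": [6, 7, 8]
  },
  "Mor16u": {
    "definition": "signal 16/unweighted",
    "family": "3D-MoRSE descriptors",
    "models": [7, 8]
  },
  "F03[N-F]": {
    "definition": "Frequency of N—F at topological distance 3",
    "family": "2D Atom Pairs",
    "models": [7]
  },
  "nR=Ct": {
    "definition": "number of aliphatic tertiary C(sp2)",
    "family": "Functional group counts",
    "models": [8]
  },
  "F06[N-S]": {
    "definition": "Frequency of N—S at topological distance 6",
    "family": "2D Atom Pairs",
    "models": [8],
    "note": "The source metadata names this variable F06[N-S] while the printed eight-variable equation spells it F06[N-F]; both spellings are kept and refer to the same model term."
  },
  "F06[N-F]": {
    "definition": "Frequency of N—S at topological distance 6",
    "family": "2D Atom Pairs",
    "models": [8],
    "note": "Spelling used in the printed eight-variable equation; the descriptor metadata table lists it as F06[N-S]. Both spellings are kept and refer to the same model term."
  }
}
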