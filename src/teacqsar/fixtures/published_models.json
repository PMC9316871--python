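{
  "1": {
    "terms": [["C-018", 0.1739, 0.0687]],
    "intercept": [0.0500, 0.0156]
  },
  "2": {
    "terms": [["C-018", 0.1760, 0.0595], ["H7s", 0.1487, 0.0673]],
    "intercept": [0.0287, 0.0166]
  },
  "3": {
    "terms": [["C-018", 0.1835, 0.0529], ["CATS2D_06_AL", 0.1464, 0.0580],
              ["Mor24e", -0.1050, 0.0487]],
    "intercept": [0.0458, 0.0157]
  },
  "4": {
    "terms": [["Mor16e", -0.0851, 0.0533], ["RDF145p", -0.1511, 0.0964],
              ["C-018", 0.1489, 0.0526], ["CATS2D_06_AL", 0.1991, 0.0694]],
    "intercept": [0.0396, 0.0156]
  },
  "5": {
    "terms": [["RCI", -0.1657, 0.0819], ["RDF145p", -0.1458, 0.0848],
              ["Mor16e", -0.0847, 0.0469], ["C-018", 0.1484, 0.0463],
              ["CATS2D_06_AL", 0.2113, 0.0613]],
    "intercept": [0.1292, 0.0463]
  },
  "6": {
    "terms": [["RCI", -0.1686, 0.0768], ["RDF145p", -0.1695, 0.0811],
              ["Mor16e", -0.0801, 0.0456], ["H7s", 0.1388, 0.0788],
              ["C-018", 0.1579, 0.0435], ["CATS2D_04_AL", 0.1061, 0.0712]],
    "intercept": [0.1175, 0.0439]
  },
  "7": {
    "terms": [["RCI", -0.1700, 0.0728], ["RDF145p", -0.1717, 0.0764],
              ["Mor16u", -0.0965, 0.0481], ["H7s", 0.1412, 0.0745],
              ["C-018", 0.2087, 0.0625], ["CATS2D_04_AL", 0.1086, 0.0682],
              ["F03[N-F]", -0.1046, 0.0952]],
    "intercept": [0.1194, 0.0416]
  },
  "8": {
    "terms": [["RCI", -0.1880, 0.0673], ["RDF145p", -0.1821, 0.0703],
              ["Mor16u", -0.0861, 0.0442], ["H7s", 0.0811, 0.0753],
              ["nR=Ct", 0.0606, 0.0386], ["C-018", 0.1483, 0.0383],
              ["CATS2D_04_AL", 0.1236, 0.0622], ["F06[N-F]", 0.0764, 0.0529]],
    "intercept": [0.1241, 0.0384]
  }
}
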