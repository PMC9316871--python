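name,cas,molecular_formula,pharmacologic_class,atc,teac_mm
Acetazolamide,59-66-5,C4H6N4O3S2,Mitotic,S,0.009
Amoxicillin,26787-78-0,C16H19N3O5S,Antibiotic,J,0.085
Antipyrine (Phenazone),60-80-0,C11H12N2O,Analgetic,N,0.013
Atenolol,29122-68-7,C14H22N2O3,Beta blocker,C,0.037
Atorvastatin,134523-00-5,C33H35FN2O5,Hypolipemic,C,0.059
Atropine sulphate,5908-99-6,C34H50N2O11S,Spasmolytic,"A, S",0.010
Azathioprine,446-86-6,C9H7N7O2S,Immunosuppressive,L,0.001
Azithromycin,83905-01-5,C38H72N2O12,Antibiotic,J,0.037
Balsalazide,80573-04-2,C17H15N3O6,Aminosalicylate,A,0.008
Barbital,57-44-3,C8H12N2O3,Sedative,N,0.001
Benzocaine (4-aminobenzoate),94-09-7,C9H11NO2,Anaesthetic,N,0.004
Bisoprolol,66722-44-9,C18H31NO4,Beta blocker,C,0.008
Caffeine,58-08-2,C8H10N4O2,Analeptic,N,0.013
Carvedilol,72956-09-3,C24H26N2O4,Beta blocker,C,0.028
Cefalexin,15686-71-2,C16H17N3O4S,Antibiotic,J,0.170
Cefradine,38821-53-3,C16H19N3O4S,Antibiotic,J,0.152
Chloramphenicol,56-75-7,C11H12Cl2N2O5,Antibiotic,J,0.041
Cimetidine,51481-61-9,C10H16N6S,H2-receptor antagonist,A,0.018
Ciprofloxacin,85721-33-1,C17H18FN3O3,Antibiotic,J,0.155
Clarithromycin,81103-11-9,C38H69NO13,Antibiotic,J,0.044
Codeine phosphate,41444-62-6,C18H24NO7P,Analgetic,N,0.017
Diazepam,439-14-5,C16H13ClN2O,Sedative,N,0.00001
Digoxin,20830-75-5,C41H64O14,Cardiotonic,C,0.00001
Docetaxel,148408-66-6,C43H59NO17,Cytostatic,L,0.001
Doxycycline,564-25-0,C22H24N2O8,Antibiotic,J,0.302
Dopamine,62-31-7,C8H12ClNO2,Dopamine,C,0.274
Ephedrine,299-42-3,C10H15NO,Adrenergic,C,0.002
Erythromycin,114-07-8,C37H67NO13,Antibiotic,J,0.080
Febuxostat,144060-53-7,C16H16N2O3S,Non-purine xanthine oxidase inhibitor,M,0.00001
Fluvastatin,93957-55-2,C24H25FNNaO4,Hypolipemic,C,0.138
Folic acid,59-30-3,C19H19N7O6,Vitamin,A,0.230
Furosemide,54-31-9,C12H11ClN2O5S,Diuretic,C,0.055
Gemcitabine,122111-03-9,C9H12ClF2N3O4,Cytostatic,L,0.060
Hydrochlorothiazide,58-93-5,C7H8ClN3O4S2,Diuretic,C,0.018
Ibuprofen,15687-27-1,C13H18O2,NSAID,M,0.005
Ketoprofen,22071-15-4,C16H14O3,NSAID,M,0.006
L-Ascorbic acid sodium salt,134-03-2,C6H8O6,Vitamin,A,0.267
6-Mercaptopurine,50-44-2,C5H4N4S,Immunosuppressive,L,0.292
Mesalazine,89-57-6,C7H7NO3,Aminosalicylate,A,0.296
Metronidazole,443-48-1,C6H9N3O3,Antibiotic,J,0.015
Nebivolol,99200-09-6,C22H25F2NO4,Beta blocker,C,0.017
Nifedipine,21829-25-4,C17H18N2O6,Calcium channel blocker,C,0.029
Nicotinamide,98-92-0,C6H6N2O,Vitamin,A,0.048
O-Acetylsalicylic acid,50-78-2,C9H8O4,NSAID,"B, N",0.012
Oxazepam,604-75-1,C15H11N2O2Cl,Sedative,M,0.007
Oxytetracycline,79-57-2,C22H24N2O9,Antibiotic,J,0.299
Olsalazine,6054-98-4,C14H8N2Na2O6,Aminosalicylate,A,0.002
Pantoprazole,102625-70-7,C16H14F2N3NaO4S,Proton-pump inhibitor,A,0.030
Calcium pantothenate,443753,C18H32CaN2O10,Vitamin,A,0.002
Papaverine,61-25-6,C20H22ClNO4,Spasmolytic,A,0.012
Paracetamol,103-90-2,C8H9NO2,Analgetic,N,0.236
Phenobarbitone,50-06-6,C12H12N2O3,Sedative,N,0.038
Physostigmine salicylate,57-64-7,C22H27N3O5,Parasympathomimetic,S,0.063
Piperazine,142-63-2,C4H22N2O6,Anthelmintic,P,0.132
Piracetam,7491-74-9,C6H10N2O2,Antidepressant,N,0.025
Pirfenidone,53179-13-8,C12H11NO,"Anti-inflammatory, antifibrotic",L,0.00001
Pravastatin sodium,81131-70-6,C23H35NaO7,Hypolipemic,C,0.097
Procaine,51-05-8,C13H21ClN2O2,Anaesthetic,N,0.024
Propyphenazone,479-92-5,C14H18N2O,Analgetic,N,0.003
Propranolol,525-66-6,C16H21NO2,Beta blocker,C,0.00001
Quetiapine fumarate,111974-72-2,C46H54N6O8S,Antipsychotic,N,0.030
Quinidine,56-54-2,C20H24N2O2,Antiarrhythmic agent,C,0.029
Quinin sulphate,207671-44-1,C40H50N4O8S,Antimalaria,P,0.017
Rifampicin,13292-46-1,C43H58N4O12,Antibiotic,J,0.292
Risperidone,106266-06-2,C23H27FN4O2,Antipsychotic,N,0.010
Ropinirole,91374-20-8,C16H25ClN2O,Anti-Parkinson's drug,N,0.285
Salicylic acid,69-72-7,C7H6O3,"Anti-inflammatory, antibacterial",D,0.024
Sildenafil citrate,171599-83-0,C22H30N6O4S,PDE 5 inhibitor,G,0.003
Simvastatin,79902-63-9,C25H38O5,Hypolipemic,C,0.141
Sulfacetamide sodium,6209-17-2,C8H11N2NaO4S,Antibiotic,J,0.015
Sulfadiazine,68-35-9,C10H10N4O2S,Antibiotic,J,0.015
Sulfamethoxazole,723-46-6,C10H11N3O3S,Antibiotic,J,0.077
Sulfasalazine,599-79-1,C18H14N4O5S,Aminosalicylate,A,0.076
Sulfathiazole,72-14-0,C9H9N3O2S2,Antibiotic,J,0.035
Sulphamic acid,5329-14-6,NH2SO3H,Antibiotic,J,0.104
Sulphanilamide,63-74-1,C6H8N2O2S,Antibiotic,J,0.023
6-Thioguanine,154-42-7,C5H5N5S,Immunosuppressive,L,0.288
Theobromine,83-67-0,C7H8N4O2,Antiasthmatic,R,0.011
Theophylline,58-55-9,C7H8N4O2,Antiasthmatic,R,0.004
Thiamine,67-03-8,C12H18Cl2N4OS,Vitamin,A,0.115
Warfarin,81-81-2,C19H16O4,Anticoagulant,"B, N",0.077
Zopiclone,43200-80-2,C17H17ClN6O3,Sedative,N,0.018
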