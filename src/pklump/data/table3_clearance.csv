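compound,pbpk,lumped,compartment
Alfentanil,0.555,0.555,0.209
Amlodipine,0.408,0.408,0.255
Artemether,13.333,13.333,16.436
Caffeine,0.134,0.134,0.094
Clozapine,0.401,0.401,0.313
Cyclosporine A,0.420,0.420,0.459
Digoxin,0.136,0.136,0.222
Fluoxetine,0.351,0.351,0.208
Metoprolol,3.250,3.250,2.821
Midazolam,0.540,0.540,0.896
Nevirapine,0.022,0.022,0.015
Ofloxacin,0.160,0.160,0.132
Paracetamol,0.270,0.270,0.215
Pioglitazone,0.068,0.068,0.035
Rifampicin,0.142,0.142,0.163
S-Warfarin,0.003,0.003,0.002
Telmisartan,0.800,0.800,0.980
Theophylline,0.045,0.045,0.054
Thiopental,0.189,0.189,0.114
Voriconazole,0.106,0.106,0.088
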