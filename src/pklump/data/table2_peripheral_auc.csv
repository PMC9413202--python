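compound,pbpk,lumped,compartment
Alfentanil,1.772,0.994,
Amlodipine,9.979,11.920,
Artemether,27.217,19.090,
Caffeine,0.901,0.638,
Clozapine,142.308,134.485,
Cyclosporine A,17.777,12.601,
Digoxin,0.077,0.057,0.030
Fluoxetine,20.178,13.400,
Metoprolol,5.476,2.644,
Midazolam,8.860,5.189,0.100
Nevirapine,315.957,208.837,202.734
Ofloxacin,34.537,29.840,55.224
Paracetamol,18.966,19.120,68.139
Pioglitazone,0.348,0.312,3.002
Rifampicin,139.803,163.653,
S-Warfarin,6.697,5.905,
Telmisartan,164.733,123.565,0.694
Theophylline,291.616,279.114,
Thiopental,11940.270,7818.454,2773.715
Voriconazole,260.225,273.008,63.054
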