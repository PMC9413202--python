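compound,pbpk,lumped,compartment
Alfentanil,0.348,0.351,0.585
Amlodipine,7.598,0.505,0.496
Artemether,2.608,2.877,0.173
Caffeine,1.349,1.482,0.953
Clozapine,130.033,12.823,14.172
Cyclosporine A,21.776,12.285,18.363
Digoxin,0.056,0.060,0.030
Fluoxetine,2.736,1.926,4.511
Metoprolol,0.987,1.074,0.630
Midazolam,1.005,0.977,0.098
Nevirapine,146.303,164.225,203.575
Ofloxacin,50.220,53.246,55.173
Paracetamol,28.650,33.827,67.964
Pioglitazone,2.368,3.201,5.529
Rifampicin,153.468,79.553,65.084
S-Warfarin,28.075,35.292,30.006
Telmisartan,760.097,986.822,0.707
Theophylline,468.329,554.051,65.239
Thiopental,1688.083,1819.869,3015.313
Voriconazole,43.587,46.360,63.400
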