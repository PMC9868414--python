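drug_class,drug_name,N,PRR,chi2
Diuretics,Furosemide,25,21.52,361.13
Diuretics,Torasemide,3,17.98,31.71
Diuretics,Spironolactone,7,15.02,73.06
α blockers,Doxazosin,3,17.63,31.00
Calcium channel blockers,Amlodipine,6,3.26,6.85
Calcium channel blockers,Diltiazem,9,24.24,163.22
Angiotensin converting enzyme inhibitors,Enalapril,8,27.60,166.14
Vasodilators,Nitroglycerin,4,18.00,46.53
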