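drug_class,drug_name,N,PRR,chi2
Diuretics,Furosemide,6,9.23,32.00
Diuretics,Hydrochlorothiazide,3,4.51,4.74
β blockers,Metoprolol,4,5.68,10.20
Calcium channel blockers,Amlodipine,5,5.83,13.95
Angiotensin II receptor blockers,Olmesartan,3,18.06,30.88
Compound preparations,"Benicar HCT (olmesartan and hydrochlorothiazide)",3,96.90,185.71
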