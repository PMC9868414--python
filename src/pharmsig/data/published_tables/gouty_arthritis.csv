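drug_class,drug_name,N,PRR,chi2
Diuretics,Furosemide,48,8.72,285.87
Diuretics,Torasemide,10,14.57,110.64
Diuretics,Hydrochlorothiazide,42,7.81,219.80
Diuretics,Indapamide,7,18.04,94.77
Diuretics,Metolazone,9,44.28,331.82
Diuretics,Spironolactone,30,15.78,373.77
Diuretics,Triamterene,7,12.38,61.27
Diuretics,Eplerenone,4,20.41,55.21
α blockers,Terazosin,4,13.92,35.57
β blockers,Bisoprolol,6,2.52,4.02
β blockers,Metoprolol,30,5.02,86.21
β blockers,Nebivolol,8,13.73,80.61
α and β blockers,Carvedilol,27,12.46,256.57
Calcium channel blockers,Amlodipine,27,3.61,45.35
Calcium channel blockers,Diltiazem,15,9.38,100.48
Angiotensin converting enzyme inhibitors,Benazepril,10,15.34,117.41
Angiotensin converting enzyme inhibitors,Captopril,8,37.27,242.80
Angiotensin converting enzyme inhibitors,Enalapril,10,7.99,53.15
Angiotensin converting enzyme inhibitors,Lisinopril,35,6.20,135.70
Angiotensin converting enzyme inhibitors,Perindopril,6,8.53,32.24
Angiotensin converting enzyme inhibitors,Ramipril,17,6.65,73.08
Angiotensin II receptor blockers,Candesartan,9,8.33,49.89
Angiotensin II receptor blockers,Losartan,12,3.72,20.67
Angiotensin II receptor blockers,Telmisartan,7,9.55,44.63
Angiotensin II receptor blockers,Valsartan,29,5.34,91.57
Vasodilators,Nitroglycerin,18,19.87,291.61
Compound preparations,"Entresto (sacubitril and valsartan)",10,3.98,18.96
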