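drug_class,drug_name,N,PRR,chi2
Diuretics,Azosemide,5,25.35,93.60
Diuretics,Furosemide,121,5.45,404.53
Diuretics,Torasemide,29,10.85,245.41
Diuretics,Bumetanide,5,3.77,7.57
Diuretics,Hydrochlorothiazide,90,4.13,199.53
Diuretics,Trichlormethiazide,11,64.76,624.32
Diuretics,Indapamide,11,7.25,52.88
Diuretics,Metolazone,4,4.99,9.07
Diuretics,Xipamide,4,36.65,105.11
Diuretics,Spironolactone,54,7.07,266.52
Diuretics,Amiloride,18,43.05,690.64
Diuretics,Triamterene,9,4.07,17.76
Diuretics,Eplerenone,13,17.11,180.04
α blockers,Terazosin,6,5.36,17.09
β blockers,Acebutolol,3,9.20,14.46
β blockers,Atenolol,30,2.86,33.76
β blockers,Bisoprolol,80,8.97,532.79
β blockers,Metoprolol,56,2.33,39.88
β blockers,Nebivolol,15,6.59,65.01
α and β blockers,Carvedilol,32,3.65,57.83
Calcium channel blockers,Amlodipine,213,7.88,1115.10
Calcium channel blockers,Cilnidipine,15,151.62,2078.43
Calcium channel blockers,Azelnidipine,6,59.27,286.95
Calcium channel blockers,Benidipine,8,74.35,505.60
Calcium channel blockers,Lercanidipine,10,9.72,69.35
Calcium channel blockers,Nifedipine,40,10.11,311.74
Calcium channel blockers,Nilvadipine,3,137.76,281.58
Calcium channel blockers,Nitrendipine,4,30.00,84.81
Calcium channel blockers,Diltiazem,15,2.36,10.34
Angiotensin converting enzyme inhibitors,Captopril,4,4.74,8.33
Angiotensin converting enzyme inhibitors,Enalapril,34,7.00,165.54
Angiotensin converting enzyme inhibitors,Imidapril,3,52.00,103.23
Angiotensin converting enzyme inhibitors,Temocapril,3,120.65,246.00
Angiotensin converting enzyme inhibitors,Trandolapril,4,9.28,21.79
Angiotensin II receptor blockers,Azilsartan medoxomil,12,32.56,333.96
Angiotensin II receptor blockers,Candesartan,42,10.08,326.33
Angiotensin II receptor blockers,Irbesartan,36,9.08,245.47
Angiotensin II receptor blockers,Losartan,44,3.52,74.94
Angiotensin II receptor blockers,Olmesartan,50,8.97,336.24
Angiotensin II receptor blockers,Telmisartan,40,14.20,466.55
Angiotensin II receptor blockers,Valsartan,81,3.78,155.08
Renin inhibitors,Aliskiren,9,8.01,48.16
Compound preparations,"Diovan HCT (valsartan and hydrochlorothiazide)",5,3.88,7.97
Compound preparations,"Hyzaar (losartan potassium and hydrochlorothiazide)",4,4.36,7.26
Compound preparations,"Exforge (amlodipine and valsartan)",5,5.17,12.88
Compound preparations,"Exforge HCT (amlodipine, valsartan and hydrochlorothiazide)",5,16.99,59.93
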