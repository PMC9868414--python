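drug_class,drug_name,N,PRR,chi2
Diuretics,Furosemide,611,5.85,2271.93
Diuretics,Torasemide,77,6.05,316.97
Diuretics,Bumetanide,56,8.97,386.44
Diuretics,Hydrochlorothiazide,398,3.85,797.91
Diuretics,Bendroflumethiazide,15,2.46,11.62
Diuretics,Indapamide,39,5.44,136.18
Diuretics,Metolazone,55,14.59,678.68
Diuretics,Chlorthalidone,22,5.00,66.35
Diuretics,Spironolactone,128,3.49,221.37
Diuretics,Triamterene,49,4.69,137.81
Diuretics,Eplerenone,26,7.21,132.63
Antihypertensive drugs with central action,Clonidine,59,2.92,72.20
α blockers,Doxazosin,47,3.61,85.65
α blockers,Terazosin,17,3.21,23.68
β blockers,Acebutolol,6,3.89,10.15
β blockers,Atenolol,167,3.38,271.46
β blockers,Bisoprolol,194,4.50,512.20
β blockers,Metoprolol,446,4.02,955.07
β blockers,Nebivolol,40,3.70,75.91
β blockers,Sotalol,13,2.01,5.59
α and β blockers,Carvedilol,170,4.11,389.50
α and β blockers,Labetalol,14,2.80,14.48
Calcium channel blockers,Amlodipine,504,3.69,923.75
Calcium channel blockers,Felodipine,20,4.23,46.10
Calcium channel blockers,Lercanidipine,22,4.51,56.57
Calcium channel blockers,Nifedipine,57,3.00,73.46
Calcium channel blockers,Verapamil,48,2.77,52.25
Calcium channel blockers,Diltiazem,95,3.17,137.71
Angiotensin converting enzyme inhibitors,Accupril,25,8.70,162.30
Angiotensin converting enzyme inhibitors,Benazepril,46,3.79,91.38
Angiotensin converting enzyme inhibitors,Captopril,10,2.50,7.59
Angiotensin converting enzyme inhibitors,Enalapril,71,3.06,95.58
Angiotensin converting enzyme inhibitors,Fosinopril,16,5.66,56.67
Angiotensin converting enzyme inhibitors,Lisinopril,370,3.46,614.45
Angiotensin converting enzyme inhibitors,Perindopril,36,2.77,38.86
Angiotensin converting enzyme inhibitors,Quinapril,40,5.97,159.73
Angiotensin converting enzyme inhibitors,Ramipril,205,4.32,507.60
Angiotensin converting enzyme inhibitors,Trandolapril,6,2.94,5.87
Angiotensin II receptor blockers,Azilsartan medoxomil,13,7.43,65.96
Angiotensin II receptor blockers,Candesartan,81,4.05,181.64
Angiotensin II receptor blockers,Eprosartan,7,14.19,73.12
Angiotensin II receptor blockers,Irbesartan,58,3.05,77.49
Angiotensin II receptor blockers,Losartan,179,3.02,234.84
Angiotensin II receptor blockers,Olmesartan,90,3.36,145.02
Angiotensin II receptor blockers,Telmisartan,41,3.02,53.30
Angiotensin II receptor blockers,Valsartan,446,4.44,1121.23
Renin inhibitors,Aliskiren,21,3.95,43.19
Vasodilators,Hydralazine,57,6.01,231.37
Vasodilators,Nitroglycerin,71,4.15,165.07
Compound preparations,"Atacand HCT (candesartan and hydrochlorothiazide)",12,13.14,122.64
Compound preparations,"Diovan HCT (valsartan and hydrochlorothiazide)",28,4.60,75.12
Compound preparations,"Hyzaar (losartan potassium and hydrochlorothiazide)",12,2.77,11.82
Compound preparations,"Micardis HCT (telmisartan and hydrochlorothiazide)",7,6.91,29.69
Compound preparations,"Micardis plus (telmisartan and amlodipine)",3,13.32,22.98
Compound preparations,"Tekturna HCT (aliskiren and hydrochlorothiazide)",3,15.93,28.38
Compound preparations,"Azor (amlodipine and olmesartan)",6,4.99,15.37
Compound preparations,"Exforge (amlodipine and valsartan)",11,2.41,7.68
Compound preparations,"Exforge HCT (amlodipine, valsartan and hydrochlorothiazide)",6,4.31,12.10
Compound preparations,"Entresto (sacubitril and valsartan)",211,4.60,576.65
Compound preparations,"Lotrel (amlodipine and benazepril)",23,5.28,75.35
Compound preparations,"Tenoretic 100 (atenolol and chlorthalidone)",6,21.27,96.53
Compound preparations,"Caduet (amlodipine and atorvastatin)",9,4.23,19.06
Compound preparations,"Edarbyclor (azilsartan medoxomil and chlorthalidone)",10,19.75,159.71
Compound preparations,"Bidil (isosorbide dinitrate and hydralazine)",3,21.68,40.32
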