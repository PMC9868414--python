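event,breakdown,stratum,count,pct
hyperuricaemia,total,total,1727,
hyperuricaemia,sex,male,960,55.59%
hyperuricaemia,sex,female,541,31.33%
hyperuricaemia,sex,unknown,226,13.09%
hyperuricaemia,age,0-17,70,4.05%
hyperuricaemia,age,18-40,128,7.41%
hyperuricaemia,age,41-65,626,36.25%
hyperuricaemia,age,>65,485,28.08%
hyperuricaemia,age,unknown,418,24.20%
hyperuricaemia,country,United States,371,21.48%
hyperuricaemia,country,other,1262,73.07%
hyperuricaemia,country,unknown,94,5.44%
gout,total,total,8159,
gout,sex,male,4673,57.27%
gout,sex,female,2873,35.21%
gout,sex,unknown,613,7.51%
gout,age,0-17,8,0.10%
gout,age,18-40,250,3.06%
gout,age,41-65,2311,28.32%
gout,age,>65,2301,28.20%
gout,age,unknown,3289,40.31%
gout,country,United States,5600,68.64%
gout,country,other,2285,28.01%
gout,country,unknown,394,4.83%
gouty arthritis,total,total,446,
gouty arthritis,sex,male,251,56.28%
gouty arthritis,sex,female,158,35.43%
gouty arthritis,sex,unknown,37,8.30%
gouty arthritis,age,0-17,0,0.00%
gouty arthritis,age,18-40,17,3.81%
gouty arthritis,age,41-65,181,40.58%
gouty arthritis,age,>65,135,30.27%
gouty arthritis,age,unknown,113,25.34%
gouty arthritis,country,United States,247,55.38%
gouty arthritis,country,other,156,34.98%
gouty arthritis,country,unknown,43,9.64%
gouty tophus,total,total,109,
gouty tophus,sex,male,61,55.96%
gouty tophus,sex,female,44,40.37%
gouty tophus,sex,unknown,4,3.67%
gouty tophus,age,0-17,6,5.50%
gouty tophus,age,18-40,14,12.84%
gouty tophus,age,41-65,28,25.69%
gouty tophus,age,>65,37,33.94%
gouty tophus,age,unknown,24,22.02%
gouty tophus,country,United States,56,51.38%
gouty tophus,country,other,46,42.20%
gouty tophus,country,unknown,7,6.42%
urate nephropathy,total,total,53,
urate nephropathy,sex,male,19,35.85%
urate nephropathy,sex,female,25,47.17%
urate nephropathy,sex,unknown,9,16.98%
urate nephropathy,age,0-17,1,1.89%
urate nephropathy,age,18-40,3,5.66%
urate nephropathy,age,41-65,24,45.28%
urate nephropathy,age,>65,7,13.21%
urate nephropathy,age,unknown,18,33.96%
urate nephropathy,country,United States,36,67.92%
urate nephropathy,country,other,14,26.42%
urate nephropathy,country,unknown,3,5.66%
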