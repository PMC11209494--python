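element,minimum,median,maximum,mean,skewness,kurtosis,sd,cv_pct,excess_rate_pct
As,5.85,26.72,83.81,26.47,1.04,2.21,13.57,51.27,16
Cd,0.20,0.54,2.48,0.70,1.38,2.69,0.40,57.21,90
Cr,16.33,81.89,219.75,87.07,1.07,1.42,36.61,42.05,8
Cu,13.33,27.42,65.46,29.37,1.34,2.57,9.98,33.99,5
Ni,10.78,27.80,71.95,28.41,1.47,5.19,8.98,31.59,2
Pb,17.85,40.35,95.85,43.94,0.93,0.84,15.63,35.57,9
Zn,73.48,131.97,305.63,133.78,1.13,3.86,35.90,26.83,5
Ca,642.73,1254.23,5966.32,1471.28,2.84,10.84,851.34,57.86,
Mg,2662.55,4444.38,10447.30,4600.78,1.53,3.85,1323.58,28.77,
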