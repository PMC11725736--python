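variable,mean,sd,minimum,maximum
cp,39.97,1.08,38.19,42.50
ee,24.49,1.30,21.02,26.08
ash,5.32,0.18,4.93,5.56
cf,4.53,1.06,2.67,6.20
adf,5.34,1.23,2.88,7.05
ndf,10.42,1.87,6.42,13.94
hemicellulose,5.08,1.31,3.55,7.41
ca,0.33,0.09,0.20,0.55
p,0.55,0.04,0.48,0.61
phytic_p,0.36,0.03,0.29,0.41
ua,0.046,0.030,0.01,0.10
ps,81.74,3.220,75.12,86.24
soluble_protein,32.66,1.40,30.22,35.31
eas,3.31,1.14,0.63,5.52
ge,5826,46.76,5762,5914
de,4558,161.23,4248,4733
me,4457,186.09,4070,4721
men,4344,172.45,3983,4610
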