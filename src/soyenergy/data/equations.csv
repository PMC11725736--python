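response,eq_no,aic,r2,ua_max
DE,1,166.24,0.85,0.046
DE,2,167.51,0.84,0.041
DE,3,167.74,0.84,0.044
DE,4,168.74,0.80,0.042
DE,5,172.56,0.69,0.041
DE,6,179.43,0.42,
ME,1,176.69,0.80,0.055
ME,2,178.59,0.77,0.045
ME,3,178.12,0.74,0.046
ME,4,178.75,0.73,0.044
ME,5,179.02,0.68,0.044
ME,6,182.27,0.54,0.044
ME,7,185.06,0.35,
ME,8,185.96,0.30,
MEn,1,171.21,0.84,0.055
MEn,2,176.11,0.77,0.045
MEn,3,175.22,0.75,0.048
MEn,4,177.69,0.71,0.043
MEn,5,177.10,0.68,0.043
MEn,6,178.62,0.64,0.044
MEn,7,179.86,0.54,0.043
MEn,8,182.47,0.37,
MEn,9,183.37,0.33,
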