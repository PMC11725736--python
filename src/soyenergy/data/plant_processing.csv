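plant_id,n_samples,time_s,temperature_c,pressure_kgf_cm2,final_moisture_pct,protein_solubility_pct,ureatic_activity_dph
1,1,180,115,0.8,11.1,78.8,0.080
2,2,960,108,1.0,9.6,83.1,0.035
3,2,1500,120,2.0,11.5,80.7,0.070
4,6,900,120,0.9,11.4,81.4,0.028
5,3,900,110,0.8,11.6,83.2,0.033
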