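troponin,ligand,up_mean_deg,up_std_deg,delta_mean_deg,p_mean_deg,p_std_deg,up_pct_above_110,delta_pct_above_110,p_pct_above_110,up_fwhm_deg,delta_fwhm_deg,p_fwhm_deg,restored_mean,restored_pct
WT,apo,101.81,9.15,-5.65,96.16,5.73,18,-17,1,17.11,-4.95,12.16,,
G159D,apo,97.06,5.48,1.91,98.97,6.73,1,6,7,12.48,1.16,13.64,False,False
G159D,EGCG,102.25,6.07,-13.25,89.0,18.07,11,-8,3,12.77,1.36,14.13,True,True
G159D,RVL,105.48,9.16,-11.14,94.34,8.72,25,-24,1,14.81,5.58,20.39,True,True
G159D,SilybinA,98.55,10.98,4.88,103.43,10.94,11,13,24,17.39,-3.28,14.11,False,False
G159D,SilybinB,103.61,5.81,-3.09,100.52,7.45,14,-5,9,14.24,0.81,15.05,True,True
G159D,ECG,98.1,6.4,-0.2,97.9,6.9,4,2,6,16.1,-2.6,13.5,False,False
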