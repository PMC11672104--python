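troponin,ligand,up_mean_deg,up_std_deg,delta_mean_deg,p_mean_deg,p_std_deg,up_fwhm_deg,delta_fwhm_deg,p_fwhm_deg,restored_mean,restored_fwhm
WT,apo,121.61,7.24,1.65,123.26,5.95,21.97,-5.54,16.43,,
G159D,apo,121.51,4.82,-5.31,116.2,6.04,11.49,0.82,12.31,False,False
G159D,EGCG,114.62,9.18,-7.03,107.59,14.53,23.99,-1.51,22.48,False,True
G159D,RVL,112.61,7.64,9.28,121.89,6.99,18.34,-4.41,13.93,True,True
G159D,SilybinA,126.65,5.77,-6.35,120.3,8.47,14.13,6.64,20.77,False,False
G159D,SilybinB,117.74,5.6,3.58,121.32,4.98,11.53,0.02,11.55,True,True
G159D,ECG,118.9,9.0,-8.3,110.6,9.0,11.2,0.5,11.7,False,False
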