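troponin,ligand,up_mean_a,up_std_a,delta_mean_a,p_mean_a,p_std_a,up_fwhm_a,delta_fwhm_a,p_fwhm_a,saltbridge_occupancy_up,saltbridge_occupancy_p,restored_mean,restored_fwhm
WT,apo,30.18,1.34,-0.28,29.9,0.9,2.99,-0.61,2.38,0,0,,
G159D,apo,29.22,0.98,0.35,29.59,1.18,1.57,-0.06,1.51,0.801,0.761,False,False
G159D,EGCG,31.17,1.48,0.81,31.98,1.59,2.38,-0.57,1.81,0.222,0.530,False,True
G159D,RVL,32.13,1.69,-0.74,31.39,1.51,4.94,-2.82,2.12,0.505,0.460,True,True
G159D,SilybinA,30.09,1.5,0.75,30.84,1.04,4.4,-1.97,2.43,0.083,0.403,False,False
G159D,SilybinB,31.83,1.83,-1.11,30.72,1.13,1.9,0.74,2.64,0.175,0.227,True,False
G159D,ECG,30.2,1.2,0.0,30.2,1.4,1.8,0.7,2.5,0.820,0.86,False,False
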