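condition,ligand,ec50_p_um,ec50_p_sem,n_p,ec50_unp_um,ec50_unp_sem,n_unp,ratio,ratio_sem,n_ratio,coupled
Native TF,none,0.14,0.03,7,0.059,0.011,6,2.24,0.10,6,True
Native TF,EGCG,0.26,0.02,7,0.15,0.02,6,1.73,0.16,6,True
Native TF,SilybinA,0.0658,,1,0.0354,,1,1.86,,1,True
Native TF,SilybinB,0.0545,,1,0.0302,,1,1.80,,1,True
Native TF,DHSA,0.0632,,1,0.0330,,1,1.91,,1,True
Native TF,DHSB,0.0660,,1,0.0331,,1,1.99,,1,True
Tm E180G,none,0.0341,0.0032,9,0.0363,0.0047,9,0.95,0.025,9,False
Tm E180G,EGCG,0.11,0.01,5,0.048,0.003,5,2.41,0.32,9,True
Tm E180G,ECG,0.092,,2,0.089,,2,1.03,,2,False
Tm E180G,SilybinA,0.0654,,1,0.0490,,1,1.33,,1,False
Tm E180G,SilybinB,0.0616,,1,0.0306,,1,2.01,,1,True
Tm E180G,DHSA,0.0209,,1,0.0341,,1,0.61,,1,False
Tm E180G,DHSB,0.0627,,1,0.0259,,1,2.42,,1,True
TnC G159D,none,0.092,0.004,5,0.095,0.0005,5,0.97,0.03,5,False
TnC G159D,EGCG,0.19,0.03,5,0.088,0.005,5,2.25,0.41,5,True
TnC G159D,SilybinA,0.141,,1,0.136,,1,1.0,,1,False
TnC G159D,SilybinB,0.121,,1,0.053,,1,2.3,,1,True
TnT R92Q,none,0.072,,1,0.060,,1,1.2,,1,False
TnT R92Q,EGCG,0.141,,1,0.045,,1,3.1,,1,True
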