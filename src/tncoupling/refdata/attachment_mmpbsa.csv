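troponin,ligand,mmpbsa_switch_up,mmpbsa_switch_up_std,mmpbsa_switch_delta,mmpbsa_switch_p,mmpbsa_switch_p_std,mmpbsa_ligand_up,mmpbsa_ligand_up_std,mmpbsa_ligand_delta,mmpbsa_ligand_p,mmpbsa_ligand_p_std,fraction_attached_up,fraction_attached_p
WT,apo,-108.43,24.05,-3.46,-111.89,13.91,,,,,,,
G159D,apo,-113.47,13.75,-3.53,-117.0,15.01,,,,,,,
G159D,EGCG,-109.26,13.73,-13.6,-122.87,13.56,-26.12,11.19,-0.71,-25.41,10.14,0.93,0.88
G159D,RVL,-104.91,15.69,-2.02,-106.93,15.23,-13.71,8.46,-1.36,-12.35,7.56,0.49,0.33
G159D,SilybinA,-113.65,15.03,1.8,-111.85,16.08,-25.48,9.21,-6.36,-19.12,9.26,0.95,0.82
G159D,SilybinB,-106.72,17.92,0.07,-106.79,13.52,-26.16,10.04,0.47,-26.63,10.69,0.95,0.88
G159D,ECG,-108.1,15.2,-4.9,-113.0,16.6,-25.0,,0.9,-25.9,,0.92,
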