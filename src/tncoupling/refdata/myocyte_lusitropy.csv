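model,mutation,ligand,ttb90_fractional_change,lusitropy,restored
mouse,WT,none,-0.21,0.21,
guinea_pig,WT,none,-0.21,0.21,
mouse,E99K,none,0.12,-0.12,False
guinea_pig,R92Q,none,0.09,-0.09,False
mouse,E99K,SilybinB,-0.25,0.25,True
guinea_pig,R92Q,SilybinB,-0.13,0.13,True
mouse,E99K,RVL,-0.41,0.41,True
guinea_pig,R92Q,RVL,-0.17,0.17,True
mouse,E99K,EGCG,-0.22,0.22,True
guinea_pig,R92Q,EGCG,-0.17,0.17,True
mouse,E99K,SilybinA,0.04,-0.04,False
guinea_pig,R92Q,SilybinA,0.18,-0.18,False
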