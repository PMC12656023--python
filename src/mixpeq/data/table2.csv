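compound,rpf_min,rpf_max,read_across
PFBA,0.1,0.1,False
PFBS,0,0,False
PFDA,4,10,False
PFDS,2,2,False
PFDoDA,3,3,False
PFHpA,0,1,False
PFHpS,0.6,2,True
PFPeS,0.001,0.6,True
PFHxA,0,0,False
PFHxS,0.6,0.6,False
PFHxDA,0.02,0.02,False
PFNA,10,10,False
PFOA,1,1,False
PFOS,2,2,False
PFODA,0.02,0.02,False
PFPeA,0,0,False
PFTeDA,0.3,0.3,False
PFTrDA,0.3,3,True
PFUnDA,4,4,False
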