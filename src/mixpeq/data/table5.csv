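group,compound,ewi_min,ewi_max,pct_min,pct_max
toddlers,PFHpA,0.00,0.03,0,1
toddlers,PFHxA,0.00,0.00,0,0
toddlers,PFHxS,0.00,0.00,0,0
toddlers,PFOA,0.63,0.63,14,14
toddlers,PFOS,3.15,3.15,72,72
toddlers,PFTrDA,0.00,0.02,0,1
toddlers,PFUnDA,0.02,0.02,0,0
toddlers,CUMULATIVE,3.80,3.85,86,88
adolescents,PFHpA,0.00,0.01,0,0
adolescents,PFHxA,0.00,0.00,0,0
adolescents,PFHxS,0.00,0.00,0,0
adolescents,PFOA,0.26,0.26,6,6
adolescents,PFOS,1.33,1.33,30,30
adolescents,PFTrDA,0.00,0.00,0,0
adolescents,PFUnDA,0.01,0.01,0,0
adolescents,CUMULATIVE,1.61,1.63,37,37
adults,PFHpA,0.00,0.01,0,0
adults,PFHxA,0.00,0.00,0,0
adults,PFHxS,0.00,0.00,0,0
adults,PFOA,0.20,0.20,5,5
adults,PFOS,1.02,1.02,23,23
adults,PFTrDA,0.00,0.00,0,0
adults,PFUnDA,0.01,0.01,0,0
adults,CUMULATIVE,1.23,1.24,28,28
elderly,PFHpA,0.00,0.01,0,0
elderly,PFHxA,0.00,0.00,0,0
elderly,PFHxS,0.00,0.00,0,0
elderly,PFOA,0.19,0.19,4,4
elderly,PFOS,0.96,0.96,22,22
elderly,PFTrDA,0.00,0.00,0,0
elderly,PFUnDA,0.01,0.01,0,0
elderly,CUMULATIVE,1.16,1.18,26,27
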