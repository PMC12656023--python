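group,compound,ewi_min,ewi_max,pct_min,pct_max
toddlers,PFBS,0.00,0.00,0,0
toddlers,PFDA,0.03,0.08,1,2
toddlers,PFHxA,0.00,0.00,0,0
toddlers,PFHxS,0.00,0.00,0,0
toddlers,PFNA,0.07,0.07,2,2
toddlers,PFOA,0.12,0.12,3,3
toddlers,PFOS,0.29,0.29,7,7
toddlers,PFPeA,0.03,0.03,1,1
toddlers,CUMULATIVE,0.54,0.59,12,13
adolescents,PFBS,0.00,0.00,0,0
adolescents,PFDA,0.01,0.02,0,0
adolescents,PFHxA,0.00,0.00,0,0
adolescents,PFHxS,0.00,0.00,0,0
adolescents,PFNA,0.02,0.02,0,0
adolescents,PFOA,0.03,0.03,1,1
adolescents,PFOS,0.08,0.08,2,2
adolescents,PFPeA,0.01,0.01,0,0
adolescents,CUMULATIVE,0.14,0.15,3,3
adults,PFBS,0.00,0.00,0,0
adults,PFDA,0.00,0.01,0,0
adults,PFHxA,0.00,0.00,0,0
adults,PFHxS,0.00,0.00,0,0
adults,PFNA,0.01,0.01,0,0
adults,PFOA,0.02,0.02,0,0
adults,PFOS,0.04,0.04,1,1
adults,PFPeA,0.00,0.00,0,0
adults,CUMULATIVE,0.07,0.08,2,2
elderly,PFBS,0.00,0.00,0,0
elderly,PFDA,0.00,0.01,0,0
elderly,PFHxA,0.00,0.00,0,0
elderly,PFHxS,0.00,0.00,0,0
elderly,PFNA,0.01,0.01,0,0
elderly,PFOA,0.01,0.01,0,0
elderly,PFOS,0.04,0.04,1,1
elderly,PFPeA,0.00,0.00,0,0
elderly,CUMULATIVE,0.07,0.07,2,2
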