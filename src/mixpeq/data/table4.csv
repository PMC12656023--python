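group,compound,ewi_min,ewi_max,pct_min,pct_max
toddlers,PFBA,0.00,0.00,0,0
toddlers,PFBS,0.00,0.00,0,0
toddlers,PFDA,0.18,0.44,4,10
toddlers,PFDS,0.09,0.09,2,2
toddlers,PFDoDA,0.32,0.32,7,7
toddlers,PFHpA,0.00,0.02,0,0
toddlers,PFHpS,0.00,0.01,0,0
toddlers,PFHxA,0.00,0.00,0,0
toddlers,PFHxS,0.00,0.00,0,0
toddlers,PFNA,0.29,0.29,7,7
toddlers,PFOA,0.57,0.57,13,13
toddlers,PFOS,2.53,2.53,58,58
toddlers,PFPeA,0.00,0.00,0,0
toddlers,PFTeDA,0.00,0.00,0,0
toddlers,PFTrDA,0.01,0.05,0,1
toddlers,PFUnDA,0.11,0.11,2,2
toddlers,CUMULATIVE,4.11,4.44,93,101
adolescents,PFBA,0.00,0.00,0,0
adolescents,PFBS,0.00,0.00,0,0
adolescents,PFDA,0.12,0.31,3,7
adolescents,PFDS,0.06,0.06,1,1
adolescents,PFDoDA,0.23,0.23,5,5
adolescents,PFHpA,0.00,0.01,0,0
adolescents,PFHpS,0.00,0.00,0,0
adolescents,PFHxA,0.00,0.00,0,0
adolescents,PFHxS,0.00,0.00,0,0
adolescents,PFNA,0.21,0.21,5,5
adolescents,PFOA,0.40,0.40,9,9
adolescents,PFOS,1.80,1.80,41,41
adolescents,PFPeA,0.00,0.00,0,0
adolescents,PFTeDA,0.00,0.00,0,0
adolescents,PFTrDA,0.00,0.04,0,1
adolescents,PFUnDA,0.07,0.07,2,2
adolescents,CUMULATIVE,2.91,3.15,66,72
adults,PFBA,0.00,0.00,0,0
adults,PFBS,0.00,0.00,0,0
adults,PFDA,0.09,0.22,2,5
adults,PFDS,0.04,0.04,1,1
adults,PFDoDA,0.16,0.16,4,4
adults,PFHpA,0.00,0.01,0,0
adults,PFHpS,0.00,0.00,0,0
adults,PFHxA,0.00,0.00,0,0
adults,PFHxS,0.00,0.00,0,0
adults,PFNA,0.14,0.14,3,3
adults,PFOA,0.28,0.28,6,6
adults,PFOS,1.26,1.26,29,29
adults,PFPeA,0.00,0.00,0,0
adults,PFTeDA,0.00,0.00,0,0
adults,PFTrDA,0.00,0.03,0,1
adults,PFUnDA,0.05,0.05,1,1
adults,CUMULATIVE,2.04,2.20,46,50
elderly,PFBA,0.00,0.00,0,0
elderly,PFBS,0.00,0.00,0,0
elderly,PFDA,0.08,0.19,2,4
elderly,PFDS,0.04,0.04,1,1
elderly,PFDoDA,0.14,0.14,3,3
elderly,PFHpA,0.00,0.01,0,0
elderly,PFHpS,0.00,0.00,0,0
elderly,PFHxA,0.00,0.00,0,0
elderly,PFHxS,0.00,0.00,0,0
elderly,PFNA,0.12,0.12,3,3
elderly,PFOA,0.25,0.25,6,6
elderly,PFOS,1.09,1.09,25,25
elderly,PFPeA,0.00,0.00,0,0
elderly,PFTeDA,0.00,0.00,0,0
elderly,PFTrDA,0.00,0.02,0,1
elderly,PFUnDA,0.05,0.05,1,1
elderly,CUMULATIVE,1.77,1.91,40,43
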