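group,compound,ewi_min,ewi_max,pct_min,pct_max
toddlers,PFBS,0.00,0.00,0,0
toddlers,PFDA,1.93,4.83,44,110
toddlers,PFDS,0.00,0.00,0,0
toddlers,PFDoDA,0.35,0.35,8,8
toddlers,PFHpA,0.00,0.04,0,1
toddlers,PFHxA,0.00,0.00,0,0
toddlers,PFHxS,0.01,0.01,0,0
toddlers,PFNA,2.56,2.56,58,58
toddlers,PFOA,1.38,1.38,31,31
toddlers,PFOS,15.59,15.59,354,354
toddlers,PFPeA,0.02,0.02,0,0
toddlers,PFTeDA,0.00,0.00,0,0
toddlers,PFTrDA,0.04,0.41,1,9
toddlers,PFUnDA,0.73,0.73,17,17
toddlers,CUMULATIVE,22.62,25.93,514,589
adolescents,PFBS,0.00,0.00,0,0
adolescents,PFDA,1.09,2.72,25,62
adolescents,PFDS,0.00,0.00,0,0
adolescents,PFDoDA,0.20,0.20,5,5
adolescents,PFHpA,0.00,0.00,0,0
adolescents,PFHxA,0.00,0.00,0,0
adolescents,PFHxS,0.01,0.01,0,0
adolescents,PFNA,1.44,1.44,33,33
adolescents,PFOA,0.77,0.77,18,18
adolescents,PFOS,8.78,8.78,199,199
adolescents,PFPeA,0.01,0.01,0,0
adolescents,PFTeDA,0.00,0.00,0,0
adolescents,PFTrDA,0.02,0.23,1,5
adolescents,PFUnDA,0.41,0.41,9,9
adolescents,CUMULATIVE,12.74,14.57,289,331
adults,PFBS,0.00,0.00,0,0
adults,PFDA,0.96,2.39,22,54
adults,PFDS,0.00,0.00,0,0
adults,PFDoDA,0.18,0.18,4,4
adults,PFHpA,0.00,0.02,0,0
adults,PFHxA,0.00,0.00,0,0
adults,PFHxS,0.01,0.01,0,0
adults,PFNA,1.27,1.27,29,29
adults,PFOA,0.68,0.68,15,15
adults,PFOS,7.72,7.72,175,175
adults,PFPeA,0.01,0.01,0,0
adults,PFTeDA,0.00,0.00,0,0
adults,PFTrDA,0.02,0.20,0,5
adults,PFUnDA,0.36,0.36,8,8
adults,CUMULATIVE,11.20,12.83,255,292
elderly,PFBS,0.00,0.00,0,0
elderly,PFDA,1.03,2.58,23,59
elderly,PFDS,0.00,0.00,0,0
elderly,PFDoDA,0.19,0.19,4,4
elderly,PFHpA,0.00,0.02,0,0
elderly,PFHxA,0.00,0.00,0,0
elderly,PFHxS,0.01,0.01,0,0
elderly,PFNA,1.37,1.37,31,31
elderly,PFOA,0.73,0.73,17,17
elderly,PFOS,8.31,8.31,189,189
elderly,PFPeA,0.01,0.01,0,0
elderly,PFTeDA,0.00,0.00,0,0
elderly,PFTrDA,0.02,0.22,0,5
elderly,PFUnDA,0.39,0.39,9,9
elderly,CUMULATIVE,12.06,13.83,274,314
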