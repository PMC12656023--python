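group,compound,ewi_min,ewi_max
toddlers,PFBA,0.00,0.00
toddlers,PFBS,0.00,0.00
toddlers,PFDA,2.14,5.35
toddlers,PFDS,0.09,0.09
toddlers,PFDoDA,0.67,0.67
toddlers,PFHpA,0.00,0.09
toddlers,PFHpS,0.00,0.01
toddlers,PFHxA,0.00,0.00
toddlers,PFHxS,0.01,0.01
toddlers,PFNA,2.92,2.92
toddlers,PFOA,2.69,2.69
toddlers,PFOS,21.56,21.56
toddlers,PFPeA,0.06,0.06
toddlers,PFTeDA,0.01,0.01
toddlers,PFTrDA,0.05,0.48
toddlers,PFUnDA,0.85,0.85
toddlers,CUMULATIVE,31.07,34.81
toddlers,PEQ_HI,7.06,7.91
toddlers,CB_HI,3.98,3.98
adolescents,PFBA,0.00,0.00
adolescents,PFBS,0.00,0.00
adolescents,PFDA,1.22,3.05
adolescents,PFDS,0.06,0.06
adolescents,PFDoDA,0.43,0.43
adolescents,PFHpA,0.00,0.03
adolescents,PFHpS,0.00,0.00
adolescents,PFHxA,0.00,0.00
adolescents,PFHxS,0.01,0.01
adolescents,PFNA,1.67,1.67
adolescents,PFOA,1.47,1.47
adolescents,PFOS,11.98,11.98
adolescents,PFPeA,0.02,0.02
adolescents,PFTeDA,0.00,0.00
adolescents,PFTrDA,0.03,0.27
adolescents,PFUnDA,0.50,0.50
adolescents,CUMULATIVE,17.40,19.50
adolescents,PEQ_HI,3.95,4.43
adolescents,CB_HI,2.15,2.15
adults,PFBA,0.00,0.00
adults,PFBS,0.00,0.00
adults,PFDA,1.05,2.62
adults,PFDS,0.04,0.04
adults,PFDoDA,0.34,0.34
adults,PFHpA,0.00,0.04
adults,PFHpS,0.00,0.00
adults,PFHxA,0.00,0.00
adults,PFHxS,0.01,0.01
adults,PFNA,1.42,1.42
adults,PFOA,1.18,1.18
adults,PFOS,10.03,10.03
adults,PFPeA,0.02,0.02
adults,PFTeDA,0.00,0.00
adults,PFTrDA,0.02,0.23
adults,PFUnDA,0.42,0.42
adults,CUMULATIVE,14.54,16.35
adults,PEQ_HI,3.30,3.72
adults,CB_HI,1.76,1.76
elderly,PFBA,0.00,0.00
elderly,PFBS,0.00,0.00
elderly,PFDA,1.11,2.78
elderly,PFDS,0.04,0.04
elderly,PFDoDA,0.33,0.33
elderly,PFHpA,0.00,0.04
elderly,PFHpS,0.00,0.00
elderly,PFHxA,0.00,0.00
elderly,PFHxS,0.01,0.01
elderly,PFNA,1.50,1.50
elderly,PFOA,1.19,1.19
elderly,PFOS,10.40,10.40
elderly,PFPeA,0.02,0.02
elderly,PFTeDA,0.00,0.00
elderly,PFTrDA,0.02,0.24
elderly,PFUnDA,0.44,0.44
elderly,CUMULATIVE,15.06,16.99
elderly,PEQ_HI,3.42,3.86
elderly,CB_HI,1.82,1.82
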