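food_category,group,mean_consumption_g_day
fish_seafood,toddlers,9.4
fish_seafood,adolescents,18.7
fish_seafood,adults,25.6
fish_seafood,elderly,28.9
meat,toddlers,47.0
meat,adolescents,125.3
meat,adults,135.9
meat,elderly,117.7
eggs,toddlers,10.1
eggs,adolescents,15.9
eggs,adults,18.6
eggs,elderly,18.3
milk_dairy,toddlers,324.5
milk_dairy,adolescents,318.0
milk_dairy,adults,254.6
milk_dairy,elderly,237.1
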