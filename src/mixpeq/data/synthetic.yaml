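# Example synthetic-truth config for `mixpeq simulate` / mixpeq.synthetic.load_truths_yaml.
# One block per compound x food category; concentrations in ng/kg food.
# censor_prob defaults to 0.92, the censored fraction of the underlying
# European monitoring dataset; positives are lognormal(meanlog, sdlog).
seed: 20201
truths:
  - compound: PFOS
    food_category: fish_seafood
    censor_prob: 0.92
    meanlog: 9.2      # median ~ 9900 ng/kg among quantified samples
    sdlog: 1.0
    lod: 200.0
    loq: 400.0
    n_samples: 5000
  - compound: PFOA
    food_category: fish_seafood
    censor_prob: 0.92
    meanlog: 8.0
    sdlog: 1.0
    lod: 200.0
    loq: 400.0
    n_samples: 5000
  - compound: PFOS
    food_category: milk_dairy
    censor_prob: 0.95
    meanlog: 5.5
    sdlog: 0.8
    lod: 40.0
    loq: 80.0
    n_samples: 5000
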