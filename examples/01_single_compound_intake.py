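"""One compound, one food, one consumer: the basic intake calculation.

Adult fish/seafood consumption (25.6 g/day, 70 kg body weight) of fish
carrying 1507.8 ng/kg PFOS.  PFOS has relative potency 2 against the index
compound PFOA, so in PFOA equivalents the weekly intake is

    EWI = 1507.8 × 2 × (25.6/1000) / 70 × 7  ≈ 7.72 ng/kg bw per week
"""

from mixpeq import pct_twi, round_report, weekly_intake_term

concentration = 1507.8  # ng PFOS per kg fish
rpf = 2.0               # PFOS potency relative to PFOA
consumption = 25.6      # g fish per day (European adult mean)
body_weight = 70.0      # kg (EFSA standard adult)

ewi = weekly_intake_term(concentration, rpf, consumption, body_weight)
print(f"PEQ-EWI: {round_report(ewi, 'ewi')} ng/kg bw per week")
print(f"as %TWI: {round_report(pct_twi(ewi), 'pct')} of the 4.4 ng/kg bw per week group TWI")
# This single compound in a single food already exceeds the tolerable weekly
# intake: ~7.72 ng/kg bw per week is ~175% of the TWI.
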