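"""From censored sample-level records to exposure: the monitoring pipeline.

Real PFAS monitoring data are ~92% left-censored; the LB mean (non-detects
counted as 0) is driven entirely by the small quantifiable tail.  Here a
synthetic generator with known ground truth emulates that structure, and the
recovered LB mean is compared with its closed-form expectation.
"""

import math

from mixpeq import (
    FoodCategory,
    Group,
    Mode,
    PopulationGroup,
    Scenario,
    SyntheticTruth,
    analytic_lb_mean,
    bound_mean,
    build_exposure_table,
    generate_occurrence_samples,
    occurrence_from_samples,
    round_report,
)
from mixpeq import reference

truth = SyntheticTruth(
    compound="PFOS", food_category=FoodCategory.FISH_SEAFOOD,
    censor_prob=0.92,            # censored fraction of the European dataset
    meanlog=math.log(10_000),    # quantified values: lognormal, median 10 ug/kg
    sdlog=1.0,
    lod=200.0, loq=400.0,
    n_samples=10_000,
)
samples = generate_occurrence_samples(truth, seed=1)

lb = bound_mean(samples, "LB")
ub = bound_mean(samples, "UB")
print(f"LB mean {lb:.1f} ng/kg (expected {analytic_lb_mean(truth):.1f}), UB mean {ub:.1f} ng/kg")

estimates = occurrence_from_samples(samples)
res = build_exposure_table(
    estimates, reference.rpf_assignments(), reference.consumption_profiles(),
    [PopulationGroup.default(Group.ADULTS)], Mode.PEQ, Scenario.MIN,
)
s = res.summaries[Group.ADULTS]
print(
    f"adult fish PEQ-EWI {round_report(s.total_ewi, 'ewi')} ng/kg bw per week, "
    f"HI {round_report(s.hazard_index, 'hi')}"
)
# Only ~8% of samples are quantified, yet they set the whole LB mean — the
# censored 92% contribute nothing under LB substitution.
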