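"""Survey-weighted mean consumption.

European mean consumption per food category and group is a weighted mean of
Member State surveys (weights = subjects).  Two hand-made surveys, then a
generated multi-survey design converging on a known population mean.
"""

from mixpeq import (
    FoodCategory,
    Group,
    SurveyConsumption,
    generate_consumption_surveys,
    weighted_mean_consumption,
)

surveys = [
    SurveyConsumption("NO-2019", FoodCategory.FISH_SEAFOOD, Group.ADULTS, 42.0, weight=1200),
    SurveyConsumption("IT-2018", FoodCategory.FISH_SEAFOOD, Group.ADULTS, 21.0, weight=2400),
]
print(f"two-survey weighted mean: {weighted_mean_consumption(surveys):.1f} g/day")

many = generate_consumption_surveys(
    200, FoodCategory.FISH_SEAFOOD, Group.ADULTS, mean=25.6, cv=0.3, seed=7
)
print(f"200-survey weighted mean: {weighted_mean_consumption(many):.1f} g/day (population mean 25.6)")
# The weighted mean always lies between the smallest and largest survey mean
# and converges to the population mean as surveys accumulate.
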