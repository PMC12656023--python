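import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixpeq import (
    ConsumptionProfile,
    FoodCategory,
    Group,
    Mode,
    OccurrenceEstimate,
    PopulationGroup,
    RpfAssignment,
    RpfTable,
    Scenario,
)
from mixpeq import reference

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rpf_table() -> RpfTable:
    """Shipped default RPF table (PFPeA = 0.03)."""
    return reference.rpf_assignments()


@pytest.fixture(scope="session")
def consumption() -> list[ConsumptionProfile]:
    return reference.consumption_profiles()


@pytest.fixture(scope="session")
def groups() -> list[PopulationGroup]:
    return reference.population_groups()


def random_inputs(seed: int, n_records: int = 200):
    """A random but valid occurrence/RPF/consumption problem for oracle checks."""
    rng = np.random.default_rng(seed)
    compounds = [f"C{i:02d}" for i in range(12)]
    assignments = []
    for c in compounds:
        lo = float(rng.uniform(0, 5))
        hi = lo if rng.random() < 0.5 else float(lo + rng.uniform(0, 5))
        assignments.append(RpfAssignment(compound=c, rpf_min=lo, rpf_max=hi))
    table = RpfTable(assignments)
    seen = set()
    occurrence = []
    while len(occurrence) < n_records:
        c = compounds[int(rng.integers(len(compounds)))]
        cat = list(FoodCategory)[int(rng.integers(4))]
        if (c, cat) in seen:
            continue
        seen.add((c, cat))
        lb = float(rng.lognormal(3, 2))
        occurrence.append(
            OccurrenceEstimate(compound=c, food_category=cat, mean_lb=lb, mean_ub=lb * float(rng.uniform(1, 3)))
        )
        if len(seen) == len(compounds) * 4:
            break
    cons = [
        ConsumptionProfile(food_category=cat, group=g, mean_consumption=float(rng.uniform(1, 400)))
        for cat in FoodCategory
        for g in Group
    ]
    pops = [PopulationGroup(name=g, body_weight=float(rng.uniform(10, 90))) for g in Group]
    return occurrence, table, cons, pops


def naive_exposure(occurrence, rpf_table, consumption, groups, mode, scenario, twi=4.4, bound="LB"):
    """Independent per-record loop oracle for the vectorized engine.

    Plain Python arithmetic, no numpy, no shared code path with the engine
    beyond the RPF lookup table.
    """
    mode = Mode(mode)
    scenario = Scenario(scenario)
    cons = {(c.food_category, c.group): c.mean_consumption for c in consumption}
    cells = {}
    totals = {}
    for pg in groups:
        per_cat = {cat: [] for cat in FoodCategory}
        for o in occurrence:
            conc = o.mean_lb if bound == "LB" else (o.mean_ub if o.mean_ub is not None else o.mean_lb)
            if mode is Mode.CB:
                rpf = 1.0
            else:
                a = rpf_table.get(o.compound)
                rpf = a.rpf_min if scenario is Scenario.MIN else a.rpf_max
            ewi = conc * rpf * (cons[(o.food_category, pg.name)] / 1000.0) / pg.body_weight * 7.0
            cells[(o.compound, o.food_category, pg.name)] = ewi
            per_cat[o.food_category].append(ewi)
        cums = {cat: math.fsum(v) for cat, v in per_cat.items()}
        tot = math.fsum(cums.values())
        totals[pg.name] = {"per_category": cums, "total": tot, "hi": tot / twi}
    return cells, totals
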