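"""Domain model and equations for cumulative PFAS risk in PFOA equivalents.

The engine implements dose-additive mixture assessment for per- and
polyfluoroalkyl substances (PFAS) in food.  Each compound's concentration is
scaled by a relative potency factor (RPF, PFOA = 1, hepatic-toxicity endpoint)
to express it in PFOA equivalents (PEQ).  Weekly intakes are

    EWI_i = C_i × RPF_i × (consumption / 1000) / BW × 7      [ng/kg bw per week]

with ``C_i`` the mean occurrence in ng/kg food, consumption in g/day and BW the
body weight in kg.  Per-category cumulative EWIs are the sum over compounds,
the total EWI the sum over food categories, and risk is characterised against
the EFSA 2020 group tolerable weekly intake (TWI = 4.4 ng/kg bw per week) via
%TWI and the Hazard Index HI = total EWI / TWI.

Data-poor compounds carry an RPF *range* from chain-length read-across; the
``min`` / ``max`` scenarios set every range-valued compound at its lower /
upper potency simultaneously.  The concentration-based (CB) comparator path is
the same arithmetic with every RPF forced to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import AggregationError, DomainError, MissingRpfError, NonInvertibleError

#: EFSA 2020 group tolerable weekly intake for PFOA+PFOS+PFNA+PFHxS, ng/kg bw per week.
TWI_EFSA_2020: float = 4.4

#: Daily-to-weekly conversion.
DAYS_PER_WEEK: int = 7

#: Consumption is recorded in g/day; concentrations are per kg food.
GRAMS_PER_KG: float = 1000.0


class FoodCategory(str, Enum):
    """The four animal-derived food categories of the assessment."""

    FISH_SEAFOOD = "fish_seafood"
    MEAT = "meat"
    EGGS = "eggs"
    MILK_DAIRY = "milk_dairy"


class Group(str, Enum):
    """European consumer age groups."""

    TODDLERS = "toddlers"
    ADOLESCENTS = "adolescents"
    ADULTS = "adults"
    ELDERLY = "elderly"


class Mode(str, Enum):
    """PEQ = potency-weighted (PFOA equivalents); CB = unweighted concentration-based."""

    PEQ = "PEQ"
    CB = "CB"


class Scenario(str, Enum):
    """Coherent RPF scenario: all range-valued compounds at their min or max potency."""

    MIN = "min"
    MAX = "max"


#: EFSA standard body weights, kg.
DEFAULT_BODY_WEIGHTS: dict[Group, float] = {
    Group.TODDLERS: 12.0,
    Group.ADOLESCENTS: 45.0,
    Group.ADULTS: 70.0,
    Group.ELDERLY: 70.0,
}


@dataclass(frozen=True, slots=True)
class PopulationGroup:
    """A consumer group with its standard body weight in kg."""

    name: Group
    body_weight: float

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise DomainError(f"body_weight must be > 0, got {self.body_weight}")

    @classmethod
    def default(cls, name: Group | str) -> "PopulationGroup":
        name = Group(name)
        return cls(name=name, body_weight=DEFAULT_BODY_WEIGHTS[name])


@dataclass(frozen=True, slots=True)
class RpfAssignment:
    """A compound's relative potency, fixed or as a read-across range.

    ``rpf_min == rpf_max`` for fixed-value compounds; the index compound PFOA
    has RPF 1 by construction.
    """

    compound: str
    rpf_min: float
    rpf_max: float
    read_across: bool = False

    def __post_init__(self) -> None:
        if self.rpf_min < 0 or self.rpf_max < 0:
            raise DomainError(f"{self.compound}: RPFs must be >= 0")
        if self.rpf_min > self.rpf_max:
            raise DomainError(
                f"{self.compound}: rpf_min {self.rpf_min} > rpf_max {self.rpf_max}"
            )

    @classmethod
    def fixed(cls, compound: str, rpf: float) -> "RpfAssignment":
        return cls(compound=compound, rpf_min=rpf, rpf_max=rpf)


@dataclass(frozen=True, slots=True)
class OccurrenceEstimate:
    """Mean lower-bound (and optionally upper-bound) occurrence of one compound
    in one food category, ng/kg food."""

    compound: str
    food_category: FoodCategory
    mean_lb: float
    mean_ub: float | None = None

    def __post_init__(self) -> None:
        if self.mean_lb < 0:
            raise DomainError(f"{self.compound}: mean_lb must be >= 0")
        if self.mean_ub is not None and self.mean_lb > self.mean_ub:
            raise DomainError(
                f"{self.compound}: mean_lb {self.mean_lb} > mean_ub {self.mean_ub}"
            )


@dataclass(frozen=True, slots=True)
class ConsumptionProfile:
    """Mean daily consumption (g/day) of one food category for one group."""

    food_category: FoodCategory
    group: Group
    mean_consumption: float

    def __post_init__(self) -> None:
        if self.mean_consumption < 0:
            raise DomainError("mean_consumption must be >= 0")


@dataclass(frozen=True, slots=True)
class ExposureCell:
    """One compound × category × group × scenario weekly-intake result."""

    compound: str
    food_category: FoodCategory
    group: Group
    mode: Mode
    scenario: Scenario
    ewi: float
    pct_twi: float

    def __post_init__(self) -> None:
        if self.ewi < 0 or self.pct_twi < 0:
            raise DomainError("EWI and %TWI must be >= 0")


@dataclass(frozen=True)
class RiskSummary:
    """Per-group risk characterisation: category cumulatives, total EWI, HI."""

    group: Group
    mode: Mode
    scenario: Scenario
    per_category_cumulative: Mapping[FoodCategory, float]
    total_ewi: float
    hazard_index: float

    def __post_init__(self) -> None:
        s = math.fsum(self.per_category_cumulative.values())
        if not math.isclose(s, self.total_ewi, rel_tol=1e-9, abs_tol=1e-12):
            raise AggregationError(
                f"total_ewi {self.total_ewi} != sum of category cumulatives {s}"
            )


class RpfTable:
    """Lookup table of RPF assignments, keyed by compound identifier."""

    def __init__(self, assignments: Sequence[RpfAssignment]):
        self._by_compound = {a.compound: a for a in assignments}

    def __contains__(self, compound: str) -> bool:
        return compound in self._by_compound

    def __iter__(self):
        return iter(self._by_compound.values())

    def __len__(self) -> int:
        return len(self._by_compound)

    def get(self, compound: str) -> RpfAssignment:
        try:
            return self._by_compound[compound]
        except KeyError:
            raise MissingRpfError(f"no RPF assignment for compound {compound!r}") from None

    def resolve(self, compound: str, scenario: Scenario | str) -> float:
        return resolve_rpf(self.get(compound), scenario)


def resolve_rpf(assignment: RpfAssignment, scenario: Scenario | str) -> float:
    """Return the scenario-resolved potency: ``rpf_min`` under the min scenario,
    ``rpf_max`` under max.  Fixed-value compounds return the same number for both."""
    scenario = Scenario(scenario)
    return assignment.rpf_min if scenario is Scenario.MIN else assignment.rpf_max


def weekly_intake_term(
    concentration: float | np.ndarray,
    rpf: float | np.ndarray,
    consumption: float | np.ndarray,
    body_weight: float,
) -> float | np.ndarray:
    """One compound's estimated weekly intake, ng/kg bw per week.

    ``concentration`` in ng/kg food, ``rpf`` dimensionless, ``consumption`` in
    g/day (converted to kg/day internally), ``body_weight`` in kg.  Accepts
    numpy arrays for the first three arguments and broadcasts.
    """
    if body_weight <= 0:
        raise DomainError(f"body_weight must be > 0, got {body_weight}")
    if np.any(np.asarray(concentration) < 0):
        raise DomainError("concentration must be >= 0")
    if np.any(np.asarray(rpf) < 0):
        raise DomainError("rpf must be >= 0")
    if np.any(np.asarray(consumption) < 0):
        raise DomainError("consumption must be >= 0")
    return concentration * rpf * (consumption / GRAMS_PER_KG) / body_weight * DAYS_PER_WEEK


def cumulative_ewi(cells: Sequence[ExposureCell]) -> float:
    """Sum the unrounded per-compound weekly intakes of one food category.

    All cells must share food_category, group, mode and scenario; compounds
    absent from the occurrence table simply contribute no cell.  An empty list
    yields 0.
    """
    if not cells:
        return 0.0
    keys = {(c.food_category, c.group, c.mode, c.scenario) for c in cells}
    if len(keys) > 1:
        raise AggregationError(f"cells mix categories/groups/modes/scenarios: {sorted(map(str, keys))}")
    return math.fsum(c.ewi for c in cells)


def total_ewi(per_category: Mapping[FoodCategory | str, float]) -> float:
    """Total weekly intake: arithmetic sum of the per-category cumulative EWIs."""
    for cat, v in per_category.items():
        if v < 0:
            raise DomainError(f"cumulative EWI for {cat} must be >= 0, got {v}")
    return math.fsum(per_category.values())


def pct_twi(ewi: float, twi: float = TWI_EFSA_2020) -> float:
    """Exposure as a percentage of the tolerable weekly intake, unrounded."""
    if twi <= 0:
        raise DomainError(f"TWI must be > 0, got {twi}")
    return ewi / twi * 100.0


def hazard_index(total: float, twi: float = TWI_EFSA_2020) -> float:
    """Hazard index = total EWI / TWI.  HI > 1 flags potential concern."""
    if twi <= 0:
        raise DomainError(f"TWI must be > 0, got {twi}")
    return total / twi


def back_derive_concentration(
    ewi: float, rpf: float, consumption: float, body_weight: float
) -> float:
    """Invert the intake equation: recover the ng/kg food concentration that
    yields ``ewi`` for the given potency, consumption and body weight.

    Round-trips with :func:`weekly_intake_term` to floating tolerance.  Raises
    :class:`NonInvertibleError` when rpf or consumption is zero.
    """
    if body_weight <= 0:
        raise DomainError(f"body_weight must be > 0, got {body_weight}")
    if ewi < 0:
        raise DomainError("ewi must be >= 0")
    if rpf <= 0 or consumption <= 0:
        raise NonInvertibleError(
            f"cannot invert intake with rpf={rpf}, consumption={consumption}"
        )
    return ewi / (rpf * (consumption / GRAMS_PER_KG) / body_weight * DAYS_PER_WEEK)
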