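"""Occurrence aggregation and the exposure engine.

Mean occurrence estimates are built from sample-level records by censoring
substitution: non-detects contribute 0 under the lower-bound (LB) convention
and their quantification/detection limit under the upper-bound (UB)
convention.  Mean consumption per food category and group is a survey-weighted
mean.  ``build_exposure_table`` combines occurrence, RPFs, consumption and
body weights into per-compound exposure cells and per-group risk summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    TWI_EFSA_2020,
    ConsumptionProfile,
    ExposureCell,
    FoodCategory,
    Group,
    Mode,
    OccurrenceEstimate,
    PopulationGroup,
    RiskSummary,
    RpfTable,
    Scenario,
    hazard_index,
    pct_twi,
    resolve_rpf,
    total_ewi,
    weekly_intake_term,
)
from .errors import (
    AggregationError,
    ConfigurationError,
    DomainError,
    MissingLimitError,
)

logger = logging.getLogger(__name__)

Bound = Literal["LB", "UB"]


@dataclass(frozen=True, slots=True)
class SampleRecord:
    """One analytical result: a quantified concentration (ng/kg) or a
    left-censored record carrying its LOD and/or LOQ."""

    compound: str
    food_category: FoodCategory
    value: float | None = None
    censored: bool = False
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise DomainError("censored record must not carry a quantified value")
            if self.lod is None and self.loq is None:
                raise DomainError("censored record needs at least one of lod/loq")
        else:
            if self.value is None or self.value < 0:
                raise DomainError("quantified record needs value >= 0")


@dataclass(frozen=True, slots=True)
class SurveyConsumption:
    """One dietary survey's mean consumption (g/day) with its weight
    (typically the number of subjects)."""

    survey_id: str
    food_category: FoodCategory
    group: Group
    mean_consumption: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DomainError("survey weight must be > 0")
        if self.mean_consumption < 0:
            raise DomainError("mean_consumption must be >= 0")


def _substitute(record: SampleRecord, bound: Bound) -> float:
    if not record.censored:
        return float(record.value)  # type: ignore[arg-type]
    if bound == "LB":
        return 0.0
    # UB: prefer LOQ (the reporting limit, and the larger, conservative bound)
    if record.loq is not None:
        return float(record.loq)
    if record.lod is not None:
        return float(record.lod)
    raise MissingLimitError(
        f"{record.compound}/{record.food_category.value}: censored record has no LOD/LOQ"
    )


def bound_mean(samples: Sequence[SampleRecord], bound: Bound = "LB") -> float:
    """Mean concentration under a censoring-substitution convention.

    LB assigns 0 to non-detects; UB assigns the LOQ (or LOD when no LOQ is
    reported).  The sample list must be non-empty and homogeneous in compound
    and food category.
    """
    if not samples:
        raise AggregationError("bound_mean needs a non-empty sample list")
    keys = {(s.compound, s.food_category) for s in samples}
    if len(keys) > 1:
        raise AggregationError(f"samples mix compounds/categories: {sorted(map(str, keys))}")
    if bound not in ("LB", "UB"):
        raise DomainError(f"bound must be 'LB' or 'UB', got {bound!r}")
    return math.fsum(_substitute(s, bound) for s in samples) / len(samples)


def occurrence_from_samples(samples: Iterable[SampleRecord]) -> list[OccurrenceEstimate]:
    """Aggregate sample records into per compound × category LB/UB occurrence means."""
    by_key: dict[tuple[str, FoodCategory], list[SampleRecord]] = {}
    for s in samples:
        by_key.setdefault((s.compound, s.food_category), []).append(s)
    out = []
    for (compound, category), recs in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        out.append(
            OccurrenceEstimate(
                compound=compound,
                food_category=category,
                mean_lb=bound_mean(recs, "LB"),
                mean_ub=bound_mean(recs, "UB"),
            )
        )
    return out


def weighted_mean_consumption(surveys: Sequence[SurveyConsumption]) -> float:
    """Survey-weighted mean consumption, Σ(wᵢ·mᵢ)/Σwᵢ, for one category × group."""
    if not surveys:
        raise AggregationError("weighted_mean_consumption needs a non-empty survey list")
    keys = {(s.food_category, s.group) for s in surveys}
    if len(keys) > 1:
        raise AggregationError(f"surveys mix categories/groups: {sorted(map(str, keys))}")
    w = np.array([s.weight for s in surveys], dtype=float)
    m = np.array([s.mean_consumption for s in surveys], dtype=float)
    tot = w.sum()
    if tot <= 0:
        raise DomainError("total survey weight must be > 0")
    return float((w * m).sum() / tot)


@dataclass(frozen=True)
class ExposureResult:
    """Output of the exposure engine: all cells plus one summary per group."""

    cells: tuple[ExposureCell, ...]
    summaries: Mapping[Group, RiskSummary]

    def cells_frame(self) -> pd.DataFrame:
        """Cells as a tidy DataFrame (one row per compound × category × group)."""
        return pd.DataFrame(
            {
                "compound": [c.compound for c in self.cells],
                "food_category": [c.food_category.value for c in self.cells],
                "group": [c.group.value for c in self.cells],
                "mode": [c.mode.value for c in self.cells],
                "scenario": [c.scenario.value for c in self.cells],
                "ewi": [c.ewi for c in self.cells],
                "pct_twi": [c.pct_twi for c in self.cells],
            }
        )


def build_exposure_table(
    occurrence: Sequence[OccurrenceEstimate],
    rpf_table: RpfTable,
    consumption: Sequence[ConsumptionProfile],
    groups: Sequence[PopulationGroup],
    mode: Mode | str = Mode.PEQ,
    scenario: Scenario | str = Scenario.MIN,
    *,
    bound: Bound = "LB",
    twi: float = TWI_EFSA_2020,
    skip_compounds: frozenset[str] | set[str] = frozenset(),
) -> ExposureResult:
    """Combine occurrence, potency, consumption and body weight into exposure.

    Produces one :class:`ExposureCell` per compound × category × group and a
    :class:`RiskSummary` per group (category cumulatives, total EWI, hazard
    index).  In CB mode every RPF is 1 and the scenario has no effect.  Every
    occurrence compound must have an RPF or be listed in ``skip_compounds``
    (skipped compounds are dropped with a warning).  Categories without any
    occurrence record contribute a cumulative EWI of 0 (logged, not an error).

    Deterministic: identical inputs yield identical, sorted output.
    """
    mode = Mode(mode)
    scenario = Scenario(scenario)
    if twi <= 0:
        raise DomainError(f"TWI must be > 0, got {twi}")

    missing = sorted(
        {o.compound for o in occurrence if o.compound not in rpf_table and o.compound not in skip_compounds}
    )
    if missing:
        raise ConfigurationError(
            f"occurrence compounds with no RPF and no skip-list entry: {missing}"
        )
    kept = [o for o in occurrence if o.compound not in skip_compounds]
    for o in occurrence:
        if o.compound in skip_compounds:
            logger.warning("skipping compound %s (%s): in skip list", o.compound, o.food_category.value)

    cons = {(c.food_category, c.group): c.mean_consumption for c in consumption}

    # vectorized over occurrence records, one pass per group
    kept = sorted(kept, key=lambda o: (o.food_category.value, o.compound))
    conc = np.array(
        [(o.mean_lb if bound == "LB" else (o.mean_ub if o.mean_ub is not None else o.mean_lb)) for o in kept],
        dtype=float,
    )
    rpfs = (
        np.ones(len(kept))
        if mode is Mode.CB
        else np.array([resolve_rpf(rpf_table.get(o.compound), scenario) for o in kept], dtype=float)
    )

    cells: list[ExposureCell] = []
    summaries: dict[Group, RiskSummary] = {}
    for pg in sorted(groups, key=lambda g: g.name.value):
        cons_vec = np.empty(len(kept))
        for i, o in enumerate(kept):
            try:
                cons_vec[i] = cons[(o.food_category, pg.name)]
            except KeyError:
                raise ConfigurationError(
                    f"no consumption profile for {o.food_category.value} / {pg.name.value}"
                ) from None
        ewi = weekly_intake_term(conc, rpfs, cons_vec, pg.body_weight) if len(kept) else np.array([])

        group_cells = [
            ExposureCell(
                compound=o.compound,
                food_category=o.food_category,
                group=pg.name,
                mode=mode,
                scenario=scenario,
                ewi=float(e),
                pct_twi=pct_twi(float(e), twi),
            )
            for o, e in zip(kept, ewi)
        ]
        cells.extend(group_cells)

        per_cat: dict[FoodCategory, float] = {}
        for cat in FoodCategory:
            cat_cells = [c for c in group_cells if c.food_category is cat]
            if not cat_cells:
                logger.warning(
                    "no occurrence records for %s / %s: cumulative EWI is 0",
                    cat.value,
                    pg.name.value,
                )
            per_cat[cat] = math.fsum(c.ewi for c in cat_cells)
        tot = total_ewi(per_cat)
        summaries[pg.name] = RiskSummary(
            group=pg.name,
            mode=mode,
            scenario=scenario,
            per_category_cumulative=per_cat,
            total_ewi=tot,
            hazard_index=hazard_index(tot, twi),
        )
    return ExposureResult(cells=tuple(cells), summaries=summaries)
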