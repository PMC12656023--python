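"""CSV readers and writers for the engine's tabular interfaces.

All files are plain UTF-8 CSV with a header row:

- ``rpf.csv``: compound, rpf_min, rpf_max, read_across
- ``occurrence.csv``: compound, food_category, mean_lb_ng_per_kg, mean_ub_ng_per_kg (UB optional)
- ``consumption.csv``: food_category, group, mean_consumption_g_day
- ``samples.csv``: compound, food_category, value_ng_per_kg, censored, lod_ng_per_kg, loq_ng_per_kg
- ``surveys.csv``: survey_id, food_category, group, mean_consumption_g_day, weight
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import (
    ConsumptionProfile,
    FoodCategory,
    Group,
    OccurrenceEstimate,
    RpfAssignment,
    RpfTable,
)
from .occurrence import SampleRecord, SurveyConsumption

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _to_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return _BOOL[str(x).strip().lower()]


def _opt(x) -> float | None:
    return None if pd.isna(x) else float(x)


def read_rpf_csv(path: str | Path) -> RpfTable:
    df = pd.read_csv(path)
    return RpfTable(
        [
            RpfAssignment(
                compound=str(r.compound),
                rpf_min=float(r.rpf_min),
                rpf_max=float(r.rpf_max),
                read_across=_to_bool(r.read_across),
            )
            for r in df.itertuples()
        ]
    )


def read_occurrence_csv(path: str | Path) -> list[OccurrenceEstimate]:
    df = pd.read_csv(path)
    return [
        OccurrenceEstimate(
            compound=str(r.compound),
            food_category=FoodCategory(r.food_category),
            mean_lb=float(r.mean_lb_ng_per_kg),
            mean_ub=_opt(getattr(r, "mean_ub_ng_per_kg", float("nan"))),
        )
        for r in df.itertuples()
    ]


def write_occurrence_csv(estimates: Iterable[OccurrenceEstimate], path: str | Path) -> None:
    rows = [
        {
            "compound": e.compound,
            "food_category": e.food_category.value,
            "mean_lb_ng_per_kg": e.mean_lb,
            "mean_ub_ng_per_kg": "" if e.mean_ub is None else e.mean_ub,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_consumption_csv(path: str | Path) -> list[ConsumptionProfile]:
    df = pd.read_csv(path)
    return [
        ConsumptionProfile(
            food_category=FoodCategory(r.food_category),
            group=Group(r.group),
            mean_consumption=float(r.mean_consumption_g_day),
        )
        for r in df.itertuples()
    ]


def read_samples_csv(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    return [
        SampleRecord(
            compound=str(r.compound),
            food_category=FoodCategory(r.food_category),
            value=_opt(r.value_ng_per_kg),
            censored=_to_bool(r.censored),
            lod=_opt(r.lod_ng_per_kg),
            loq=_opt(r.loq_ng_per_kg),
        )
        for r in df.itertuples()
    ]


def write_samples_csv(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "compound": s.compound,
            "food_category": s.food_category.value,
            "value_ng_per_kg": "" if s.value is None else s.value,
            "censored": s.censored,
            "lod_ng_per_kg": "" if s.lod is None else s.lod,
            "loq_ng_per_kg": "" if s.loq is None else s.loq,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_surveys_csv(path: str | Path) -> list[SurveyConsumption]:
    df = pd.read_csv(path)
    return [
        SurveyConsumption(
            survey_id=str(r.survey_id),
            food_category=FoodCategory(r.food_category),
            group=Group(r.group),
            mean_consumption=float(r.mean_consumption_g_day),
            weight=float(r.weight),
        )
        for r in df.itertuples()
    ]
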