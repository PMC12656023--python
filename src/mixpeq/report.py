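"""Rounding and rendering conventions for risk reports.

All computation upstream is full floating precision; this layer formats for
display only.  Intakes and hazard indices print to two decimals, percentages
of the TWI to the nearest integer, both rounded half-away-from-zero (87.5% →
"88%").  A positive value below display precision prints as "0.00" — present
but below the second decimal, never to be read as absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .core import ExposureCell, FoodCategory, Group, Mode, RiskSummary, Scenario
from .errors import DomainError

Kind = Literal["ewi", "pct", "hi"]


@dataclass(frozen=True)
class ReportOptions:
    decimals_ewi: int = 2
    pct_as_integer: bool = True
    rounding: str = "half_away_from_zero"
    output_format: Literal["csv", "json", "text"] = "csv"

    def __post_init__(self) -> None:
        if self.decimals_ewi < 0:
            raise DomainError("decimals_ewi must be >= 0")
        if self.rounding != "half_away_from_zero":
            raise DomainError(f"unsupported rounding mode {self.rounding!r}")


_DEFAULT = ReportOptions()


def round_report(value: float, kind: Kind, options: ReportOptions = _DEFAULT) -> str:
    """Format one number for display.

    ``ewi`` and ``hi`` use ``decimals_ewi`` decimals; ``pct`` rounds to the
    nearest integer and appends '%'.  Rounding is half-away-from-zero (values
    are non-negative by contract, so ROUND_HALF_UP coincides with it).
    Idempotent: re-rounding a parsed rendered value returns the same string.
    """
    if value < 0:
        raise DomainError(f"report values must be >= 0, got {value}")
    d = Decimal(repr(float(value)))
    if kind == "pct":
        if options.pct_as_integer:
            return f"{d.quantize(Decimal(1), rounding=ROUND_HALF_UP)}%"
        return f"{d.quantize(Decimal(1).scaleb(-options.decimals_ewi), rounding=ROUND_HALF_UP)}%"
    if kind in ("ewi", "hi"):
        q = Decimal(1).scaleb(-options.decimals_ewi)
        return str(d.quantize(q, rounding=ROUND_HALF_UP))
    raise DomainError(f"unknown report kind {kind!r}")


_CUMULATIVE = "CUMULATIVE"


def _category_frame(
    cells_by_scenario: Mapping[Scenario, Sequence[ExposureCell]],
    category: FoodCategory,
    options: ReportOptions,
) -> pd.DataFrame:
    """One category's table: per-compound EWI and %TWI rows with min/max
    scenario columns, plus a cumulative row. Mirrors the published layout."""
    rows = []
    per = {
        scen: {c.compound: c for c in cells if c.food_category is category}
        for scen, cells in cells_by_scenario.items()
    }
    mn = per.get(Scenario.MIN, {})
    mx = per.get(Scenario.MAX, mn)
    mn = mn or mx
    for group in Group:
        compounds = sorted(
            {c.compound for c in mn.values() if c.group is group}
            | {c.compound for c in mx.values() if c.group is group}
        )
        g_mn = {k: v for k, v in mn.items() if v.group is group}
        g_mx = {k: v for k, v in mx.items() if v.group is group}
        for comp in compounds:
            a, b = g_mn.get(comp), g_mx.get(comp)
            rows.append(
                {
                    "group": group.value,
                    "compound": comp,
                    "ewi_min": round_report(a.ewi if a else 0.0, "ewi", options),
                    "ewi_max": round_report(b.ewi if b else 0.0, "ewi", options),
                    "pct_twi_min": round_report(a.pct_twi if a else 0.0, "pct", options),
                    "pct_twi_max": round_report(b.pct_twi if b else 0.0, "pct", options),
                }
            )
        if compounds:
            cum_mn = sum(c.ewi for c in g_mn.values())
            cum_mx = sum(c.ewi for c in g_mx.values())
            pct_mn = sum(c.pct_twi for c in g_mn.values())
            pct_mx = sum(c.pct_twi for c in g_mx.values())
            rows.append(
                {
                    "group": group.value,
                    "compound": _CUMULATIVE,
                    "ewi_min": round_report(cum_mn, "ewi", options),
                    "ewi_max": round_report(cum_mx, "ewi", options),
                    "pct_twi_min": round_report(pct_mn, "pct", options),
                    "pct_twi_max": round_report(pct_mx, "pct", options),
                }
            )
    columns = ["group", "compound", "ewi_min", "ewi_max", "pct_twi_min", "pct_twi_max"]
    return pd.DataFrame(rows, columns=columns)


def _totals_frame(
    summaries_by_scenario: Mapping[Scenario, Mapping[Group, RiskSummary]],
    options: ReportOptions,
) -> pd.DataFrame:
    mn = summaries_by_scenario.get(Scenario.MIN) or summaries_by_scenario.get(Scenario.MAX, {})
    mx = summaries_by_scenario.get(Scenario.MAX, mn)
    rows = []
    for group in Group:
        if group not in mn and group not in mx:
            continue
        a = mn.get(group) or mx[group]
        b = mx.get(group) or a
        row = {"group": group.value}
        for cat in FoodCategory:
            row[f"{cat.value}_min"] = round_report(a.per_category_cumulative.get(cat, 0.0), "ewi", options)
            row[f"{cat.value}_max"] = round_report(b.per_category_cumulative.get(cat, 0.0), "ewi", options)
        row["total_ewi_min"] = round_report(a.total_ewi, "ewi", options)
        row["total_ewi_max"] = round_report(b.total_ewi, "ewi", options)
        row["hi_min"] = round_report(a.hazard_index, "hi", options)
        row["hi_max"] = round_report(b.hazard_index, "hi", options)
        rows.append(row)
    columns = ["group"]
    for cat in FoodCategory:
        columns += [f"{cat.value}_min", f"{cat.value}_max"]
    columns += ["total_ewi_min", "total_ewi_max", "hi_min", "hi_max"]
    return pd.DataFrame(rows, columns=columns)


def render_risk_report(
    summaries_by_scenario: Mapping[Scenario, Mapping[Group, RiskSummary]],
    cells_by_scenario: Mapping[Scenario, Sequence[ExposureCell]],
    options: ReportOptions,
    out_dir: str | Path,
) -> list[Path]:
    """Write the per-category compound tables and the totals/HI block.

    Produces one file per food category plus a totals file (csv or text), or a
    single nested JSON document.  Output bytes are deterministic for fixed
    inputs and options; empty input yields header-only files.  I/O errors are
    re-raised with the offending path in the message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modes = {c.mode for cells in cells_by_scenario.values() for c in cells}
    mode_tag = modes.pop().value.lower() if len(modes) == 1 else "mixed"
    frames = {
        f"{mode_tag}_{cat.value}": _category_frame(cells_by_scenario, cat, options)
        for cat in FoodCategory
    }
    frames[f"{mode_tag}_totals"] = _totals_frame(summaries_by_scenario, options)

    written: list[Path] = []
    try:
        if options.output_format == "json":
            path = out_dir / f"{mode_tag}_report.json"
            doc = {name: df.to_dict(orient="records") for name, df in sorted(frames.items())}
            path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
            written.append(path)
        else:
            for name, df in sorted(frames.items()):
                if options.output_format == "csv":
                    path = out_dir / f"{name}.csv"
                    df.to_csv(path, index=False, lineterminator="\n")
                else:
                    path = out_dir / f"{name}.txt"
                    path.write_text(df.to_string(index=False) + "\n")
                written.append(path)
    except OSError as exc:
        raise OSError(f"failed writing risk report under {out_dir}: {exc}") from exc
    return written
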