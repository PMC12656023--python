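"""Bundled reference tables of the European PFAS dietary assessment.

Seven small CSV grids ship with the package:

- ``T1`` — mean consumption (g/day) of the four animal-derived food categories
  for toddlers, adolescents, adults and the elderly;
- ``T2`` — relative potency factors (liver-hypertrophy endpoint, PFOA = 1),
  including read-across ranges for data-poor compounds;
- ``T3``–``T6`` — per-compound PFOA-equivalent weekly intakes (LB occurrence
  scenario) with their %TWI, plus cumulative rows, for milk/dairy, meat, eggs
  and fish/seafood respectively;
- ``T7`` — per-group totals across all four categories with the hazard-index
  block.

Values are verbatim transcriptions of the published grids and are never
regenerated; a recorded SHA-256 per file guards against silent edits.  The
shipped default RPF table (``rpf.csv``) differs from ``T2`` in one entry:
PFPeA carries 0.03 (the value consistent with the published nonzero PFPeA
intakes) instead of the grid's literal 0; both are loadable.

The assessment does not publish concentrations, so
:func:`back_derived_occurrence` reconstructs group-specific mean occurrence
values by inverting the intake equation on the printed per-compound EWIs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd

from .core import (
    TWI_EFSA_2020,
    ConsumptionProfile,
    FoodCategory,
    Group,
    OccurrenceEstimate,
    PopulationGroup,
    RpfTable,
    Scenario,
    back_derive_concentration,
)
from .errors import FixtureError
from .io import read_consumption_csv, read_rpf_csv

TABLE_IDS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")

#: Food category documented by each per-category intake grid.
CATEGORY_BY_TABLE: dict[str, FoodCategory] = {
    "T3": FoodCategory.MILK_DAIRY,
    "T4": FoodCategory.MEAT,
    "T5": FoodCategory.EGGS,
    "T6": FoodCategory.FISH_SEAFOOD,
}

#: Marker rows in the intake grids.
CUMULATIVE = "CUMULATIVE"
PEQ_HI = "PEQ_HI"
CB_HI = "CB_HI"

_EXPECTED_COLUMNS = {
    "T1": ["food_category", "group", "mean_consumption_g_day"],
    "T2": ["compound", "rpf_min", "rpf_max", "read_across"],
    "T3": ["group", "compound", "ewi_min", "ewi_max", "pct_min", "pct_max"],
    "T4": ["group", "compound", "ewi_min", "ewi_max", "pct_min", "pct_max"],
    "T5": ["group", "compound", "ewi_min", "ewi_max", "pct_min", "pct_max"],
    "T6": ["group", "compound", "ewi_min", "ewi_max", "pct_min", "pct_max"],
    "T7": ["group", "compound", "ewi_min", "ewi_max"],
}


@dataclass(frozen=True)
class ReferenceTable:
    """A validated, checksummed reference grid."""

    table_id: str
    payload: pd.DataFrame


def _data_file(name: str):
    return resources.files("mixpeq").joinpath("data", name)


def _read_bytes(name: str) -> bytes:
    return _data_file(name).read_bytes()


def _checksums() -> dict[str, str]:
    return json.loads(_data_file("checksums.json").read_text())


def _verify_checksum(name: str) -> None:
    recorded = _checksums().get(name)
    actual = hashlib.sha256(_read_bytes(name)).hexdigest()
    if recorded != actual:
        raise FixtureError(
            f"reference file {name} failed its transcription checksum "
            f"(recorded {recorded}, actual {actual})"
        )


def load_reference_table(table_id: str) -> ReferenceTable:
    """Load one reference grid, verifying checksum and shape."""
    if table_id not in TABLE_IDS:
        raise FixtureError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
    name = f"table{table_id[1]}.csv"
    _verify_checksum(name)
    with resources.as_file(_data_file(name)) as path:
        df = pd.read_csv(path)
    if list(df.columns) != _EXPECTED_COLUMNS[table_id]:
        raise FixtureError(f"{name}: unexpected columns {list(df.columns)}")
    return ReferenceTable(table_id=table_id, payload=df)


def population_groups() -> list[PopulationGroup]:
    """The four consumer groups with their standard body weights."""
    return [PopulationGroup.default(g) for g in Group]


def consumption_profiles() -> list[ConsumptionProfile]:
    """The full consumption grid (T1) as typed profiles."""
    load_reference_table("T1")  # checksum + shape
    with resources.as_file(_data_file("table1.csv")) as path:
        return read_consumption_csv(path)


def rpf_assignments(source: Literal["default", "printed"] = "default") -> RpfTable:
    """The RPF table.

    ``default`` ships PFPeA = 0.03 (consistent with the published intakes);
    ``printed`` is the literal T2 grid with PFPeA = 0.
    """
    name = "rpf.csv" if source == "default" else "table2.csv"
    _verify_checksum(name)
    with resources.as_file(_data_file(name)) as path:
        return read_rpf_csv(path)


def _intake_frame(table_id: str) -> pd.DataFrame:
    if table_id not in CATEGORY_BY_TABLE:
        raise FixtureError(f"{table_id} is not a per-category intake grid")
    return load_reference_table(table_id).payload


def compound_ewis(table_id: str, group: Group | str) -> pd.DataFrame:
    """Per-compound printed EWI rows (no cumulative row) for one group."""
    df = _intake_frame(table_id)
    g = Group(group).value
    return df[(df["group"] == g) & (df["compound"] != CUMULATIVE)].reset_index(drop=True)


def cumulative_values(table_id: str, group: Group | str) -> tuple[float, float]:
    """Printed cumulative EWI (min, max) for one category grid and group."""
    df = _intake_frame(table_id)
    row = df[(df["group"] == Group(group).value) & (df["compound"] == CUMULATIVE)]
    if len(row) != 1:
        raise FixtureError(f"{table_id}: expected one cumulative row for {group}")
    return float(row["ewi_min"].iloc[0]), float(row["ewi_max"].iloc[0])


def _t7_row(group: Group | str, compound: str) -> tuple[float, float]:
    df = load_reference_table("T7").payload
    row = df[(df["group"] == Group(group).value) & (df["compound"] == compound)]
    if len(row) != 1:
        raise FixtureError(f"T7: expected one {compound} row for {group}")
    return float(row["ewi_min"].iloc[0]), float(row["ewi_max"].iloc[0])


def total_ewi_values(group: Group | str) -> tuple[float, float]:
    """Printed total EWI (min, max) across all four categories."""
    return _t7_row(group, CUMULATIVE)


def peq_hi_values(group: Group | str) -> tuple[float, float]:
    """Printed potency-weighted hazard index (min, max)."""
    return _t7_row(group, PEQ_HI)


def cb_hi_value(group: Group | str) -> float:
    """Printed concentration-based hazard index (single value)."""
    return _t7_row(group, CB_HI)[0]


def back_derived_occurrence(
    group: Group | str,
    rpf_table: RpfTable | None = None,
    scenario_for_inversion: Scenario = Scenario.MAX,
) -> list[OccurrenceEstimate]:
    """Reconstruct group-specific mean LB occurrence (ng/kg food) from the
    printed per-compound EWIs by inverting the intake equation.

    The printed grids round each compound independently, so inversion from the
    max-scenario value with ``rpf_max`` is used by default: forward
    recomputation then reproduces the printed two-decimal EWIs and hazard
    indices.  Compounds with zero potency or a printed intake of 0.00 are not
    recoverable and get concentration 0.
    """
    group = Group(group)
    rpfs = rpf_table if rpf_table is not None else rpf_assignments()
    bw = PopulationGroup.default(group).body_weight
    cons = {
        (c.food_category, c.group): c.mean_consumption for c in consumption_profiles()
    }
    out: list[OccurrenceEstimate] = []
    for table_id, category in CATEGORY_BY_TABLE.items():
        df = compound_ewis(table_id, group)
        for row in df.itertuples():
            a = rpfs.get(str(row.compound))
            if scenario_for_inversion is Scenario.MAX:
                ewi, rpf = float(row.ewi_max), a.rpf_max
            else:
                ewi, rpf = float(row.ewi_min), a.rpf_min
            if rpf <= 0 or ewi <= 0:
                conc = 0.0
            else:
                conc = back_derive_concentration(ewi, rpf, cons[(category, group)], bw)
            out.append(
                OccurrenceEstimate(compound=str(row.compound), food_category=category, mean_lb=conc)
            )
    return out


def verify_reference_tables(twi: float = TWI_EFSA_2020) -> None:
    """Self-check of the transcription: internal identities of the grids.

    Verifies, for every group: (a) the T7 total equals the sum of the four
    per-category cumulative EWIs, per scenario; (b) the T7 hazard index equals
    total/TWI rounded to two decimals; (c) the toddler milk/dairy per-compound
    intakes sum exactly to the printed cumulative; (d) the consumption grid is
    the complete 4×4 category × group matrix; (e) the index compound PFOA has
    RPF 1.  Raises :class:`FixtureError` listing every failed identity.
    """
    from .report import round_report  # local import: report depends on core only

    failures: list[str] = []
    for g in Group:
        tot = total_ewi_values(g)
        hi = peq_hi_values(g)
        cums = {tid: cumulative_values(tid, g) for tid in CATEGORY_BY_TABLE}
        for i, scen in enumerate(("min", "max")):
            s = round(math.fsum(c[i] for c in cums.values()), 2)
            if not math.isclose(s, tot[i], abs_tol=1e-9):
                failures.append(f"{g.value}/{scen}: category cumulatives sum to {s}, total prints {tot[i]}")
            hi_str = round_report(tot[i] / twi, "hi")
            if hi_str != f"{hi[i]:.2f}":
                failures.append(f"{g.value}/{scen}: HI {hi_str} != printed {hi[i]:.2f}")
    milk = compound_ewis("T3", Group.TODDLERS)
    cum = cumulative_values("T3", Group.TODDLERS)
    for col, expected in (("ewi_min", cum[0]), ("ewi_max", cum[1])):
        s = round(float(milk[col].sum()), 2)
        if not math.isclose(s, expected, abs_tol=1e-9):
            failures.append(f"toddler milk {col} rows sum to {s}, cumulative prints {expected}")
    grid = {(c.food_category, c.group) for c in consumption_profiles()}
    if len(grid) != len(FoodCategory) * len(Group):
        failures.append(f"consumption grid incomplete: {len(grid)} of 16 cells")
    for source in ("default", "printed"):
        pfoa = rpf_assignments(source).get("PFOA")
        if not (pfoa.rpf_min == pfoa.rpf_max == 1.0):
            failures.append(f"{source} RPF table: PFOA is not the unit index compound")
    if failures:
        raise FixtureError("reference-table verification failed:\n  " + "\n  ".join(failures))
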