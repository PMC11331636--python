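"""Run the design families across a scenario grid and tabulate results.

Each scenario is a null rate ``p0`` with alternative ``pa = p0 + delta``;
for every scenario all five two-stage design families are derived and their
operating characteristics collected into one long-format table (one row per
scenario x family). Infeasible cells are kept with an explicit status
instead of being dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import DesignParams, operating_characteristics
from .search import (
    AdmissibleConstraints,
    SearchConfig,
    TwoStageDesign,
    build_catalog,
)

__all__ = [
    "ScenarioGrid",
    "ComparisonTable",
    "run_scenario_grid",
    "compare_designs",
    "COLUMNS",
    "CHARACTERISTICS",
]

#: fixed column order of the long-format comparison table
COLUMNS = [
    "p0",
    "pa",
    "alpha",
    "beta",
    "design",
    "r1",
    "n1",
    "r",
    "n",
    "ratio",
    "pet_p0",
    "pet_pa",
    "alpha_d",
    "alpha_no_stop",
    "power_d",
    "en_p0",
    "en_pa",
    "status",
]

#: the six reported performance measures (sample sizes counted as one group)
CHARACTERISTICS = (
    "ratio",
    "pet_pa",
    "pet_p0",
    "alpha_no_stop",
    "power_d",
    "n",
    "en_p0",
    "en_pa",
)

FAMILIES = ("simon_optimal", "simon_minimax", "kim_optimal", "kim_minimax", "optimized")


@dataclass(frozen=True)
class ScenarioGrid:
    """A ladder of null rates sharing delta, error rates and constraints."""

    p0_values: tuple[float, ...]
    delta: float = 0.15
    alpha: float = 0.05
    beta: float = 0.2
    constraints: AdmissibleConstraints = field(default_factory=AdmissibleConstraints)

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.p0_values)
        if not values:
            raise ValueError("p0_values must be non-empty")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("p0_values must be strictly increasing")
        if any(not 0 < v for v in values) or any(v + self.delta >= 1 for v in values):
            raise ValueError(
                f"every p0 must satisfy 0 < p0 and p0 + delta < 1 (delta={self.delta})"
            )
        object.__setattr__(self, "p0_values", values)

    def scenarios(self) -> list[DesignParams]:
        return [
            DesignParams(p0=p0, pa=p0 + self.delta, alpha=self.alpha, beta=self.beta)
            for p0 in self.p0_values
        ]


@dataclass(frozen=True)
class ComparisonTable:
    """Long-format table of designs and characteristics plus run metadata."""

    data: pd.DataFrame
    metadata: Mapping[str, object]

    def to_csv(self, path) -> None:
        """Write the table with the documented fixed column order."""
        self.data.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        """Write a JSON document nested by scenario, plus metadata."""
        scenarios: dict[str, dict] = {}
        for p0, group in self.data.groupby("p0", sort=True):
            key = f"{p0:g}"
            scenarios[key] = {
                row["design"]: {
                    c: (None if pd.isna(row[c]) else row[c])
                    for c in COLUMNS
                    if c not in ("p0", "design")
                }
                for _, row in group.iterrows()
            }
        doc = {"metadata": dict(self.metadata), "scenarios": scenarios}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)


def _design_row(params: DesignParams, name: str, design, oc_or_err) -> dict:
    row = {
        "p0": params.p0,
        "pa": params.pa,
        "alpha": params.alpha,
        "beta": params.beta,
        "design": name,
    }
    if design is None:
        row.update({c: float("nan") for c in COLUMNS[5:-1]})
        row["status"] = f"infeasible:{oc_or_err.constraint}"
        return row
    oc = oc_or_err
    row.update(
        r1=design.r1,
        n1=design.n1,
        r=design.r,
        n=design.n,
        ratio=oc.ratio,
        pet_p0=oc.pet_p0,
        pet_pa=oc.pet_pa,
        alpha_d=oc.alpha_d,
        alpha_no_stop=oc.alpha_no_stop,
        power_d=oc.power_d,
        en_p0=oc.en_p0,
        en_pa=oc.en_pa,
        status="ok",
    )
    return row


def run_scenario_grid(
    grid: ScenarioGrid, config: SearchConfig = SearchConfig()
) -> ComparisonTable:
    """Derive all five design families for every scenario in the grid."""
    rows = []
    for params in grid.scenarios():
        catalog = build_catalog(params, grid.constraints, config)
        for name in FAMILIES:
            design, oc_or_err = catalog.entries[name]
            rows.append(_design_row(params, name, design, oc_or_err))
    data = pd.DataFrame(rows, columns=COLUMNS)
    metadata = {
        "delta": grid.delta,
        "alpha": grid.alpha,
        "beta": grid.beta,
        "pow_loss": grid.constraints.pow_loss,
        "pi_wrong": grid.constraints.pi_wrong,
        "ratio_lower": str(grid.constraints.ratio_lower),
        "ratio_upper": str(grid.constraints.ratio_upper),
        "pet_pa_bound_kim": grid.constraints.pet_pa_bound_kim,
        "n_max": config.n_max,
    }
    return ComparisonTable(data=data, metadata=metadata)


def recompute_row(row: Mapping[str, object]) -> dict:
    """Recompute a table row's characteristics from its stored tuple.

    Supports the round-trip invariant: every 'ok' row must reproduce
    identically from (r1, n1, r, n) and (p0, pa, alpha, beta).
    """
    design = TwoStageDesign(
        r1=int(row["r1"]), n1=int(row["n1"]), r=int(row["r"]), n=int(row["n"])
    )
    params = DesignParams(
        p0=float(row["p0"]),
        pa=float(row["pa"]),
        alpha=float(row["alpha"]),
        beta=float(row["beta"]),
    )
    oc = operating_characteristics(design, params)
    return {
        "ratio": oc.ratio,
        "pet_p0": oc.pet_p0,
        "pet_pa": oc.pet_pa,
        "alpha_d": oc.alpha_d,
        "alpha_no_stop": oc.alpha_no_stop,
        "power_d": oc.power_d,
        "en_p0": oc.en_p0,
        "en_pa": oc.en_pa,
    }


@dataclass(frozen=True)
class RankedSummary:
    """Per-scenario ranking of designs on one characteristic."""

    characteristic: str
    ranking: pd.DataFrame  # columns: p0, design, value, rank (1 = smallest)
    pairwise: Mapping[float, pd.DataFrame]  # p0 -> design x design differences


def compare_designs(table: ComparisonTable, characteristic: str) -> RankedSummary:
    """Rank the design families per scenario on one reported measure.

    Ranks ascend with the value (rank 1 = smallest); pairwise difference
    frames hold ``value[row] - value[col]``. Infeasible rows are excluded.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(
            f"unknown characteristic {characteristic!r}; "
            f"expected one of {sorted(CHARACTERISTICS)}"
        )
    ok = table.data[table.data["status"] == "ok"]
    records = []
    pairwise: dict[float, pd.DataFrame] = {}
    for p0, group in ok.groupby("p0", sort=True):
        sub = group[["design", characteristic]].reset_index(drop=True)
        sub["rank"] = sub[characteristic].rank(method="min").astype(int)
        for _, row in sub.iterrows():
            records.append(
                {
                    "p0": p0,
                    "design": row["design"],
                    "value": row[characteristic],
                    "rank": row["rank"],
                }
            )
        values = sub.set_index("design")[characteristic]
        pairwise[float(p0)] = pd.DataFrame(
            values.values[:, None] - values.values[None, :],
            index=values.index,
            columns=values.index,
        )
    ranking = pd.DataFrame(records, columns=["p0", "design", "value", "rank"])
    return RankedSummary(
        characteristic=characteristic, ranking=ranking, pairwise=pairwise
    )
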