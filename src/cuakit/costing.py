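"""Service-use costing and annual cost aggregation.

Costs are valued from a unit-cost table (€ per unit of each service item),
aggregated per participant and 6-month wave into six service categories,
and then annualised.  With four 6-month assessments (t0 retrospective at
baseline, t1–t3 at 6-month follow-ups) the annual measures are

    annual_total = (C_t0 + C_t1 + C_t2 + C_t3) / 2     (€/year over 24 months)
    annual_y1    =  C_t0 + C_t1                        (€/year, first year)
    annual_y2    =  C_t2 + C_t3                        (€/year, second year)

so annual_total == (annual_y1 + annual_y2) / 2 holds exactly.  No
discounting is applied over the 24-month horizon.  Intervention delivery
costs (staff time priced at an hourly rate) are booked to the intervention
arm's first year only.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import CATEGORIES, WAVES, TrialDataError

logger = logging.getLogger("cuakit")


class UnitCostError(ValueError):
    """Raised when service items cannot be priced."""


def load_unit_costs(path) -> pd.DataFrame:
    """Read a unit-cost CSV (category, item, unit, unit_cost_eur)."""
    table = pd.read_csv(path)
    required = {"category", "item", "unit_cost_eur"}
    missing = required - set(table.columns)
    if missing:
        raise UnitCostError(f"unit-cost table missing columns: {sorted(missing)}")
    if (table["unit_cost_eur"] <= 0).any():
        bad = table.loc[table["unit_cost_eur"] <= 0, "item"].tolist()
        raise UnitCostError(f"non-positive unit costs for items: {bad}")
    unknown = sorted(set(table["category"]) - set(CATEGORIES))
    if unknown:
        raise UnitCostError(f"unknown categories in unit-cost table: {unknown}")
    return table


def default_unit_costs() -> pd.DataFrame:
    """Editable placeholder unit-cost table shipped with the package.

    The prices are plausible mid-2010s German magnitudes for illustration
    and testing only; a real analysis must supply its own table.
    """
    with importlib.resources.files("cuakit.data").joinpath("unit_costs.csv").open() as f:
        return load_unit_costs(f)


def price_service_use(
    service_use: pd.DataFrame,
    unit_costs: pd.DataFrame,
    participants: pd.Series | None = None,
) -> pd.DataFrame:
    """Value service units into a per-participant, per-wave cost panel.

    Each row's cost is ``units × unit_cost`` for its (category, item); costs
    are summed within category and wave.  Returns a wide panel with one row
    per participant × wave, one column per category, and an exact ``total``
    column.  ``participants`` (optional) fixes the participant set so that
    zero-use participants still appear with all-zero rows.

    Raises :class:`UnitCostError` naming any (category, item) pair that has
    no price.
    """
    s = service_use.merge(
        unit_costs[["category", "item", "unit_cost_eur"]],
        on=["category", "item"],
        how="left",
    )
    unpriced = s[s["unit_cost_eur"].isna()]
    if len(unpriced):
        pairs = sorted(set(zip(unpriced["category"], unpriced["item"])))
        raise UnitCostError(f"no unit cost for service item(s): {pairs}")
    s["cost"] = s["units"] * s["unit_cost_eur"]

    if participants is None:
        participants = pd.Series(s["participant_id"].unique())
    grid = pd.MultiIndex.from_product(
        [participants, WAVES], names=["participant_id", "wave"]
    )
    wide = (
        s.pivot_table(
            index=["participant_id", "wave"],
            columns="category",
            values="cost",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(grid, fill_value=0.0)
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    wide.columns.name = None
    wide["total"] = wide[list(CATEGORIES)].sum(axis=1)
    return wide.reset_index()


def annualize(cost_panel: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the four 6-month wave totals into annual cost measures.

    Returns one row per participant with ``annual_total`` (average €/year
    over 24 months), ``annual_y1`` and ``annual_y2``.  Every participant
    must have all four waves (run LOCF first); otherwise this is an error.
    """
    counts = cost_panel.groupby("participant_id")["wave"].agg(["nunique", "size"])
    incomplete = counts.index[(counts["nunique"] != len(WAVES))].tolist()
    if incomplete:
        raise TrialDataError(
            f"participants without all four waves (run LOCF first): {incomplete}"
        )
    waves = cost_panel.pivot(index="participant_id", columns="wave", values="total")
    out = pd.DataFrame(index=waves.index)
    out["annual_y1"] = waves[0] + waves[1]
    out["annual_y2"] = waves[2] + waves[3]
    out["annual_total"] = (waves[0] + waves[1] + waves[2] + waves[3]) / 2.0
    return out.reset_index()[["participant_id", "annual_total", "annual_y1", "annual_y2"]]


# ---------------------------------------------------------------------------
# Intervention costs
# ---------------------------------------------------------------------------

@dataclass
class InterventionCostSpec:
    """Costing of the family-focused intervention itself.

    ``hourly_rate`` is the staff cost in €/h (default €102.57, the study's
    stated blended psychiatrist/psychologist rate), ``total_hours`` the
    total session time per family, and ``mean_children_per_family`` spreads
    the family-level cost over children for the child-level analysis.
    ``rounding_granularity`` optionally rounds the per-child cost to a
    reporting granularity (e.g. €50).  The cost is booked to year 1.
    """

    hourly_rate: float = 102.57
    total_hours: float = 7.0
    mean_children_per_family: float = 1.6
    rounding_granularity: float | None = 50.0
    include_in_year: int = 1


def intervention_cost_per_family(spec: InterventionCostSpec) -> float:
    """Total intervention cost per family: hourly rate × total hours."""
    if spec.hourly_rate <= 0 or spec.total_hours < 0:
        raise ValueError("hourly_rate must be positive and total_hours nonnegative")
    return spec.hourly_rate * spec.total_hours


def intervention_cost_per_child(spec: InterventionCostSpec, rounded: bool = False) -> float:
    """Per-child intervention cost: family cost / mean children per family.

    With ``rounded=True`` the result is rounded to the spec's granularity
    (e.g. €448.74 → €450 at €50 granularity).
    """
    if spec.mean_children_per_family <= 0:
        raise ValueError("mean_children_per_family must be positive")
    per_child = intervention_cost_per_family(spec) / spec.mean_children_per_family
    if rounded and spec.rounding_granularity:
        g = spec.rounding_granularity
        per_child = g * round(per_child / g)
    return per_child


def add_intervention_cost(
    annual_costs: pd.DataFrame, arm: pd.Series, per_child_cost: float
) -> pd.DataFrame:
    """Book the per-child intervention cost to intervention-arm participants.

    The cost is added to ``annual_y1`` and, at half weight, to
    ``annual_total`` (which averages two years); control participants are
    untouched.  ``arm`` maps participant_id → {TAU, INT}.
    """
    if per_child_cost < 0:
        raise ValueError("per_child_cost must be nonnegative")
    out = annual_costs.copy()
    is_int = out["participant_id"].map(arm).eq("INT").to_numpy()
    out.loc[is_int, "annual_y1"] += per_child_cost
    out.loc[is_int, "annual_total"] += per_child_cost / 2.0
    return out


def sixmonth_category_means(cost_panel: pd.DataFrame, arm: pd.Series) -> pd.DataFrame:
    """Per-arm mean (SD) 6-month costs by category and wave, report-style."""
    panel = cost_panel.copy()
    panel["arm"] = panel["participant_id"].map(arm)
    long = panel.melt(
        id_vars=["participant_id", "wave", "arm"],
        value_vars=list(CATEGORIES) + ["total"],
        var_name="category",
        value_name="cost",
    )
    return (
        long.groupby(["wave", "category", "arm"])["cost"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
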