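"""Utility mapping and QALY computation.

Health-related quality of life is measured at each wave with a child
instrument (KIDSCREEN-10 style) and mapped to a preference-based utility
index via a user-supplied additive coefficient table (intercept plus one
coefficient per item response level).  Quality-adjusted life years are the
area under the utility curve: with two assessments per year, each wave
utility represents 0.5 QALYs, so

    qaly_total = (u_t0 + u_t1 + u_t2 + u_t3) / 4     (QALY/year over 24 months)
    qaly_y1    = (u_t0 + u_t1) / 2
    qaly_y2    = (u_t2 + u_t3) / 2

The plain-mean convention above is the default; a trapezoid AUC over the
observed 18-month span is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .trial_data import WAVES, TrialDataError


class UtilityMappingError(ValueError):
    """Raised for malformed mappings or out-of-range item responses."""


@dataclass
class UtilityMapping:
    """Additive instrument-to-utility valuation.

    utility = intercept + Σ_items coefficient(item, response level),
    clamped to [u_min, u_max].  The valid response levels of each item are
    exactly those with a coefficient entry.
    """

    intercept: float
    coefficients: dict = field(default_factory=dict)  # (item, level) -> coefficient
    u_min: float = -1.0
    u_max: float = 1.0

    @property
    def items(self) -> list[str]:
        return sorted({item for item, _ in self.coefficients})

    def levels(self, item: str) -> set[int]:
        return {lvl for it, lvl in self.coefficients if it == item}


def load_utility_mapping(path, u_min: float = -1.0, u_max: float = 1.0) -> UtilityMapping:
    """Read a mapping CSV with columns item, response_level, coefficient.

    One row with ``item == "intercept"`` supplies the intercept.
    """
    table = pd.read_csv(path)
    required = {"item", "response_level", "coefficient"}
    if required - set(table.columns):
        raise UtilityMappingError(
            f"mapping table must have columns {sorted(required)}"
        )
    inter = table[table["item"] == "intercept"]
    if len(inter) != 1:
        raise UtilityMappingError("mapping table needs exactly one intercept row")
    coeffs = {
        (row["item"], int(row["response_level"])): float(row["coefficient"])
        for _, row in table[table["item"] != "intercept"].iterrows()
    }
    return UtilityMapping(
        intercept=float(inter["coefficient"].iloc[0]),
        coefficients=coeffs,
        u_min=u_min,
        u_max=u_max,
    )


def map_to_utility(responses: pd.DataFrame, mapping: UtilityMapping) -> pd.Series:
    """Map item responses (one column per mapping item) to utilities.

    Deterministic additive valuation with clamping; a response level with
    no coefficient for its item is a hard error naming the offender.
    """
    total = pd.Series(mapping.intercept, index=responses.index, dtype=float)
    for item in mapping.items:
        if item not in responses.columns:
            raise UtilityMappingError(f"responses are missing item column {item!r}")
        levels = responses[item].astype(int)
        valid = mapping.levels(item)
        bad = sorted(set(levels.unique()) - valid)
        if bad:
            raise UtilityMappingError(
                f"response level(s) {bad} out of range for item {item!r}; "
                f"valid: {sorted(valid)}"
            )
        total += levels.map(lambda lvl: mapping.coefficients[(item, lvl)])
    return total.clip(mapping.u_min, mapping.u_max)


def map_utility_table(utilities: pd.DataFrame, mapping: UtilityMapping) -> pd.DataFrame:
    """Convert an item-response utility table to the scalar-utility dialect.

    Rows with ``assessed == 0`` keep a missing utility; assessed rows are
    mapped.  Returns (participant_id, wave, utility, assessed).
    """
    out = utilities[["participant_id", "wave", "assessed"]].copy()
    out["utility"] = float("nan")
    assessed = utilities["assessed"] == 1
    out.loc[assessed, "utility"] = map_to_utility(
        utilities.loc[assessed, mapping.items], mapping
    ).to_numpy()
    return out[["participant_id", "wave", "utility", "assessed"]]


def compute_qalys(utilities: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Per-participant annual QALYs from a complete four-wave utility panel.

    ``method="mean"`` (default) treats each assessment as 0.5 QALYs; the
    yearly values are the means of the year's two wave utilities and the
    total is the mean of all four.  ``method="trapezoid"`` integrates the
    piecewise-linear utility curve over the observed 18-month span and
    annualises: (u0 + 2·u1 + 2·u2 + u3)/6.  Missing waves are an error
    (run LOCF first).
    """
    if method not in ("mean", "trapezoid"):
        raise ValueError(f"unknown QALY method {method!r}")
    counts = utilities.dropna(subset=["utility"]).groupby("participant_id")["wave"].nunique()
    incomplete = counts.index[counts != len(WAVES)].tolist()
    all_ids = utilities["participant_id"].unique()
    incomplete += [p for p in all_ids if p not in counts.index]
    if incomplete:
        raise TrialDataError(
            f"participants without utilities at all four waves (run LOCF first): "
            f"{sorted(map(str, incomplete))}"
        )
    u = utilities.pivot(index="participant_id", columns="wave", values="utility")
    out = pd.DataFrame(index=u.index)
    out["qaly_y1"] = (u[0] + u[1]) / 2.0
    out["qaly_y2"] = (u[2] + u[3]) / 2.0
    if method == "mean":
        out["qaly_total"] = (u[0] + u[1] + u[2] + u[3]) / 4.0
    else:
        out["qaly_total"] = (u[0] + 2 * u[1] + 2 * u[2] + u[3]) / 6.0
    return out.reset_index()[["participant_id", "qaly_total", "qaly_y1", "qaly_y2"]]
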