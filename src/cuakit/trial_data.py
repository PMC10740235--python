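"""Data model and preparation for long-format two-arm trial tables.

A trial is held as three tidy tables:

* ``participants`` — one row per child/adolescent with the family (cluster)
  identifier and the randomised arm.  Randomisation is at family level, so
  every member of a family is in the same arm.
* ``service_use`` — one row per (participant, wave, category, item) with the
  number of service units consumed in the 6-month recall window preceding
  the assessment.  An ``assessed`` flag distinguishes a wave that was not
  assessed (missing) from one in which no services were used (zero).
* ``utilities`` — one row per (participant, wave) with the preference-based
  utility score (or, alternatively, instrument item responses to be mapped
  to a utility downstream), again with an ``assessed`` flag.

This module validates the tables, reports missingness, applies the
baseline-complete-case filter and performs last-observation-carried-forward
(LOCF) imputation at the per-category / per-utility level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cuakit")

ARMS = ("TAU", "INT")
SEXES = ("female", "male", "other")
CATEGORIES = (
    "inpatient",
    "outpatient",
    "institutional_welfare",
    "ambulant_welfare",
    "medication",
    "school_based",
)
WAVES = (0, 1, 2, 3)
WAVE_LABELS = ("t0", "t1", "t2", "t3")
#: Length of the retrospective recall window covered by each assessment.
WAVE_WINDOW_MONTHS = 6

PARTICIPANT_COLUMNS = (
    "participant_id",
    "family_id",
    "arm",
    "age_years",
    "sex",
    "baseline_diagnosis",
)
SERVICE_USE_COLUMNS = ("participant_id", "wave", "category", "item", "units", "assessed")
UTILITY_COLUMNS = ("participant_id", "wave", "utility", "assessed")


class TrialDataError(ValueError):
    """Raised when trial tables violate the data contract."""


@dataclass
class TrialBundle:
    """The three validated trial tables, keyed consistently by participant."""

    participants: pd.DataFrame
    service_use: pd.DataFrame
    utilities: pd.DataFrame

    def copy(self) -> "TrialBundle":
        return TrialBundle(
            self.participants.copy(),
            self.service_use.copy(),
            self.utilities.copy(),
        )

    @property
    def arm_of(self) -> pd.Series:
        return self.participants.set_index("participant_id")["arm"]

    @property
    def family_of(self) -> pd.Series:
        return self.participants.set_index("participant_id")["family_id"]


@dataclass
class ExclusionReport:
    """Participants removed by the baseline-complete-case filter."""

    excluded: int
    by_arm: dict[str, int]
    participant_ids: list = field(default_factory=list)


@dataclass
class ImputationReport:
    """Participants with at least one LOCF-imputed value, per wave."""

    cost_by_wave: dict[int, int]
    utility_by_wave: dict[int, int]


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialDataError(f"{table} is missing required columns: {missing}")


def _check_enum(values: pd.Series, allowed, what: str) -> None:
    bad = sorted(set(values.dropna().unique()) - set(allowed))
    if bad:
        raise TrialDataError(f"unknown {what} value(s): {bad}; allowed: {list(allowed)}")


def validate_bundle(bundle: TrialBundle) -> TrialBundle:
    """Validate the data contract of a trial bundle; return it unchanged.

    Raises :class:`TrialDataError` on any violation: unknown enum values,
    duplicate keys, families split across arms, negative units, or service
    use / utility rows for participants absent from the participant table.
    """
    p, s, u = bundle.participants, bundle.service_use, bundle.utilities
    _require_columns(p, PARTICIPANT_COLUMNS, "participants")
    _require_columns(s, SERVICE_USE_COLUMNS, "service_use")
    utility_mode = "utility" in u.columns
    item_cols = [c for c in u.columns if c.startswith("item_")]
    if not utility_mode and not item_cols:
        raise TrialDataError(
            "utilities must carry either a 'utility' column or item_* response columns"
        )
    _require_columns(u, ("participant_id", "wave", "assessed"), "utilities")

    if p["participant_id"].duplicated().any():
        dupes = p.loc[p["participant_id"].duplicated(), "participant_id"].tolist()
        raise TrialDataError(f"duplicate participant_id values: {dupes}")
    _check_enum(p["arm"], ARMS, "arm")
    _check_enum(p["sex"], SEXES, "sex")
    if (p["age_years"] < 0).any():
        raise TrialDataError("age_years must be nonnegative")
    # family-level randomisation: family -> arm must be a function
    split = p.groupby("family_id")["arm"].nunique()
    if (split > 1).any():
        raise TrialDataError(
            f"families split across arms: {split.index[split > 1].tolist()}"
        )

    _check_enum(s["category"], CATEGORIES, "category")
    _check_enum(s["wave"], WAVES, "wave")
    _check_enum(u["wave"], WAVES, "wave")
    if (pd.to_numeric(s["units"], errors="coerce") < 0).any():
        raise TrialDataError("service units must be nonnegative")
    if not s["assessed"].isin((0, 1)).all() or not u["assessed"].isin((0, 1)).all():
        raise TrialDataError("assessed flags must be 0 or 1")

    known = set(p["participant_id"])
    for name, table in (("service_use", s), ("utilities", u)):
        unknown = sorted(set(table["participant_id"]) - known)
        if unknown:
            raise TrialDataError(
                f"{name} contains participants absent from the participant table: {unknown}"
            )
    if u.duplicated(["participant_id", "wave"]).any():
        raise TrialDataError("utilities has duplicate (participant, wave) rows")
    if utility_mode:
        bad = u[(u["assessed"] == 1) & u["utility"].isna()]
        if len(bad):
            raise TrialDataError(
                "assessed utility rows with missing utility for participants "
                f"{bad['participant_id'].tolist()}"
            )
    # within one (participant, wave, category) cell the assessed flag must be constant
    mixed = s.groupby(["participant_id", "wave", "category"])["assessed"].nunique()
    if (mixed > 1).any():
        raise TrialDataError(
            "mixed assessed flags within a (participant, wave, category) cell"
        )

    for arm in ARMS:
        n = int((p["arm"] == arm).sum())
        logger.info("validated %d participants in arm %s", n, arm)
    return bundle


def load_trial(
    participants_path: str | Path,
    service_use_path: str | Path,
    utilities_path: str | Path,
) -> TrialBundle:
    """Read and validate the three trial CSV files (UTF-8, header row)."""
    p = pd.read_csv(participants_path)
    s = pd.read_csv(service_use_path)
    u = pd.read_csv(utilities_path)
    if "baseline_diagnosis" in p.columns:
        p["baseline_diagnosis"] = p["baseline_diagnosis"].astype(bool)
    bundle = TrialBundle(p, s, u)
    validate_bundle(bundle)
    for wave in WAVES:
        n = int((u["wave"] == wave).sum())
        logger.info("utilities: %d rows at wave %d", n, wave)
    return bundle


def write_trial(bundle: TrialBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle to ``participants.csv``, ``service_use.csv`` and
    ``utilities.csv`` in ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("participants", bundle.participants),
        ("service_use", bundle.service_use),
        ("utilities", bundle.utilities),
    ):
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def _cost_cell_status(bundle: TrialBundle) -> pd.DataFrame:
    """Observedness of every (participant, wave, category) cost cell.

    A wave is assessed for costs when it has at least one ``assessed == 1``
    service-use row.  Within an assessed wave, a category with no rows is an
    observed zero; a category whose rows carry ``assessed == 0`` is missing
    (partial-wave missingness).  A wave with no assessed rows at all is
    missing for every category.

    Returns a frame indexed by (participant_id, wave, category) with a
    boolean ``observed`` column covering the full participants × 4 waves ×
    6 categories grid.
    """
    p_ids = bundle.participants["participant_id"]
    grid = pd.MultiIndex.from_product(
        [p_ids, WAVES, CATEGORIES], names=["participant_id", "wave", "category"]
    )
    s = bundle.service_use
    wave_assessed = (
        s.groupby(["participant_id", "wave"])["assessed"].max().rename("wave_assessed")
    )
    cell_flag = (
        s.groupby(["participant_id", "wave", "category"])["assessed"]
        .max()
        .rename("cell_flag")
    )
    out = pd.DataFrame(index=grid).join(wave_assessed, on=["participant_id", "wave"])
    out = out.join(cell_flag, on=["participant_id", "wave", "category"])
    wave_ok = out["wave_assessed"].fillna(0).astype(bool)
    # no rows for the cell -> inherit wave status (observed zero if assessed)
    cell = out["cell_flag"]
    out["observed"] = np.where(cell.isna(), wave_ok, cell.fillna(0).astype(bool) & wave_ok)
    return out[["observed"]]


def missingness_mask(bundle: TrialBundle) -> pd.DataFrame:
    """Per participant × wave observedness of the cost and utility groups.

    ``cost_observed`` requires every service category observed at that wave;
    ``utility_observed`` requires an assessed utility row.
    """
    cells = _cost_cell_status(bundle)
    cost_obs = cells.groupby(["participant_id", "wave"])["observed"].all()
    u = bundle.utilities
    util_obs = u.set_index(["participant_id", "wave"])["assessed"].astype(bool)
    grid = pd.MultiIndex.from_product(
        [bundle.participants["participant_id"], WAVES], names=["participant_id", "wave"]
    )
    mask = pd.DataFrame(index=grid)
    mask["cost_observed"] = cost_obs.reindex(grid, fill_value=False)
    mask["utility_observed"] = util_obs.reindex(grid, fill_value=False)
    return mask.reset_index()


# ---------------------------------------------------------------------------
# Baseline complete-case filter
# ---------------------------------------------------------------------------

def filter_baseline_complete(bundle: TrialBundle) -> tuple[TrialBundle, ExclusionReport]:
    """Drop participants missing baseline (t0) cost or utility data.

    Analysis is intention-to-treat on participants with a complete baseline;
    a participant lacking an assessed t0 service-use record (any category)
    or an assessed t0 utility is excluded.  Returns the retained bundle and
    a per-arm exclusion report.
    """
    mask = missingness_mask(bundle)
    t0 = mask[mask["wave"] == 0].set_index("participant_id")
    complete = t0["cost_observed"] & t0["utility_observed"]
    excluded_ids = complete.index[~complete].tolist()
    keep = complete.index[complete]
    if len(keep) == 0:
        raise TrialDataError("no participants with complete baseline data")

    p = bundle.participants
    arms = p.set_index("participant_id")["arm"]
    by_arm = {
        arm: int((arms.loc[excluded_ids] == arm).sum()) for arm in ARMS
    }
    report = ExclusionReport(
        excluded=len(excluded_ids), by_arm=by_arm, participant_ids=excluded_ids
    )
    keep_set = set(keep)
    retained = TrialBundle(
        p[p["participant_id"].isin(keep_set)].reset_index(drop=True),
        bundle.service_use[
            bundle.service_use["participant_id"].isin(keep_set)
        ].reset_index(drop=True),
        bundle.utilities[bundle.utilities["participant_id"].isin(keep_set)].reset_index(
            drop=True
        ),
    )
    logger.info(
        "baseline filter: excluded %d participants (%s)", report.excluded, by_arm
    )
    return retained, report


# ---------------------------------------------------------------------------
# LOCF imputation
# ---------------------------------------------------------------------------

def locf_impute(bundle: TrialBundle) -> tuple[TrialBundle, ImputationReport]:
    """Last-observation-carried-forward imputation of cost and utility data.

    Imputation is at the finest level the tables carry: each missing
    (participant, wave, category) cost cell receives a copy of that
    participant's most recent observed service-use rows for the same
    category (an observed zero carries forward as zero), and each missing
    utility receives the most recent observed utility.  Observed values are
    never altered, so the operation is idempotent.  Requires a
    baseline-complete bundle (apply :func:`filter_baseline_complete` first).

    Returns the completed bundle — where ``service_use``/``utilities`` carry
    an ``imputed`` flag and every wave is effectively assessed — plus a
    report counting participants with ≥1 imputed value per wave.
    """
    cells = _cost_cell_status(bundle).reset_index()
    u = bundle.utilities
    t0_missing_cost = cells[(cells["wave"] == 0) & ~cells["observed"]]
    t0_util = u[u["wave"] == 0]
    t0_missing_util = set(bundle.participants["participant_id"]) - set(
        t0_util.loc[t0_util["assessed"] == 1, "participant_id"]
    )
    if len(t0_missing_cost) or t0_missing_util:
        raise TrialDataError(
            "LOCF requires complete baseline data; run filter_baseline_complete first"
        )

    # --- costs: copy forward the last observed wave's rows per category ----
    obs = cells[cells["observed"]]
    # for each missing cell, the source wave is the latest observed wave before it
    merged = cells.merge(
        obs.rename(columns={"wave": "src_wave"})[
            ["participant_id", "category", "src_wave"]
        ],
        on=["participant_id", "category"],
    )
    merged = merged[(~merged["observed"]) & (merged["src_wave"] < merged["wave"])]
    src = (
        merged.groupby(["participant_id", "wave", "category"])["src_wave"]
        .max()
        .reset_index()
    )

    s = bundle.service_use
    observed_rows = s[s["assessed"] == 1].copy()
    if "imputed" not in observed_rows.columns:
        observed_rows["imputed"] = False
    donor = observed_rows.rename(columns={"wave": "src_wave"})
    imputed_rows = src.merge(donor, on=["participant_id", "src_wave", "category"])
    imputed_rows = imputed_rows.drop(columns=["src_wave"])
    imputed_rows["imputed"] = True
    completed_s = pd.concat(
        [observed_rows, imputed_rows[observed_rows.columns]], ignore_index=True
    )
    completed_s["assessed"] = 1
    completed_s = completed_s.sort_values(
        ["participant_id", "wave", "category", "item"]
    ).reset_index(drop=True)

    # --- utilities: ffill within participant -------------------------------
    grid = pd.MultiIndex.from_product(
        [bundle.participants["participant_id"], WAVES], names=["participant_id", "wave"]
    )
    uu = (
        u[u["assessed"] == 1]
        .set_index(["participant_id", "wave"])["utility"]
        .reindex(grid)
        .reset_index()
    )
    uu["imputed"] = uu["utility"].isna()
    if "imputed" in u.columns:
        prior = (
            u.set_index(["participant_id", "wave"])["imputed"]
            .reindex(grid)
            .fillna(False)
            .astype(bool)
        )
        uu["imputed"] = uu["imputed"].to_numpy() | prior.to_numpy()
    uu["utility"] = uu.groupby("participant_id")["utility"].ffill()
    uu["assessed"] = 1
    completed_u = uu[["participant_id", "wave", "utility", "assessed", "imputed"]]

    cost_by_wave = {
        int(w): int(src.loc[src["wave"] == w, "participant_id"].nunique()) for w in WAVES
    }
    utility_by_wave = {
        int(w): int(uu.loc[(uu["wave"] == w) & uu["imputed"], "participant_id"].nunique())
        for w in WAVES
    }
    report = ImputationReport(cost_by_wave=cost_by_wave, utility_by_wave=utility_by_wave)
    logger.info("LOCF: cost imputations per wave %s", cost_by_wave)
    return TrialBundle(bundle.participants.copy(), completed_s, completed_u), report
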