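"""Synthetic family-clustered two-arm trials with known ground truth.

The study data behind this kind of economic evaluation are typically not
shareable, so every stage of the pipeline is exercised on generated trials
that reproduce the *statistical structure* the analysis assumes:

* children nested in families (1 or 2 children, mean ≈ 1.6/family), two
  arms randomised at family level (~105 families each);
* four assessment waves 6 months apart, each covering the preceding
  6 months;
* heavily right-skewed 6-month service costs with a point mass at zero,
  generated per category by a two-part model (Bernoulli use × lognormal
  positive part) whose parameters are solved from target marginal mean/SD;
* utilities near 0.76 with SD 0.07, bounded;
* within-family correlation (Gaussian-copula ICC on the latent scale) for
  both costs and utilities;
* missing assessments at follow-up waves and a small set of
  baseline-incomplete participants, with the planted missing sets recorded
  for ground-truth tests.

True intervention effects (an annual cost shift and a per-wave utility
shift) are injected additively for the intervention arm and stored
alongside every generated trial so recovery can be tested.

Clinical content (symptom trajectories, the intervention mechanism) is not
simulated — only the structure the economic analysis consumes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .inference import DEFAULT_SEED
from .trial_data import CATEGORIES, WAVES, TrialBundle, write_trial

logger = logging.getLogger("cuakit")


@dataclass
class CategorySpec:
    """Two-part marginal model for one service category's 6-month cost."""

    name: str
    mean: float  # target marginal mean, € per 6 months
    sd: float  # target marginal SD
    p_use: float  # probability of any use in a 6-month window

    def positive_part(self) -> tuple[float, float]:
        """(mu, sigma) of the lognormal positive part matching the moments."""
        if self.mean < 0 or self.sd < 0 or not (0 < self.p_use <= 1):
            raise ValueError(f"infeasible category spec: {self}")
        if self.mean == 0:
            return 0.0, 0.0
        e_pos = self.mean / self.p_use
        e2 = (self.sd**2 + self.mean**2) / self.p_use
        var_pos = e2 - e_pos**2
        if var_pos < -1e-9 * e_pos**2:
            raise ValueError(
                f"infeasible moments for {self.name}: need "
                f"p_use >= mean^2/(sd^2+mean^2) = "
                f"{self.mean**2 / (self.sd**2 + self.mean**2):.3f}"
            )
        # var_pos == 0 (e.g. sd=0 with p_use=1) degenerates to a constant
        sigma2 = np.log1p(max(var_pos, 0.0) / e_pos**2)
        mu = np.log(e_pos) - sigma2 / 2.0
        return float(mu), float(np.sqrt(sigma2))


#: Default category targets: 6-month means/SDs of the six service categories
#: in the study population (inpatient, outpatient, institutional welfare,
#: ambulant welfare, medication, school-based), with use probabilities
#: chosen so the zero mass matches the SD ≫ mean regime.
DEFAULT_CATEGORIES = (
    CategorySpec("inpatient", 791.57, 3808.48, 0.06),
    CategorySpec("outpatient", 206.06, 579.93, 0.35),
    CategorySpec("institutional_welfare", 224.45, 1862.13, 0.05),
    CategorySpec("ambulant_welfare", 131.10, 529.56, 0.12),
    CategorySpec("medication", 19.89, 157.56, 0.15),
    CategorySpec("school_based", 518.18, 2306.12, 0.18),
)

#: Follow-up missingness calibrated to 96/172/170 missing of 327 at t1–t3.
DEFAULT_P_MISSING_WAVE = (96 / 327, 172 / 327, 170 / 327)


@dataclass
class SyntheticTrialConfig:
    """Study-condition parameters of the generator (defaults = the trial)."""

    n_families_per_arm: int = 105
    p_two_children: float = 0.6  # mean children/family = 1 + p = 1.6
    categories: tuple = DEFAULT_CATEGORIES
    icc_cost: float = 0.3  # latent-scale intraclass (family) correlation
    icc_utility: float = 0.3
    # latent-scale wave-to-wave correlation within a child (persistence of
    # service use / quality of life); must be >= the family ICC
    cost_wave_corr: float = 0.6
    utility_wave_corr: float = 0.8
    utility_mean: float = 0.76
    utility_sd: float = 0.07
    u_min: float = 0.0
    u_max: float = 1.0
    delta_cost_per_year: float = 0.0  # true INT−TAU annual cost effect, €
    delta_qaly: float = 0.0  # true INT−TAU per-wave utility shift
    p_missing_wave: tuple = DEFAULT_P_MISSING_WAVE  # t1..t3, MCAR
    p_missing_baseline: float = 0.03
    missing_cost_gradient: float = 0.0  # MNAR knob: logit shift per SD of cost
    item_level: bool = False  # emit two priced items per category
    dropout: bool = True
    seed: int = DEFAULT_SEED


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery and planted-set tests."""

    delta_cost_per_year: float
    delta_qaly: float
    seed: int
    n_families: int
    n_children: int
    planted_baseline_missing: dict = field(default_factory=dict)  # id -> group
    planted_wave_missing: dict = field(default_factory=dict)  # wave -> [ids]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


ITEM_SPLIT = (("item_a", 0.6, 50.0), ("item_b", 0.4, 20.0))  # name, cost share, € price


def unit_cost_table_for(config: SyntheticTrialConfig) -> pd.DataFrame:
    """The unit-cost table matching the generator's emitted service items."""
    rows = []
    if config.item_level:
        for cat in CATEGORIES:
            for item, _, price in ITEM_SPLIT:
                rows.append((cat, item, "unit", price))
    else:
        for cat in CATEGORIES:
            rows.append((cat, "direct_cost", "eur", 1.0))
    return pd.DataFrame(rows, columns=["category", "item", "unit", "unit_cost_eur"])


def _correlated_normal(
    rng, fam_codes: np.ndarray, n_waves: int, icc: float, wave_corr: float
) -> np.ndarray:
    """Std-normal (n_children, n_waves) draws with a three-level structure.

    Marginals are N(0,1); correlation is ``icc`` between children of one
    family and ``wave_corr`` between waves of one child (so persistence of
    a child's service use / quality of life is reproduced).  Requires
    icc <= wave_corr <= 1.
    """
    if not (0 <= icc <= wave_corr <= 1):
        raise ValueError("need 0 <= icc <= wave_corr <= 1")
    n = len(fam_codes)
    n_fam = fam_codes.max() + 1
    z_fam = rng.standard_normal(n_fam)[fam_codes]
    z_child = rng.standard_normal(n)
    z_wave = rng.standard_normal((n, n_waves))
    return (
        np.sqrt(icc) * z_fam[:, None]
        + np.sqrt(wave_corr - icc) * z_child[:, None]
        + np.sqrt(1 - wave_corr) * z_wave
    )


def generate_trial(config: SyntheticTrialConfig) -> tuple[TrialBundle, GroundTruth]:
    """Generate a complete trial bundle plus its ground-truth record.

    Reproducible under ``config.seed``.  Dropout is applied unless
    ``config.dropout`` is false.
    """
    rng = np.random.default_rng(config.seed)
    n_fam = 2 * config.n_families_per_arm
    fam_arm = np.array(
        ["TAU"] * config.n_families_per_arm + ["INT"] * config.n_families_per_arm
    )
    rng.shuffle(fam_arm)
    kids_per_fam = 1 + (rng.random(n_fam) < config.p_two_children).astype(int)
    fam_codes = np.repeat(np.arange(n_fam), kids_per_fam)
    n = len(fam_codes)
    is_int = (fam_arm[fam_codes] == "INT").astype(float)

    pid = np.array([f"P{i:04d}" for i in range(n)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "family_id": [f"F{c:04d}" for c in fam_codes],
            "arm": fam_arm[fam_codes],
            "age_years": np.round(rng.uniform(3, 19, size=n), 1),
            "sex": rng.choice(["female", "male"], size=n),
            "baseline_diagnosis": rng.random(n) < 0.535,
        }
    )

    # ---- costs: two-part model per category --------------------------------
    n_waves = len(WAVES)
    costs = np.zeros((n, n_waves, len(CATEGORIES)))
    for j, spec in enumerate(config.categories):
        if spec.mean == 0:
            continue
        mu, sigma = spec.positive_part()
        z_use = _correlated_normal(
            rng, fam_codes, n_waves, config.icc_cost, config.cost_wave_corr
        )
        z_amt = _correlated_normal(
            rng, fam_codes, n_waves, config.icc_cost, config.cost_wave_corr
        )
        use = stats.norm.cdf(z_use) < spec.p_use
        costs[:, :, j] = use * np.exp(mu + sigma * z_amt)

    # true annual cost effect: +Δ/2 per wave on the outpatient category (the
    # annual measures sum two waves, so the annual contrast is exactly Δ)
    if config.delta_cost_per_year != 0.0:
        j_out = CATEGORIES.index("outpatient")
        shifted = costs[:, :, j_out] + is_int[:, None] * config.delta_cost_per_year / 2.0
        if (shifted < 0).any():
            logger.warning(
                "negative cost effect clipped at zero for %d cells; the realised "
                "effect is attenuated",
                int((shifted < 0).sum()),
            )
        costs[:, :, j_out] = np.maximum(shifted, 0.0)

    # ---- utilities ---------------------------------------------------------
    z_u = _correlated_normal(
        rng, fam_codes, n_waves, config.icc_utility, config.utility_wave_corr
    )
    utility = config.utility_mean + config.utility_sd * z_u
    utility += is_int[:, None] * config.delta_qaly
    utility = np.clip(utility, config.u_min, config.u_max)

    # ---- assessment status -------------------------------------------------
    cost_assessed = np.ones((n, n_waves), dtype=bool)
    util_assessed = np.ones((n, n_waves), dtype=bool)
    planted_baseline: dict[str, str] = {}
    base_missing = rng.random(n) < config.p_missing_baseline
    kinds = rng.choice(["cost", "utility", "both"], size=n, p=[0.4, 0.4, 0.2])
    for i in np.flatnonzero(base_missing):
        kind = kinds[i]
        planted_baseline[pid[i]] = kind
        if kind in ("cost", "both"):
            cost_assessed[i, 0] = False
        if kind in ("utility", "both"):
            util_assessed[i, 0] = False

    truth = GroundTruth(
        delta_cost_per_year=config.delta_cost_per_year,
        delta_qaly=config.delta_qaly,
        seed=config.seed,
        n_families=n_fam,
        n_children=n,
        planted_baseline_missing=planted_baseline,
        config={
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name != "categories"
        },
    )

    bundle = _emit_bundle(config, participants, costs, utility, cost_assessed, util_assessed)
    if config.dropout:
        dropout_seed = int(rng.integers(2**31))
        bundle, planted = induce_dropout(
            bundle,
            config.p_missing_wave,
            seed=dropout_seed,
            missing_cost_gradient=config.missing_cost_gradient,
        )
        truth.planted_wave_missing = planted
    return bundle, truth


def _emit_bundle(config, participants, costs, utility, cost_assessed, util_assessed):
    """Materialise arrays as the long-format CSV dialect of the data model."""
    n, n_waves, n_cat = costs.shape
    pid = participants["participant_id"].to_numpy()
    i_idx, w_idx, c_idx = np.meshgrid(
        np.arange(n), np.arange(n_waves), np.arange(n_cat), indexing="ij"
    )
    keep = cost_assessed[i_idx.ravel(), w_idx.ravel()]
    base = pd.DataFrame(
        {
            "participant_id": pid[i_idx.ravel()[keep]],
            "wave": w_idx.ravel()[keep],
            "category": np.asarray(CATEGORIES)[c_idx.ravel()[keep]],
            "cost": costs.ravel()[keep],
        }
    )
    if config.item_level:
        parts = []
        for item, share, price in ITEM_SPLIT:
            part = base.copy()
            part["item"] = item
            part["units"] = part["cost"] * share / price
            parts.append(part)
        service = pd.concat(parts, ignore_index=True)
    else:
        service = base.copy()
        service["item"] = "direct_cost"
        service["units"] = service["cost"]
    service["assessed"] = 1
    service = service.drop(columns="cost").sort_values(
        ["participant_id", "wave", "category", "item"]
    )[["participant_id", "wave", "category", "item", "units", "assessed"]].reset_index(
        drop=True
    )

    ii, ww = np.meshgrid(np.arange(n), np.arange(n_waves), indexing="ij")
    utilities = pd.DataFrame(
        {
            "participant_id": pid[ii.ravel()],
            "wave": ww.ravel(),
            "utility": np.where(util_assessed.ravel(), utility.ravel(), np.nan),
            "assessed": util_assessed.ravel().astype(int),
        }
    ).sort_values(["participant_id", "wave"]).reset_index(drop=True)
    utilities["utility"] = utilities["utility"].round(6)

    return TrialBundle(participants, service, utilities)


def induce_dropout(
    bundle: TrialBundle,
    p_missing_wave=DEFAULT_P_MISSING_WAVE,
    seed: int = DEFAULT_SEED,
    missing_cost_gradient: float = 0.0,
) -> tuple[TrialBundle, dict]:
    """Blank out follow-up assessments wave by wave (missing completely at
    random by default).

    Each participant's wave t1..t3 is unassessed (both cost and utility)
    with the configured marginal probability, independently across waves —
    the marginals, not a monotone dropout pattern, are the calibrated
    quantity.  ``missing_cost_gradient`` > 0 makes missingness depend on
    the participant's baseline total cost (a missing-not-at-random knob for
    robustness experiments; 0 keeps MCAR).

    Returns the bundle with missingness applied plus the planted missing
    set {wave: [participant ids]}.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(p_missing_wave, dtype=float)
    if len(p) != 3 or ((p < 0) | (p > 1)).any():
        raise ValueError("p_missing_wave must be three probabilities for waves 1..3")
    pid = bundle.participants["participant_id"].to_numpy()
    n = len(pid)

    if missing_cost_gradient != 0.0:
        s = bundle.service_use
        base_cost = (
            s[s["wave"] == 0]
            .groupby("participant_id")["units"]
            .sum()
            .reindex(pid, fill_value=0.0)
            .to_numpy()
        )
        from scipy.special import expit, logit

        z = (base_cost - base_cost.mean()) / (base_cost.std() or 1.0)
        probs = expit(
            logit(np.clip(p, 1e-6, 1 - 1e-6))[None, :]
            + missing_cost_gradient * z[:, None]
        )
    else:
        probs = np.broadcast_to(p, (n, 3))

    miss = rng.random((n, 3)) < probs
    planted = {int(w): pid[miss[:, w - 1]].tolist() for w in (1, 2, 3)}

    drop_pairs = {
        (pid_i, w) for w in (1, 2, 3) for pid_i in planted[w]
    }
    s = bundle.service_use
    keep_mask = ~pd.MultiIndex.from_arrays([s["participant_id"], s["wave"]]).isin(drop_pairs)
    service = s[keep_mask].reset_index(drop=True)

    u = bundle.utilities.copy()
    u_drop = pd.MultiIndex.from_arrays([u["participant_id"], u["wave"]]).isin(drop_pairs)
    u.loc[u_drop, "utility"] = np.nan
    u.loc[u_drop, "assessed"] = 0

    return TrialBundle(bundle.participants.copy(), service, u), planted


def write_synthetic_trial(
    bundle: TrialBundle, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write the trial CSVs plus ``ground_truth.json`` to a directory."""
    paths = write_trial(bundle, directory)
    gt_path = Path(directory) / "ground_truth.json"
    truth.to_json(gt_path)
    paths["ground_truth"] = gt_path
    return paths
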