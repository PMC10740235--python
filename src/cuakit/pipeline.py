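"""One-command orchestration of the full cost-utility analysis.

Stage order follows the analysis chain: load (or generate) the trial →
baseline-complete-case filter → LOCF imputation → service-use costing and
annualisation (+ intervention cost booking) → QALY computation →
cluster-robust incremental estimates with bootstrap CIs (+ gamma-GLM
sensitivity fits for costs) → ICUR / bootstrap cloud / CEAC / NMB curves.

Every run writes a ``manifest.json`` recording the complete configuration,
seeds and package version, so a run can be reproduced bit-for-bit from the
manifest alone, plus a ``run.log``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cea, costing, inference, outcomes, synthetic, trial_data

logger = logging.getLogger("cuakit")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either ``input_dir`` (a directory with participants/service_use/
    utilities CSVs) or ``synthetic`` (a generator configuration) supplies
    the trial.  ``B_ci`` bootstrap replications feed the incremental-
    estimate CIs, ``B_cloud`` the ICUR cloud.  The willingness-to-pay grid
    runs 0 … ``lambda_max`` in ``lambda_step`` increments.
    """

    input_dir: str | None = None
    synthetic: synthetic.SyntheticTrialConfig | None = None
    unit_costs_path: str | None = None
    utility_mapping_path: str | None = None
    intervention: costing.InterventionCostSpec = field(
        default_factory=costing.InterventionCostSpec
    )
    apply_intervention_cost: bool = True
    use_rounded_intervention_cost: bool = True
    B_ci: int = 2000
    B_cloud: int = 10_000
    lambda_max: float = 125_000.0
    lambda_step: float = 1000.0
    glm_sensitivity: bool = True
    qaly_method: str = "mean"
    seed: int = inference.DEFAULT_SEED
    out_dir: str = "cuakit_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "categories" in syn:
                syn["categories"] = tuple(
                    synthetic.CategorySpec(**c) for c in syn["categories"]
                )
            raw["synthetic"] = synthetic.SyntheticTrialConfig(**syn)
        if "intervention" in raw and raw["intervention"] is not None:
            raw["intervention"] = costing.InterventionCostSpec(**raw["intervention"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.arange(0.0, self.lambda_max + self.lambda_step / 2, self.lambda_step)


@dataclass
class RunResult:
    out_dir: Path
    paths: dict[str, Path]
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage {name!r} failed: {err}") from err

        return inner

    return wrap


OUTCOME_COLUMNS = {
    "cost_total": ("annual", "annual_total"),
    "cost_y1": ("annual", "annual_y1"),
    "cost_y2": ("annual", "annual_y2"),
    "qaly_total": ("qaly", "qaly_total"),
    "qaly_y1": ("qaly", "qaly_y1"),
    "qaly_y2": ("qaly", "qaly_y2"),
}


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all result files.

    Produces ``annual_costs.csv``, ``sixmonth_costs.csv``, ``qalys.csv``,
    ``incremental_estimates.csv``, ``icur.json``, ``ceac.csv``, ``nmb.csv``,
    ``cloud.csv`` and ``manifest.json`` in ``config.out_dir``.  Any stage
    error is re-raised as :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, out: Path) -> RunResult:
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in ("ci", "cloud")}

    # ---- trial data --------------------------------------------------------
    @_stage("trial_data")
    def load():
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.synthetic.seed)
            bundle, truth = synthetic.generate_trial(syn)
            unit_costs = synthetic.unit_cost_table_for(syn)
            return bundle, truth, unit_costs
        if config.input_dir is None:
            raise ValueError("config needs input_dir or a synthetic block")
        d = Path(config.input_dir)
        bundle = trial_data.load_trial(
            d / "participants.csv", d / "service_use.csv", d / "utilities.csv"
        )
        if config.unit_costs_path:
            unit_costs = costing.load_unit_costs(config.unit_costs_path)
        else:
            unit_costs = costing.default_unit_costs()
        return bundle, None, unit_costs

    bundle, truth, unit_costs = load()

    @_stage("trial_data")
    def prepare(bundle):
        if "utility" not in bundle.utilities.columns:
            if not config.utility_mapping_path:
                raise ValueError(
                    "utilities carry item responses but no utility_mapping_path is set"
                )
            mapping = outcomes.load_utility_mapping(config.utility_mapping_path)
            bundle = trial_data.TrialBundle(
                bundle.participants,
                bundle.service_use,
                outcomes.map_utility_table(bundle.utilities, mapping),
            )
        bundle, exclusions = trial_data.filter_baseline_complete(bundle)
        bundle, imputation = trial_data.locf_impute(bundle)
        return bundle, exclusions, imputation

    bundle, exclusions, imputation = prepare(bundle)
    arm = bundle.arm_of
    fam = bundle.family_of

    # ---- costing -----------------------------------------------------------
    @_stage("costing")
    def cost_stage():
        panel = costing.price_service_use(
            bundle.service_use, unit_costs, participants=bundle.participants["participant_id"]
        )
        annual = costing.annualize(panel)
        per_child = 0.0
        if config.apply_intervention_cost:
            per_child = costing.intervention_cost_per_child(
                config.intervention, rounded=config.use_rounded_intervention_cost
            )
            annual = costing.add_intervention_cost(annual, arm, per_child)
        return panel, annual, per_child

    panel, annual, per_child_cost = cost_stage()

    # ---- outcomes ----------------------------------------------------------
    @_stage("outcomes")
    def qaly_stage():
        return outcomes.compute_qalys(bundle.utilities, method=config.qaly_method)

    qaly = qaly_stage()

    merged = annual.merge(qaly, on="participant_id")
    merged["arm"] = merged["participant_id"].map(arm)
    merged["family_id"] = merged["participant_id"].map(fam)
    arm_v = merged["arm"].to_numpy()
    fam_v = merged["family_id"].to_numpy()

    # ---- inference ---------------------------------------------------------
    @_stage("inference")
    def inference_stage():
        estimates = []
        tables = {"annual": merged, "qaly": merged}
        for i, (name, (tab, col)) in enumerate(OUTCOME_COLUMNS.items()):
            y = tables[tab][col].to_numpy()
            est = inference.estimate_difference_ols(y, arm_v, fam_v, outcome=name)
            boot = inference.bootstrap_ci(
                y, arm_v, fam_v, B=config.B_ci, seed=seeds["ci"] + i
            )
            est.extra.update(
                {
                    "boot_ci_low": boot.ci_low,
                    "boot_ci_high": boot.ci_high,
                    "B": boot.B,
                    "boot_seed": boot.seed,
                }
            )
            estimates.append(est)
            if config.glm_sensitivity and name.startswith("cost"):
                estimates.append(
                    inference.estimate_difference_glm(y, arm_v, fam_v, outcome=name)
                )
        return estimates

    estimates = inference_stage()

    # ---- cea ---------------------------------------------------------------
    @_stage("cea")
    def cea_stage():
        grid = config.lambda_grid
        points = {}
        for span, ckey, qkey in (
            ("year1plus2", "cost_total", "qaly_total"),
            ("year1", "cost_y1", "qaly_y1"),
            ("year2", "cost_y2", "qaly_y2"),
        ):
            dc = next(e for e in estimates if e.outcome == ckey and e.method == "ols_robust")
            dq = next(e for e in estimates if e.outcome == qkey and e.method == "ols_robust")
            points[span] = cea.icur_point(dc.delta, dq.delta)
        cloud = cea.bootstrap_cloud(
            merged["annual_total"].to_numpy(),
            merged["qaly_total"].to_numpy(),
            arm_v,
            fam_v,
            B=config.B_cloud,
            seed=seeds["cloud"],
        )
        ceac_curve = cea.ceac(cloud, grid)
        nmb_curve = cea.nmb_regression(
            merged["annual_total"].to_numpy(),
            merged["qaly_total"].to_numpy(),
            arm_v,
            fam_v,
            lambdas=grid,
        )
        return points, cloud, ceac_curve, nmb_curve

    points, cloud, ceac_curve, nmb_curve = cea_stage()

    # ---- outputs -----------------------------------------------------------
    paths: dict[str, Path] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path

    save(annual, "annual_costs.csv")
    save(panel, "sixmonth_costs.csv")
    save(qaly, "qalys.csv")
    save(inference.estimates_to_frame(estimates), "incremental_estimates.csv")
    save(ceac_curve, "ceac.csv")
    save(nmb_curve.table, "nmb.csv")
    save(cloud.to_frame(), "cloud.csv")

    icur_payload = {
        span: {
            "delta_cost": r.delta_cost,
            "delta_qaly": r.delta_qaly,
            "icur_eur_per_qaly": r.icur if r.defined else None,
            "icur_eur_per_milli_qaly": r.icur_per_milli_qaly if r.defined else None,
            "quadrant": r.quadrant,
            "defined": r.defined,
        }
        for span, r in points.items()
    }
    icur_payload["quadrant_shares"] = cloud.quadrant_shares
    icur_payload["B_cloud"] = cloud.B
    (out / "icur.json").write_text(json.dumps(icur_payload, indent=2))
    paths["icur.json"] = out / "icur.json"

    manifest = {
        "package": "cuakit",
        "version": _pkg_version("cuakit"),
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_participants": int(len(merged)),
        "n_families": int(merged["family_id"].nunique()),
        "n_by_arm": merged["arm"].value_counts().to_dict(),
        "exclusions": dataclasses.asdict(exclusions),
        "locf_imputation": dataclasses.asdict(imputation),
        "intervention_cost_per_child": per_child_cost,
        "outputs": sorted(paths),
    }
    if truth is not None:
        manifest["synthetic_ground_truth"] = {
            "delta_cost_per_year": truth.delta_cost_per_year,
            "delta_qaly": truth.delta_qaly,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest.json"] = out / "manifest.json"
    logger.info("pipeline complete: %d outputs in %s", len(paths), out)
    return RunResult(out_dir=out, paths=paths, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
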