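"""Decision-analytic layer: ICUR, cost-effectiveness plane, CEAC and NMB.

The incremental cost-utility ratio (ICUR) is ∆cost/∆QALY between the
intervention and control arms.  Its sampling uncertainty is summarised by
a cluster-bootstrap cloud of (∆cost, ∆QALY) pairs on the cost-effectiveness
plane; from the cloud follow the quadrant shares, the cost-effectiveness
acceptability curve (CEAC: the fraction of replicates with positive
incremental net benefit λ·∆E − ∆C at each willingness-to-pay λ), and the
net-monetary-benefit (NMB) regression curve λ·∆Ê − ∆Ĉ with cluster-robust
95% confidence bands.

Because the study reports ICURs on two scales, both are always computed:
€ per QALY and € per 0.001 QALY (the €/QALY value divided by 1000).

Tie rules are deterministic: a replicate with net benefit exactly 0 counts
as not cost-effective; quadrant boundaries go to the positive-∆E side, and
∆C = 0 to the cost-saving side (so ∆C=0, ∆E>0 is SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    DEFAULT_SEED,
    InferenceError,
    _as_arrays,
    _design,
    cluster_bootstrap_deltas,
    cluster_robust_cov,
)
from scipy import stats

QUADRANTS = ("NE", "SE", "SW", "NW")

#: Default willingness-to-pay grid: €0 to €125,000 in €1,000 steps.
DEFAULT_LAMBDA_GRID = tuple(range(0, 125_001, 1000))


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly >= 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


@dataclass
class ICURResult:
    """A point on the cost-effectiveness plane with its ratio."""

    delta_cost: float
    delta_qaly: float
    icur: float  # €/QALY; nan when undefined
    icur_per_milli_qaly: float  # €/(0.001 QALY)
    quadrant: str
    defined: bool


def icur_point(delta_cost: float, delta_qaly: float) -> ICURResult:
    """ICUR point estimate with quadrant label and per-milli-QALY rescaling.

    ∆QALY = 0 yields an undefined-ratio flag rather than a division.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("delta_cost and delta_qaly must be finite")
    if delta_qaly == 0:
        icur = float("nan")
        defined = False
    else:
        icur = delta_cost / delta_qaly
        defined = True
    return ICURResult(
        delta_cost=float(delta_cost),
        delta_qaly=float(delta_qaly),
        icur=icur,
        icur_per_milli_qaly=icur / 1000.0,
        quadrant=_quadrant(delta_cost, delta_qaly),
        defined=defined,
    )


@dataclass
class BootstrapCloud:
    """Joint bootstrap distribution of (∆cost, ∆QALY) at family resolution."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    B: int
    seed: int
    n_discarded: int = 0

    @property
    def quadrant_shares(self) -> dict[str, float]:
        dc, de = self.delta_costs, self.delta_qalys
        n = len(dc)
        east = de >= 0
        shares = {
            "NE": float(((dc > 0) & east).sum() / n),
            "SE": float(((dc <= 0) & east).sum() / n),
            "SW": float(((dc <= 0) & ~east).sum() / n),
            "NW": float(((dc > 0) & ~east).sum() / n),
        }
        return shares

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.delta_costs)),
                "delta_cost": self.delta_costs,
                "delta_qaly": self.delta_qalys,
            }
        )


def bootstrap_cloud(
    cost, qaly, arm, clusters, B: int = 10_000, seed: int = DEFAULT_SEED
) -> BootstrapCloud:
    """Family-bootstrap cloud of (∆cost, ∆QALY) on the CE plane.

    Both deltas are recomputed on the same family resample per replicate,
    preserving their joint (within-person, within-family) dependence.
    """
    if B < 100:
        raise InferenceError("bootstrap needs B >= 100 replications")
    Y = np.column_stack([np.asarray(cost, dtype=float), np.asarray(qaly, dtype=float)])
    deltas, n_discarded = cluster_bootstrap_deltas(Y, arm, clusters, B=B, seed=seed)
    return BootstrapCloud(
        delta_costs=deltas[:, 0],
        delta_qalys=deltas[:, 1],
        B=B,
        seed=seed,
        n_discarded=n_discarded,
    )


def ceac(cloud: BootstrapCloud, lambdas=DEFAULT_LAMBDA_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from a bootstrap cloud.

    prob_ce(λ) is the fraction of replicates with λ·∆QALY − ∆cost strictly
    positive (net benefit exactly zero counts as not cost-effective).
    Returns a frame with columns ``lambda_`` and ``prob_ce``.
    """
    if len(cloud.delta_costs) == 0:
        raise ValueError("empty bootstrap cloud")
    lam = np.asarray(list(lambdas), dtype=float)
    nb = lam[:, None] * cloud.delta_qalys[None, :] - cloud.delta_costs[None, :]
    prob = (nb > 0).mean(axis=1)
    return pd.DataFrame({"lambda_": lam, "prob_ce": prob})


@dataclass
class NMBCurve:
    """NMB regression estimates over a willingness-to-pay grid."""

    table: pd.DataFrame  # lambda_, nmb, se, ll, ul
    delta_cost: float
    delta_qaly: float
    cov: np.ndarray = field(repr=False, default=None)  # 2x2 cov of (∆Ĉ, ∆Ê)


def nmb_regression(
    cost,
    qaly,
    arm,
    clusters,
    lambdas=DEFAULT_LAMBDA_GRID,
    ci: str = "robust",
    alpha: float = 0.05,
    B: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> NMBCurve:
    """Incremental net-monetary-benefit curve with 95% confidence band.

    At each willingness-to-pay λ the individual net benefit is
    nb_i = λ·qaly_i − cost_i and the incremental NMB is the arm coefficient
    of the cluster-robust OLS regression of nb on treatment — which by
    linearity equals λ·∆Ê − ∆Ĉ, so the curve is affine in λ with slope ∆Ê
    and intercept −∆Ĉ.  The variance at λ is
    λ²·Var(∆Ê) − 2λ·Cov(∆Ĉ,∆Ê) + Var(∆Ĉ) from the joint CR1 sandwich.

    ``ci="robust"`` (default) gives the normal-theory band; ``ci="bootstrap"``
    gives percentile bands from the family bootstrap.
    """
    lam = np.asarray(list(lambdas), dtype=float)
    if (lam < 0).any():
        raise ValueError("willingness-to-pay grid must be nonnegative")
    cost = np.asarray(cost, dtype=float)
    qaly = np.asarray(qaly, dtype=float)
    _, arm_num, codes = _as_arrays(cost, arm, clusters)
    if arm_num.min() == arm_num.max():
        raise InferenceError("arm indicator is constant; both arms required")
    X = _design(arm_num)
    Y = np.column_stack([cost, qaly])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    V = cluster_robust_cov(X, resid, codes)  # 4x4 for (cost, qaly) x (b0, b1)
    # arm-coefficient block: indices 1 (cost) and 3 (qaly)
    cov = V[np.ix_([1, 3], [1, 3])]
    d_cost, d_qaly = float(beta[1, 0]), float(beta[1, 1])

    nmb = lam * d_qaly - d_cost
    var = lam**2 * cov[1, 1] - 2 * lam * cov[0, 1] + cov[0, 0]
    se = np.sqrt(np.maximum(var, 0.0))
    if ci == "robust":
        q = stats.norm.ppf(1 - alpha / 2)
        ll, ul = nmb - q * se, nmb + q * se
    elif ci == "bootstrap":
        cloud = bootstrap_cloud(cost, qaly, arm, codes, B=B, seed=seed)
        nb_b = lam[:, None] * cloud.delta_qalys[None, :] - cloud.delta_costs[None, :]
        ll = np.percentile(nb_b, 100 * alpha / 2, axis=1)
        ul = np.percentile(nb_b, 100 * (1 - alpha / 2), axis=1)
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    table = pd.DataFrame({"lambda_": lam, "nmb": nmb, "se": se, "ll": ll, "ul": ul})
    return NMBCurve(table=table, delta_cost=d_cost, delta_qaly=d_qaly, cov=cov)


def ceac_normal(curve: NMBCurve) -> pd.DataFrame:
    """Normal-theory CEAC variant: Φ(NMB(λ)/SE(λ)) from the NMB regression.

    An option beside the bootstrap-fraction CEAC; the two agree closely
    when the cloud is approximately Gaussian.
    """
    t = curve.table
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(t["se"] > 0, t["nmb"] / t["se"], np.where(t["nmb"] > 0, np.inf, -np.inf))
    return pd.DataFrame({"lambda_": t["lambda_"], "prob_ce": stats.norm.cdf(z)})
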