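import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cuakit

settings.register_profile(
    "cuakit",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cuakit")


def build_bundle(participants, service_rows, utility_rows):
    """Assemble a TrialBundle from plain tuples (test convenience)."""
    p = pd.DataFrame(
        participants,
        columns=["participant_id", "family_id", "arm", "age_years", "sex", "baseline_diagnosis"],
    )
    s = pd.DataFrame(
        service_rows,
        columns=["participant_id", "wave", "category", "item", "units", "assessed"],
    )
    u = pd.DataFrame(
        utility_rows, columns=["participant_id", "wave", "utility", "assessed"]
    )
    return cuakit.TrialBundle(p, s, u)


@pytest.fixture
def tiny_bundle():
    """Five children in three families, fully observed, direct costs."""
    participants = [
        ("p1", "f1", "TAU", 10, "female", True),
        ("p2", "f1", "TAU", 12, "male", False),
        ("p3", "f2", "INT", 8, "female", True),
        ("p4", "f2", "INT", 15, "male", True),
        ("p5", "f3", "TAU", 11, "female", False),
    ]
    service, utility = [], []
    for i, (pid, *_rest) in enumerate(participants):
        for w in range(4):
            service.append((pid, w, "inpatient", "direct_cost", 100.0 * i + 10 * w, 1))
            service.append((pid, w, "outpatient", "direct_cost", 5.0 * i, 1))
            utility.append((pid, w, 0.7 + 0.02 * i, 1))
    return build_bundle(participants, service, utility)


@pytest.fixture
def direct_unit_costs():
    return cuakit.unit_cost_table_for(cuakit.SyntheticTrialConfig())


def prepared_frame(config):
    """Generate → filter → LOCF → cost → QALY; merged per-participant frame.

    Returns a frame with annual costs, QALYs, arm and family columns — the
    analysis-ready object the inference and CEA layers consume.  No
    intervention cost is booked (pure outcome of the generated data).
    """
    bundle, truth = cuakit.generate_trial(config)
    bundle, _ = cuakit.filter_baseline_complete(bundle)
    bundle, _ = cuakit.locf_impute(bundle)
    unit_costs = cuakit.unit_cost_table_for(config)
    panel = cuakit.price_service_use(
        bundle.service_use, unit_costs, participants=bundle.participants["participant_id"]
    )
    annual = cuakit.annualize(panel)
    qaly = cuakit.compute_qalys(bundle.utilities)
    merged = annual.merge(qaly, on="participant_id")
    merged["arm"] = merged["participant_id"].map(bundle.arm_of)
    merged["family_id"] = merged["participant_id"].map(bundle.family_of)
    return merged


@pytest.fixture
def null_trial_frame():
    return prepared_frame(cuakit.SyntheticTrialConfig(seed=424242))
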