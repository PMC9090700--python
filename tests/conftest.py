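import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import prp_introspect as pi

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng(request):
    # per-test stream derived from the test id: deterministic and
    # independent of execution order
    import zlib

    seed = zlib.adler32(request.node.nodeid.encode()) & 0x7FFFFFFF
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def memory_study():
    """One small memory-model study (1 AV + 1 VA experiment), preprocessed
    and radian-annotated; shared by the slower analysis-stage tests."""
    df = pi.simulate_study(n_av=1, n_va=1, seed=424242, trials_per_cell=40)
    clean, _ = pi.run_cascade(df)
    return pi.add_radian_columns(clean)


def make_trial_row(
    participant="p00",
    soa=50.0,
    t_S1=1000.0,
    t_S2=None,
    t_R1=1550.0,
    t_R2=1800.0,
    correct1=True,
    correct2=True,
    markers=(300.0, 350.0, 500.0, 600.0),
    timeline_px=1000.0,
    trial_duration_ms=2800.0,
    modality_order="AV",
    experiment="fix",
):
    """One hand-built trial row in the tidy schema (used by fixtures)."""
    iS1, iS2, iR1, iR2 = markers
    return {
        "participant": participant,
        "experiment": experiment,
        "modality_order": modality_order,
        "soa": soa,
        "t_S1": t_S1,
        "t_S2": t_S1 + soa if t_S2 is None else t_S2,
        "t_R1": t_R1,
        "t_R2": t_R2,
        "correct1": correct1,
        "correct2": correct2,
        "iS1_px": iS1,
        "iS2_px": iS2,
        "iR1_px": iR1,
        "iR2_px": iR2,
        "timeline_px": timeline_px,
        "trial_duration_ms": trial_duration_ms,
        "total_estimate_ms": 3000.0,
    }


@pytest.fixture
def trial_row_factory():
    return make_trial_row


def rows_to_frame(rows):
    return pd.DataFrame(rows)
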