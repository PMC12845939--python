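import numpy as np
import pandas as pd
import pytest

from oculogate import simgen


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simgen.CohortConfig(n_total=40, n_depressed=13, seed=7)
    return simgen.generate_cohort(cfg)


@pytest.fixture(scope="session")
def iris_image_pair():
    """Same identity rendered at 0.10 and 0.40 dilation, noise-free."""
    params = simgen.IrisIdentityParams(identity_seed=11, intra_noise_sd=0.0)
    a = simgen.simulate_iris_image(params, dilation=0.10, seed=1)
    b = simgen.simulate_iris_image(params, dilation=0.40, seed=2)
    return a, b


def single_block_schedule(valence: str = "neg") -> simgen.BlockSchedule:
    return simgen.BlockSchedule(
        "P0000", "screening", [simgen.Block(onset_ms=5000, valence=valence)])


def pupil_trace_frame(amplitude: float, noise_sd: float = 0.0,
                      latency_ms: float = 400.0, seed: int = 0,
                      schedule: simgen.BlockSchedule | None = None,
                      baseline_mm: float = 4.0) -> pd.DataFrame:
    """Two-eye trace frame realising one pupil response, static gaze."""
    schedule = schedule or single_block_schedule()
    pk = simgen.PupilKernelParams(baseline_diameter=baseline_mm,
                                  amplitude=amplitude, noise_sd=noise_sd,
                                  latency_ms=latency_ms)
    tr = simgen.simulate_pupil_trace(pk, schedule, seed=seed)
    return pd.DataFrame({
        "t_ms": tr["t_ms"], "pupil_l_mm": tr["pupil_mm"],
        "pupil_r_mm": tr["pupil_mm"], "gaze_x_deg": 0.0, "gaze_y_deg": 0.0,
        "valid": tr["valid"],
    })
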