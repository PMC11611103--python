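import numpy as np
import pandas as pd
import pytest

from panelgfr import CohortData, MARKERS, default_design, generate_multistudy


@pytest.fixture
def raw_frame():
    """Tiny natural-scale cohort table with all required columns."""
    rng = np.random.default_rng(42)
    n = 12
    frame = pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "study": ["A"] * 6 + ["B"] * 6,
        "mgfr": rng.uniform(20, 120, n),
        "mgfr_method": ["iothalamate", "iohexol", "inulin"] * 4,
    })
    for m in MARKERS:
        frame[m] = rng.uniform(0.5, 3.0, n)
    return frame


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-design multi-study cohort shared across tests."""
    return generate_multistudy(default_design(n_total=1200, seed=101))


@pytest.fixture(scope="session")
def dev_xy(small_cohort):
    return small_cohort.X(), small_cohort.y()


def make_noiseless_cohort(n=300, seed=0):
    """Cohort where every log marker is an exact linear function of log mGFR."""
    rng = np.random.default_rng(seed)
    log_g = rng.normal(4.0, 0.5, n)
    frame = pd.DataFrame({
        "id": [f"N{i:04d}" for i in range(n)],
        "study": "noiseless",
        "mgfr": np.exp(log_g),
        "mgfr_method": "iothalamate",
        "log_mgfr": log_g,
    })
    for j, m in enumerate(MARKERS):
        logs = 0.5 + (0.1 * (j + 1)) * log_g * (-1) ** j
        frame[m] = np.exp(logs)
        frame[f"log_{m}"] = logs
    return CohortData(frame, harmonized=True, logged=True)
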