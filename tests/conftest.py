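import logging

import numpy as np
import pandas as pd
import pytest

from rheumet import SyntheticConfig, build_default_panel, simulate_cohort
from rheumet.containers import SpectraSet

logging.getLogger("rheumet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free jittered spectral cohort used by several alignment and
    end-to-end checks (session-scoped: simulation is the slow part)."""
    cfg = SyntheticConfig(seed=7, noise_sd=0.0, baseline_amplitude=0.0,
                          sigma_log_subject=0.4, dropout_prob=0.0,
                          cohort_sizes={"RA": 10, "AS": 10, "PsA": 10})
    sset, truth = simulate_cohort(cfg)
    return cfg, sset, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-condition cohort at reduced size for pipeline tests."""
    cfg = SyntheticConfig(seed=5, n_points=4096,
                          cohort_sizes={"RA": 12, "AS": 12, "PsA": 12})
    sset, truth = simulate_cohort(cfg)
    return cfg, sset, truth


def toy_spectra_set(n_samples=6, n_points=1024, seed=0, peaks=(2.0, 4.5, 7.0)):
    """Minimal multi-sample set of Lorentzian peaks on a descending axis."""
    rng = np.random.default_rng(seed)
    ppm = np.linspace(10.0, 0.0, n_points)
    mat = np.zeros((n_samples, n_points))
    for i in range(n_samples):
        for c in peaks:
            amp = rng.uniform(0.5, 1.5)
            mat[i] += amp * 0.01 / np.pi / ((ppm - c) ** 2 + 0.01 ** 2)
    meta = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_samples)],
        "disease": ["RA"] * n_samples,
        "timepoint": ["BT"] * n_samples,
        "response": [""] * n_samples,
    }, index=pd.Index([f"s{i}_BT" for i in range(n_samples)],
                      name="sample_id"))
    return SpectraSet(ppm, mat, meta)
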