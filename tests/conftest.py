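import numpy as np
import pandas as pd
import pytest

from pacemeter import (
    SimulationConfig,
    simulate_longitudinal_biomarkers,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_panel():
    """Compact longitudinal panel (80 subjects, 6 biomarkers) with truth."""
    cfg = SimulationConfig(n_subjects=80, n_biomarkers=6, seed=42)
    panel, truth = simulate_longitudinal_biomarkers(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def small_methylation():
    """Small training cohort: 120 samples, 300 CpGs, 10 planted."""
    rng = np.random.default_rng(7)
    pace = pd.Series(
        1.0 + 0.38 * rng.standard_normal(120),
        index=[f"s{i:04d}" for i in range(120)],
        name="pace",
    )
    beta, truth = simulate_methylation(
        pace, n_cpgs=300, n_signal=10, effect_size=0.45, seed=17
    )
    return beta, pace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
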