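import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import lvepulse as lp
from lvepulse.preprocessing import preprocess_cohort
from lvepulse.harmonics import subject_power_table, representative_waveform
from lvepulse.classify import build_features

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def cohort_features(config, mode="waveform", kmeans_seed=0):
    """Generate a cohort and assemble per-subject features and labels."""
    subjects, recordings = lp.generate_cohort(config)
    cycles = preprocess_cohort(recordings)
    powers = subject_power_table(cycles)
    rep = {
        sid: representative_waveform(
            [c for c in cycles[sid] if c.valid], k=2, seed=kmeans_seed)
        for sid in sorted(cycles)
    }
    X = build_features(rep, power_table=powers, mode=mode)
    y = subjects.set_index("subject_id").loc[X.index, "true_group"]
    return subjects, X, y


@pytest.fixture(scope="session")
def flow_fixture():
    return lp.paper_flow_fixture()


@pytest.fixture(scope="session")
def screened_flow(flow_fixture):
    subjects, recordings = flow_fixture
    return lp.screen(subjects, recordings)


@pytest.fixture(scope="session")
def imbalanced_cohort():
    """120 non-LVE / 40 LVE cohort with the default group structure."""
    config = lp.GeneratorConfig(n_non_lve=120, n_lve=40, seed=33)
    return cohort_features(config)


@pytest.fixture(scope="session")
def separable_cohort():
    """Two harmonic regimes far apart: every model should separate them."""
    config = lp.GeneratorConfig(
        n_non_lve=60, n_lve=20,
        harmonic_power_means={"non_lve": (3.5, 0.4, 0.1),
                              "lve": (1.5, 1.4, 0.4)},
        harmonic_power_sds={"non_lve": (0.1, 0.05, 0.02),
                            "lve": (0.1, 0.05, 0.02)},
        noise_sd=0.05, seed=21)
    return cohort_features(config)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Cohort whose LVDdI is a fixed linear map of the harmonic powers."""
    config = lp.GeneratorConfig(n_non_lve=137, n_lve=90,
                                deterministic_lvddi=True, seed=11)
    subjects, X, y = cohort_features(config, mode="powers")
    lvddi = subjects.set_index("subject_id").loc[X.index, "lvddi_mm_m2"]
    return X, lvddi, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
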