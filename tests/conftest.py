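import numpy as np
import pytest

from gazediff.framewise import AnalysisConfig, framewise_arrays, summarise
from gazediff.io_gaze import frame_matrices_from_table
from gazediff.questionnaire import split_from_responses
from gazediff.simulate import SimConfig, generate_cohort


def small_sim_config(**overrides) -> SimConfig:
    """A fast 24-participant, 4-video, 5-second cohort for unit tests."""
    defaults = dict(
        n_participants=24,
        group_sizes=(12, 12),
        categories={"FUN_1": "FUN", "SPORT_1": "SPORT", "PRODUCT_1": "PRODUCT", "CONTROL_1": "CONTROL"},
        duration_s=5.0,
        signal_videos=("FUN_1",),
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def analyse_cohort(cohort, cfg: AnalysisConfig = AnalysisConfig()):
    """Cohort -> (matrices, groups, per-video summaries), the standard path."""
    matrices = frame_matrices_from_table(cohort.gaze, fps=cfg.fps)
    _, groups = split_from_responses(cohort.responses())
    summaries = [
        summarise(framewise_arrays(matrices[v], groups, cfg), cohort.config.categories[v])
        for v in sorted(matrices)
    ]
    return matrices, groups, summaries


@pytest.fixture(scope="session")
def small_null_cohort():
    return generate_cohort(small_sim_config(dispersion_ratio=1.0))


@pytest.fixture(scope="session")
def small_signal_cohort():
    return generate_cohort(small_sim_config(dispersion_ratio=2.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
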