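import numpy as np
import pytest

from aromatype.data_io import FeatureTable
from aromatype.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def survey_table() -> FeatureTable:
    """One full-size synthetic survey (619 x 51, default design)."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_survey() -> FeatureTable:
    """A reduced survey (120/60/30) for model-fitting tests."""
    return generate(GeneratorConfig(class_sizes=(120, 60, 30), seed=1))


@pytest.fixture
def blob_table() -> FeatureTable:
    """Three well-separated Gaussian blobs, 20 samples each, 4 features."""
    rng = np.random.default_rng(7)
    centers = np.array(
        [[0.0, 0.0, 0.0, 0.0], [10.0, 10.0, 0.0, 0.0], [0.0, 10.0, 10.0, 10.0]]
    )
    rows, labels = [], []
    for c in range(3):
        rows.append(centers[c] + rng.normal(0, 0.5, size=(20, 4)))
        labels += [c] * 20
    values = np.vstack(rows)
    return FeatureTable(
        [f"b{i}" for i in range(60)],
        ["w", "x", "y", "z"],
        values,
        np.array(labels),
    )


def exact_moments_sample(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """A sample whose *sample* mean and SD (ddof=1) equal mean and sd exactly."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
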