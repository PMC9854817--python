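"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

import numpy as np
import pytest

from ramandx import GeneratorConfig, PeakSpec, make_axis


def small_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A scaled-down cohort on a short axis: 3 classes, 3 peaks, fast to render."""
    peaks = [
        PeakSpec(600.0, 16.0, 0.4, {"HC": 1.0, "BC": 1.2, "DCIS": 1.1}),
        PeakSpec(1154.0, 16.0, 1.0, {"HC": 1.0, "BC": 0.6, "DCIS": 0.78}),
        PeakSpec(1514.0, 16.0, 0.95, {"HC": 1.0, "BC": 0.6, "DCIS": 0.78}),
    ]
    defaults = dict(
        n_per_class={"HC": 12, "BC": 16, "DCIS": 8},
        peaks=peaks,
        noise_sd=0.01,
        jitter_sd=0.05,
        replicates=3,
        seed=seed,
        axis_start=400.0,
        axis_stop=1800.0,
        axis_points=256,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return small_generator_config()


@pytest.fixture
def axis256() -> np.ndarray:
    return make_axis(400.0, 1800.0, 256)
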