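"""Shared fixtures: ground truths, generated datasets and reusable fits."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fracrad as fr
from fracrad.model import FractionatedRadiationModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def one_line_truth(truth, cell_line="9L"):
    """Restrict a TruthConfig to a single cell line."""
    return replace(truth, cell_lines={cell_line: truth.cell_lines[cell_line]})


@pytest.fixture(scope="session")
def kinetics():
    return fr.DEFAULT_REPAIR_KINETICS


@pytest.fixture(scope="session")
def growth_9l():
    return fr.default_truth().cell_lines["9L"].growth


@pytest.fixture(scope="session")
def spec3():
    return fr.model_family((16.0, 20.0))[2]


@pytest.fixture(scope="session")
def truth_noisefree():
    """Noise-free single-line truth: 24 curves over both dose arms, 10x N0 range."""
    return one_line_truth(fr.default_truth(noise_cv=0.0, replicates_per_condition=4))


@pytest.fixture(scope="session")
def dataset_noisefree(truth_noisefree):
    return fr.generate_dataset(truth_noisefree, 7)


@pytest.fixture(scope="session")
def truth_noisy():
    """Default study conditions (21% noise, 8 replicates/condition) at dt=0.02."""
    return fr.default_truth(dt=0.02)


@pytest.fixture(scope="session")
def dataset_noisy(truth_noisy):
    return fr.generate_dataset(truth_noisy, 11)


@pytest.fixture(scope="session")
def split_noisy(dataset_noisy):
    return fr.train_validation_split(dataset_noisy, seed=12)


@pytest.fixture(scope="session")
def noisy_fit_9l(truth_noisy, split_noisy):
    """Well-converged Model-3 calibration of the noisy 9L training split."""
    train, _ = split_noisy
    curves = [c for c in train if c.cell_line == "9L"]
    line = truth_noisy.cell_lines["9L"]
    model = FractionatedRadiationModel(
        curves, truth_noisy.generating_spec(), line.growth, line.kinetics, dt=0.02
    )
    return model.fit(n_starts=3, seed=2, max_nfev=300)


@pytest.fixture(scope="session")
def noisy_fits(truth_noisy, split_noisy, noisy_fit_9l):
    """Per-cell-line calibrations on the noisy training split."""
    train, _ = split_noisy
    curves = [c for c in train if c.cell_line == "C6"]
    line = truth_noisy.cell_lines["C6"]
    model = FractionatedRadiationModel(
        curves, truth_noisy.generating_spec(), line.growth, line.kinetics, dt=0.02
    )
    return {"9L": noisy_fit_9l, "C6": model.fit(n_starts=3, seed=2, max_nfev=300)}


@pytest.fixture(scope="session")
def validation_metrics(noisy_fits, split_noisy):
    _, val = split_noisy
    return fr.validate(noisy_fits, val)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
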