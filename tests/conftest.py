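import numpy as np
import pytest

from floricolor.spectra import ReflectanceSpectrum, standard_grid


@pytest.fixture(scope="session")
def grid():
    return standard_grid()


@pytest.fixture
def flat_spectrum(grid):
    def _make(level, sample_id="flat", part="whole"):
        return ReflectanceSpectrum(sample_id, part, grid, np.full_like(grid, float(level)))

    return _make


@pytest.fixture
def logistic_spectrum(grid):
    """base + amplitude * logistic((wl - center) / width)."""

    def _make(center, amplitude, base=2.0, width=5.0, sample_id="step"):
        refl = base + amplitude / (1.0 + np.exp(-(grid - center) / width))
        return ReflectanceSpectrum(sample_id, "whole", grid, refl)

    return _make


@pytest.fixture(scope="session")
def small_study():
    """A 60-sample synthetic study shared by pipeline-level tests."""
    from floricolor.synthetic_data import StudyDesign, make_study

    design = StudyDesign(
        n_samples=60,
        category_proportions={"DEO90": 10 / 60, "DEO_HYD": 10 / 60, "HYD90": 30 / 60, "NONE": 10 / 60},
        seed=7,
    )
    return make_study(design)
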