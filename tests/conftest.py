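import numpy as np
import pytest

from ftirdry.band_markers import MarkerSet, extract_markers
from ftirdry.preprocess import normalized_second_derivative
from ftirdry.spectral_core import FINGERPRINT, SpectralRegion, Spectrum
from ftirdry.synthetic import FormulationSpec, generate_component, generate_formulation

GEN_REGION = SpectralRegion(900.0, 1800.0)


def pipeline_markers(spectrum: Spectrum, state: str) -> MarkerSet:
    """The standard chain: vector-normalize fingerprint, SG(21,3), extract."""
    d = normalized_second_derivative(spectrum, FINGERPRINT)
    return extract_markers(d, state=state)


@pytest.fixture
def dsdna_a_spectrum() -> Spectrum:
    return generate_component("dsDNA_A", 1.0, GEN_REGION)


@pytest.fixture
def dsdna_b_spectrum() -> Spectrum:
    return generate_component("dsDNA_B", 1.0, GEN_REGION)


@pytest.fixture
def gaussian_spectrum():
    """Single gaussian band factory on a 1 cm^-1 grid."""

    def make(center=1100.0, fwhm=20.0, amp=1.0, lo=900.0, hi=1500.0):
        w = np.arange(lo, hi + 0.5)
        a = amp * np.exp(-4 * np.log(2) * (w - center) ** 2 / fwhm**2)
        return Spectrum(w, a)

    return make


@pytest.fixture
def full_matrix_spec():
    """dsDNA in a trehalose/albumin matrix (the protective formulation)."""

    def make(hydration, noise_sd=0.0, seed=None):
        return FormulationSpec(
            components={"dsDNA": 1.0, "trehalose_dry": 0.6, "albumin": 0.5},
            hydration=hydration,
            noise_sd=noise_sd,
            seed=seed,
        )

    return make
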