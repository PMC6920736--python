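"""Shared fixtures: small geometries, a reference phantom, seeded spectra."""

import numpy as np
import pytest

from qusradiomics.spectral import AnalysisBand, PowerSpectrum
from qusradiomics.synthetic import FrameGeometry, simulate_reference


@pytest.fixture(scope="session")
def small_geometry() -> FrameGeometry:
    return FrameGeometry(n_axial=1400, n_lines=128)


@pytest.fixture(scope="session")
def reference(small_geometry):
    """Matched tissue-mimicking phantom: alpha 0.5 dB/cm/MHz, 40 um beads."""
    return simulate_reference(
        small_geometry, alpha_ref=0.5, mean_diameter=40.0, seed=10, n_frames=6
    )


@pytest.fixture(scope="session")
def band() -> AnalysisBand:
    return AnalysisBand(5.0, 11.0)


def make_spectrum(power, freqs=None, **kwargs) -> PowerSpectrum:
    power = np.asarray(power, dtype=float)
    if freqs is None:
        freqs = np.linspace(0.0, 20.0, power.size)
    return PowerSpectrum(freqs=freqs, power=power, **kwargs)
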