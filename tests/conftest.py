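"""Shared fixtures and independent signal-construction oracles.

The helpers here are deliberately implemented from first principles
(plain FFT phase ramps, spectral masks) so that tests never validate the
package against its own code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from sonodent import Indenter, LoadStep, PulseModel, TissuePhantom


def fractional_delay(x: np.ndarray, shift_samples: float) -> np.ndarray:
    """Delay a band-limited signal by a (possibly fractional) number of
    samples using an FFT phase ramp.  Positive shift moves content later."""
    n = x.size
    freqs = np.fft.rfftfreq(n)
    spectrum = np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * shift_samples)
    return np.fft.irfft(spectrum, n)


def bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-peak Gaussian noise band-limited to [f_lo, f_hi] Hz."""
    spectrum = np.fft.rfft(rng.normal(size=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spectrum, n)
    return x / np.max(np.abs(x))


@pytest.fixture
def pulse() -> PulseModel:
    return PulseModel()


@pytest.fixture
def indenter() -> Indenter:
    return Indenter(contact_radius_a=0.01)


@pytest.fixture
def soft_phantom() -> TissuePhantom:
    """A 30 mm, 10 kPa incompressible soft-tissue block."""
    return TissuePhantom(
        thickness_h=0.03, sound_speed_v=1540.0, youngs_modulus_e=10e3
    )


def load_of(force_n: float, label: str | None = None) -> LoadStep:
    return LoadStep(label=label or f"{force_n:g}N", applied_force_p=force_n)
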