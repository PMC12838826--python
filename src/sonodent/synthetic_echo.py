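"""Synthetic A-mode pulse-echo signals from indented tissue phantoms.

This module stands in for the measurement hardware of an ultrasonic
indentation tester: a single-element transducer (2 MHz by default) whose
flat cylindrical face doubles as the indenter.  Pressing the face into a
soft sample thins the tissue column underneath, so the echo from the far
interface arrives earlier; the round-trip arrival-time change is the
quantity every downstream module works with.

The acoustic model is deliberately one-dimensional and two-interface: a
fixed-amplitude surface echo at time zero and a back-wall echo at the
round-trip time ``2*(h - w)/v``, both Gabor (Gaussian-windowed sinusoid)
replicas of the excitation pulse.  Frequency-dependent attenuation scales
the back-echo amplitude only — never its timing.  Mechanics follow the
flat-punch (cylindrical indenter) contact model ``E = (1 - nu^2) P / (2 a w)``
with an optional single-coefficient strain-stiffening extension and an
optional stiff inclusion folded in through a series-spring composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    InvalidConfigurationError,
    InvalidInputError,
    InvalidLoadError,
    InvalidProtocolError,
)

__all__ = [
    "PulseModel",
    "Inclusion",
    "TissuePhantom",
    "Indenter",
    "LoadStep",
    "DeformationState",
    "AScan",
    "make_pulse",
    "deform",
    "effective_modulus",
    "simulate_ascan",
    "simulate_sweep",
    "shore_to_young",
    "derive_seed",
]

#: -6 dB full width of a Gaussian magnitude spectrum, in units of sigma_f.
_SIX_DB_WIDTH = 2.0 * math.sqrt(2.0 * math.log(10.0 ** (6.0 / 20.0)))

#: Envelope half-duration used when rendering pulses, in units of sigma_t.
_PULSE_HALF_SIGMAS = 4.0

#: Deformation cap as a fraction of the resting thickness.
BOTTOM_OUT_FRACTION = 0.95


@dataclass(frozen=True)
class PulseModel:
    """Excitation pulse: a Gaussian-windowed sinusoid (Gabor pulse).

    Parameters
    ----------
    center_frequency : float
        Carrier frequency in Hz (> 0).  Default 2 MHz, the transducer
        used for soft-tissue indentation sensing.
    fractional_bandwidth : float
        -6 dB spectral full width divided by the center frequency,
        in (0, 1].
    amplitude : float
        Peak amplitude in arbitrary units.
    """

    center_frequency: float = 2.0e6
    fractional_bandwidth: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise InvalidConfigurationError("center_frequency must be > 0")
        if not 0.0 < self.fractional_bandwidth <= 1.0:
            raise InvalidConfigurationError(
                "fractional_bandwidth must lie in (0, 1]"
            )

    @property
    def sigma_f(self) -> float:
        """Std of the Gaussian magnitude spectrum, Hz."""
        return self.fractional_bandwidth * self.center_frequency / _SIX_DB_WIDTH

    @property
    def sigma_t(self) -> float:
        """Std of the Gaussian time envelope, s."""
        return 1.0 / (2.0 * math.pi * self.sigma_f)

    @property
    def half_duration(self) -> float:
        """Half-length of the rendered pulse, s."""
        return _PULSE_HALF_SIGMAS * self.sigma_t


@dataclass(frozen=True)
class Inclusion:
    """A stiffer (or softer) layer embedded in the phantom.

    Fractions are relative to the resting thickness: the inclusion starts
    at depth ``depth_fraction * h`` and spans ``thickness_fraction * h``.
    """

    depth_fraction: float
    thickness_fraction: float
    youngs_modulus_e_inc: float

    def __post_init__(self) -> None:
        if not 0.0 < self.depth_fraction < 1.0:
            raise InvalidConfigurationError("depth_fraction must be in (0, 1)")
        if not 0.0 < self.thickness_fraction < 1.0:
            raise InvalidConfigurationError(
                "thickness_fraction must be in (0, 1)"
            )
        if self.depth_fraction + self.thickness_fraction > 1.0:
            raise InvalidConfigurationError(
                "inclusion must fit inside the phantom "
                "(depth_fraction + thickness_fraction <= 1)"
            )
        if not self.youngs_modulus_e_inc > 0:
            raise InvalidConfigurationError("inclusion modulus must be > 0")


@dataclass(frozen=True)
class TissuePhantom:
    """Geometric, elastic and acoustic description of the sample.

    Parameters
    ----------
    thickness_h : float
        Resting thickness under the indenter, m.
    sound_speed_v : float
        Longitudinal sound speed, m/s.
    youngs_modulus_e : float
        Young's modulus of the host material, Pa.
    poisson_ratio_nu : float
        Poisson's ratio in [0, 0.5]; 0.5 models incompressible soft tissue.
    attenuation_alpha : float
        Amplitude attenuation coefficient, dB/(cm MHz).
    stiffening_beta : float
        Dimensionless strain-stiffening coefficient (>= 0); 0 means
        linear-elastic.
    inclusion : Inclusion, optional
        Embedded layer modelling a stiff lesion.
    """

    thickness_h: float
    sound_speed_v: float
    youngs_modulus_e: float
    poisson_ratio_nu: float = 0.5
    attenuation_alpha: float = 0.5
    stiffening_beta: float = 0.0
    inclusion: Inclusion | None = None

    def __post_init__(self) -> None:
        if not self.thickness_h > 0:
            raise InvalidConfigurationError("thickness_h must be > 0")
        if not self.sound_speed_v > 0:
            raise InvalidConfigurationError("sound_speed_v must be > 0")
        if not self.youngs_modulus_e > 0:
            raise InvalidConfigurationError("youngs_modulus_e must be > 0")
        if not 0.0 <= self.poisson_ratio_nu <= 0.5:
            raise InvalidConfigurationError("poisson_ratio_nu must be in [0, 0.5]")
        if self.attenuation_alpha < 0:
            raise InvalidConfigurationError("attenuation_alpha must be >= 0")
        if self.stiffening_beta < 0:
            raise InvalidConfigurationError("stiffening_beta must be >= 0")


@dataclass(frozen=True)
class Indenter:
    """Flat cylindrical indenter (the transducer face)."""

    contact_radius_a: float = 0.01

    def __post_init__(self) -> None:
        if not self.contact_radius_a > 0:
            raise InvalidConfigurationError("contact_radius_a must be > 0")

    @property
    def contact_area(self) -> float:
        """Contact area pi a^2, m^2."""
        return math.pi * self.contact_radius_a**2


@dataclass(frozen=True)
class LoadStep:
    """One level of an indentation protocol.

    Either the indentation force (N) or the applied pressure (Pa) must be
    given; when only a pressure is given the force is obtained through the
    indenter contact area.
    """

    label: str
    applied_pressure: float | None = None
    applied_force_p: float | None = None

    def __post_init__(self) -> None:
        if self.applied_pressure is None and self.applied_force_p is None:
            raise InvalidLoadError(
                f"load {self.label!r}: need a pressure or a force"
            )
        if self.applied_pressure is not None and self.applied_pressure < 0:
            raise InvalidLoadError(f"load {self.label!r}: negative pressure")
        if self.applied_force_p is not None and self.applied_force_p < 0:
            raise InvalidLoadError(f"load {self.label!r}: negative force")

    def resolve_force(self, indenter: Indenter) -> float:
        """Indentation force in N, mapping pressure through the contact area."""
        if self.applied_force_p is not None:
            if self.applied_pressure is not None:
                implied = self.applied_pressure * indenter.contact_area
                if not math.isclose(
                    implied, self.applied_force_p, rel_tol=1e-6, abs_tol=1e-12
                ):
                    raise InvalidLoadError(
                        f"load {self.label!r}: force {self.applied_force_p} N "
                        f"inconsistent with pressure-implied {implied} N"
                    )
            return self.applied_force_p
        return self.applied_pressure * indenter.contact_area


@dataclass(frozen=True)
class DeformationState:
    """Indentation outcome: depth ``w`` and compressed thickness ``h - w``."""

    deformation_w: float
    compressed_thickness_hi: float
    bottomed_out: bool = False


@dataclass(eq=False)
class AScan:
    """A sampled pulse-echo signal.

    ``time_origin`` is the time of the first sample, so sample *i* sits at
    ``time_origin + i / sampling_rate``; the surface echo is centred at
    t = 0 and the back-wall echo at the round-trip time.
    """

    samples: np.ndarray
    sampling_rate: float
    time_origin: float = 0.0
    load_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise InvalidConfigurationError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfigurationError("AScan samples must be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.time_origin + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate


def make_pulse(pulse: PulseModel, sampling_rate: float) -> np.ndarray:
    """Render the excitation pulse on a symmetric sample grid.

    The waveform is a sine carrier under a Gaussian window, normalised so
    the largest sample magnitude equals ``pulse.amplitude``.  The odd
    carrier makes the rendered pulse exactly zero-mean on the symmetric
    grid, and its -6 dB spectral width matches
    ``fractional_bandwidth * center_frequency``.
    """
    _check_sampling(pulse, sampling_rate)
    n_half = int(math.ceil(pulse.half_duration * sampling_rate))
    t = np.arange(-n_half, n_half + 1) / sampling_rate
    if pulse.amplitude == 0:
        return np.zeros_like(t)
    wave = _gabor(t, pulse)
    return pulse.amplitude * wave / np.max(np.abs(wave))


def _check_sampling(pulse: PulseModel, sampling_rate: float) -> None:
    if sampling_rate < 10.0 * pulse.center_frequency:
        raise InvalidConfigurationError(
            f"sampling_rate {sampling_rate:g} Hz is below 10x the "
            f"{pulse.center_frequency:g} Hz carrier; sub-sample timing "
            "would be unreliable"
        )


def _gabor(t: np.ndarray, pulse: PulseModel) -> np.ndarray:
    s = pulse.sigma_t
    return np.exp(-(t**2) / (2.0 * s * s)) * np.sin(
        2.0 * math.pi * pulse.center_frequency * t
    )


def effective_modulus(phantom: TissuePhantom) -> float:
    """Series-spring composite modulus of a phantom with an inclusion.

    The host and inclusion layers are springs in series along the
    indentation axis: ``E_eff = 1 / (f_host/E + f_inc/E_inc)`` with
    ``f_inc`` the inclusion thickness fraction.  Strictly increasing in
    the inclusion modulus; equals the host modulus when they match.
    """
    if phantom.inclusion is None:
        raise InvalidInputError("phantom has no inclusion")
    f_inc = phantom.inclusion.thickness_fraction
    f_host = 1.0 - f_inc
    return 1.0 / (
        f_host / phantom.youngs_modulus_e
        + f_inc / phantom.inclusion.youngs_modulus_e_inc
    )


def _load_bearing_modulus(phantom: TissuePhantom) -> float:
    if phantom.inclusion is not None:
        return effective_modulus(phantom)
    return phantom.youngs_modulus_e


def deform(
    phantom: TissuePhantom, indenter: Indenter, load: LoadStep
) -> DeformationState:
    """Indentation depth of the phantom under one load step.

    With ``stiffening_beta == 0`` this is the flat-punch contact result
    ``w = (1 - nu^2) P / (2 a E)``; with stiffening the depth solves
    ``P = 2 a E w (1 + beta w / h) / (1 - nu^2)`` by bisection.  The depth
    is capped at 95% of the resting thickness, with ``bottomed_out`` set
    when the cap engages.  An inclusion stiffens the column through the
    series composite modulus.
    """
    p = load.resolve_force(indenter)
    if p < 0:
        raise InvalidLoadError("indentation force must be >= 0")
    h = phantom.thickness_h
    e = _load_bearing_modulus(phantom)
    nu = phantom.poisson_ratio_nu
    a = indenter.contact_radius_a
    beta = phantom.stiffening_beta
    cap = BOTTOM_OUT_FRACTION * h

    k = 2.0 * a * e / (1.0 - nu * nu)  # N per metre of linear indentation
    w_lin = p / k
    if beta == 0.0:
        w = min(w_lin, cap)
        return DeformationState(w, h - w, bottomed_out=w_lin >= cap)

    def force_at(w: float) -> float:
        return k * w * (1.0 + beta * w / h)

    if p >= force_at(cap):
        return DeformationState(cap, h - cap, bottomed_out=True)
    lo, hi = 0.0, cap
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if force_at(mid) < p:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-10 * max(hi, 1e-30):
            break
    w = 0.5 * (lo + hi)
    return DeformationState(w, h - w, bottomed_out=False)


def _render_echo(
    times: np.ndarray, center: float, pulse: PulseModel, amplitude: float
) -> np.ndarray:
    wave = _gabor(times - center, pulse)
    peak = np.max(np.abs(wave))
    if peak == 0.0:
        return np.zeros_like(times)
    return amplitude * wave / peak


def _attenuation_factor(phantom: TissuePhantom, path_m: float, f0: float) -> float:
    db = phantom.attenuation_alpha * (path_m * 100.0) * (f0 / 1e6)
    return 10.0 ** (-db / 20.0)


def simulate_ascan(
    phantom: TissuePhantom,
    indenter: Indenter,
    load: LoadStep,
    pulse: PulseModel | None = None,
    sampling_rate: float = 50e6,
    snr_db: float | None = None,
    seed: int | None = None,
) -> AScan:
    """Simulate one pulse-echo A-scan of the phantom under a load step.

    The record holds a fixed-amplitude surface echo centred at t = 0 and a
    back-wall echo centred at the round-trip time ``2 (h - w) / v``, with
    the back echo attenuated by ``10^(-alpha * d_cm * f_MHz / 20)`` over
    the round-trip path.  When ``snr_db`` is given, white Gaussian noise is
    added with RMS set so that ``20 log10(peak / rms) = snr_db``; the noise
    stream is fully determined by ``seed``.
    """
    pulse = pulse or PulseModel()
    _check_sampling(pulse, sampling_rate)
    state = deform(phantom, indenter, load)
    t_back = 2.0 * state.compressed_thickness_hi / phantom.sound_speed_v

    t0 = -math.ceil(pulse.half_duration * sampling_rate) / sampling_rate
    t_end = 1.15 * (2.0 * phantom.thickness_h / phantom.sound_speed_v) + 2.0 * (
        pulse.half_duration
    )
    n = int(math.ceil((t_end - t0) * sampling_rate)) + 1
    times = t0 + np.arange(n) / sampling_rate

    back_amp = pulse.amplitude * _attenuation_factor(
        phantom, 2.0 * state.compressed_thickness_hi, pulse.center_frequency
    )
    wave = _render_echo(times, 0.0, pulse, pulse.amplitude)
    wave = wave + _render_echo(times, t_back, pulse, back_amp)

    if snr_db is not None:
        peak = np.max(np.abs(wave))
        rms = peak / 10.0 ** (snr_db / 20.0)
        rng = np.random.default_rng(seed)
        wave = wave + rng.normal(0.0, rms, size=n)

    return AScan(
        samples=wave,
        sampling_rate=sampling_rate,
        time_origin=t0,
        load_label=load.label,
        seed=seed,
    )


def derive_seed(base_seed: int | None, index: int) -> int | None:
    """Deterministic per-signal seed from a base seed and a counter."""
    if base_seed is None:
        return None
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_sweep(
    phantom: TissuePhantom,
    indenter: Indenter,
    loads: list[LoadStep],
    pulse: PulseModel | None = None,
    sampling_rate: float = 50e6,
    snr_db: float | None = None,
    seed: int | None = None,
) -> list[AScan]:
    """Simulate one A-scan per load step of a stepped-indentation protocol.

    The first load must be the baseline (lowest force); per-scan noise
    seeds are derived deterministically from ``seed`` and the load index,
    so reruns with the same base seed are bit-identical.
    """
    if not loads:
        raise InvalidProtocolError("load protocol is empty")
    forces = [step.resolve_force(indenter) for step in loads]
    if forces[0] != min(forces):
        raise InvalidProtocolError(
            "the first load step must be the baseline (lowest force)"
        )
    return [
        simulate_ascan(
            phantom,
            indenter,
            step,
            pulse=pulse,
            sampling_rate=sampling_rate,
            snr_db=snr_db,
            seed=derive_seed(seed, i),
        )
        for i, step in enumerate(loads)
    ]


def shore_to_young(shore_ha: float) -> float:
    """Young's modulus (Pa) of an elastomer from Shore A hardness.

    Uses the Gent relation
    ``E(MPa) = 0.0981 (56 + 7.62336 S) / (0.137505 (254 - 2.54 S))``,
    strictly increasing in S and singular at S = 100.  This parameterises
    silicone-like calibration phantoms; it is simulator metadata, not a
    measured property of any particular sample.
    """
    if not 0.0 <= shore_ha < 100.0:
        raise InvalidInputError("Shore A hardness must lie in [0, 100)")
    e_mpa = (0.0981 * (56.0 + 7.62336 * shore_ha)) / (
        0.137505 * (254.0 - 2.54 * shore_ha)
    )
    return e_mpa * 1e6


def with_inclusion(
    phantom: TissuePhantom,
    depth_fraction: float,
    thickness_fraction: float,
    youngs_modulus_e_inc: float,
) -> TissuePhantom:
    """Copy of ``phantom`` with an embedded inclusion."""
    return replace(
        phantom,
        inclusion=Inclusion(depth_fraction, thickness_fraction, youngs_modulus_e_inc),
    )
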