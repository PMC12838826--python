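"""Stiffness inversion, calibration fits, ranking, and operating pressure.

The contact model is the rigid flat cylindrical punch on an elastic
half-space,

    E = (1 - nu^2) / (2 a) * P / w,

and the acoustic link between indentation depth and the round-trip
time-of-flight difference is

    w = v * tau / 2.

Because tau is measured at a *fixed pressure differential*, it can serve
directly as a stiffness proxy without knowing the sound speed: a stiffer
tissue deforms less and shows a smaller tau.  The functions here cover
both uses — absolute modulus recovery when ``v`` is known, and fitting /
ranking of raw tau when it is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSweepError,
    InvalidInputError,
    NoSensitivityError,
)
from .synthetic_echo import Indenter
from .tof_estimation import TofMeasurement

__all__ = [
    "LinearFit",
    "SensitivityCurve",
    "hertz_modulus",
    "hertz_deformation",
    "tof_to_deformation",
    "deformation_to_tof",
    "estimate_modulus_from_sweep",
    "fit_tof_vs_load",
    "fit_tof_vs_hardness",
    "rank_stiffness",
    "sensitivity_curve",
    "select_operating_pressure",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line: slope, intercept, R^2, point count."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidInputError("a linear fit needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidInputError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class SensitivityCurve:
    """tau against applied pressure, with per-step rates of change.

    ``rate_of_change[i]`` is the first difference of tau over the step
    ``pressures[i] -> pressures[i + 1]`` divided by the pressure increment,
    so it has one fewer entry than the pressure grid.
    """

    pressures: tuple[float, ...]
    tau_vs_baseline: tuple[float, ...]
    rate_of_change: tuple[float, ...]


def hertz_modulus(p: float, w: float, a: float, nu: float) -> float:
    """Young's modulus from force and indentation depth (flat punch)."""
    if w <= 0:
        raise InvalidInputError("indentation depth must be > 0")
    if a <= 0:
        raise InvalidInputError("contact radius must be > 0")
    if not 0.0 <= nu <= 0.5:
        raise InvalidInputError("Poisson ratio must be in [0, 0.5]")
    return (1.0 - nu * nu) / (2.0 * a) * p / w


def hertz_deformation(p: float, e: float, a: float, nu: float) -> float:
    """Indentation depth from force and modulus; inverse of
    :func:`hertz_modulus`."""
    if e <= 0:
        raise InvalidInputError("Young's modulus must be > 0")
    if a <= 0:
        raise InvalidInputError("contact radius must be > 0")
    if not 0.0 <= nu <= 0.5:
        raise InvalidInputError("Poisson ratio must be in [0, 0.5]")
    return (1.0 - nu * nu) * p / (2.0 * a * e)


def tof_to_deformation(tau: float, v: float) -> float:
    """Indentation depth ``w = v tau / 2`` from a round-trip ToF difference."""
    if tau < 0:
        raise InvalidInputError(
            "negative tau violates the compression sign convention"
        )
    if v <= 0:
        raise InvalidInputError("sound speed must be > 0")
    return v * tau / 2.0


def deformation_to_tof(w: float, v: float) -> float:
    """Round-trip ToF difference ``tau = 2 w / v``; inverse of
    :func:`tof_to_deformation`."""
    if w < 0:
        raise InvalidInputError("deformation must be >= 0")
    if v <= 0:
        raise InvalidInputError("sound speed must be > 0")
    return 2.0 * w / v


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InvalidInputError("fit needs >= 2 (x, y) pairs of equal length")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise InvalidInputError("all x values identical; slope undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    # Constant y: define R^2 = 0 (the line explains no variance because
    # there is none).
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else 0.0
    return LinearFit(slope, intercept, float(np.clip(r2, 0.0, 1.0)), int(x.size))


def fit_tof_vs_load(loads, taus) -> LinearFit:
    """OLS fit of tau against applied load (N or kPa); the calibration line
    of a stepped-indentation sweep."""
    return _ols(np.asarray(loads), np.asarray(taus))


def fit_tof_vs_hardness(hardness_ha, taus) -> LinearFit:
    """OLS fit of tau against Shore A hardness.

    On a compliant-to-stiff phantom series at a fixed load differential the
    slope is negative: harder samples deform less and show smaller tau.
    """
    return _ols(np.asarray(hardness_ha), np.asarray(taus))


def estimate_modulus_from_sweep(
    measurements: list[TofMeasurement],
    v: float,
    indenter: Indenter,
    nu: float = 0.5,
) -> tuple[float, LinearFit]:
    """Recover Young's modulus from a ToF sweep with known sound speed.

    Each tau is converted to a depth ``w = v tau / 2`` and ``w`` is
    regressed on force *through the origin* (the flat-punch law forces a
    zero intercept); then ``E = (1 - nu^2) / (2 a slope)``.  Returns the
    modulus and the through-origin fit diagnostics (intercept fixed at 0,
    R^2 about the origin).
    """
    pairs = [
        (m.load_force_n, m.tof_difference_tau)
        for m in measurements
        if m.load_force_n is not None and m.load_force_n > 0
    ]
    if len(pairs) < 2:
        raise InvalidInputError(
            "need >= 2 measurements at non-zero load with recorded forces"
        )
    p = np.array([q[0] for q in pairs])
    w = np.array([tof_to_deformation(q[1], v) for q in pairs])
    denom = float(np.dot(p, p))
    slope = float(np.dot(p, w) / denom)
    if slope <= 0.0:
        raise DegenerateSweepError(
            "non-positive w-vs-P slope; the sweep carries no stiffness signal"
        )
    ss_res = float(np.sum((w - slope * p) ** 2))
    ss_tot = float(np.sum(w**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fit = LinearFit(slope, 0.0, float(np.clip(r2, 0.0, 1.0)), len(pairs))
    e = (1.0 - nu * nu) / (2.0 * indenter.contact_radius_a * slope)
    return e, fit


def rank_stiffness(named_taus: dict[str, float]) -> list[list[str]]:
    """Order labels from stiffest to most compliant by their tau.

    At a fixed load differential a smaller tau means less deformation,
    hence a stiffer sample.  Returns groups of labels: each inner list is
    one tie group (labels with exactly equal tau), ordered stiffest first.
    Ties are reported as a group rather than broken silently.
    """
    if not named_taus:
        raise InvalidInputError("need at least one labelled tau")
    for label, tau in named_taus.items():
        if tau < 0:
            raise InvalidInputError(f"negative tau for {label!r}")
    groups: dict[float, list[str]] = {}
    for label, tau in named_taus.items():
        groups.setdefault(float(tau), []).append(label)
    return [sorted(groups[tau]) for tau in sorted(groups)]


def sensitivity_curve(pressures, taus_vs_baseline) -> SensitivityCurve:
    """Rate of ToF-difference change over a stepped pressure escalation.

    The first pressure is the baseline (tau = 0 by construction); the rate
    over each step is the first difference of tau divided by the pressure
    increment.
    """
    p = np.asarray(pressures, dtype=float)
    t = np.asarray(taus_vs_baseline, dtype=float)
    if p.size != t.size or p.size < 2:
        raise InvalidInputError("need equal-length pressure and tau lists (>= 2)")
    if not np.all(np.diff(p) > 0):
        raise InvalidInputError("pressures must be strictly increasing")
    if abs(t[0]) > 1e-15:
        raise InvalidInputError("the first entry is the baseline; its tau must be 0")
    rates = np.diff(t) / np.diff(p)
    return SensitivityCurve(tuple(p), tuple(t), tuple(rates))


def select_operating_pressure(
    curve: SensitivityCurve, plateau_fraction: float = 0.25
) -> float:
    """Operating pressure at the knee of a sensitivity curve.

    Returns the largest pressure whose incoming rate of ToF change is
    still at least ``plateau_fraction`` of the maximum rate — the level
    just before the curve plateaus.  On a curve that is steep through some
    level and flat after, this is the end of the last steep step.
    """
    if len(curve.pressures) < 3:
        raise InvalidInputError("need at least 3 pressure levels")
    rates = np.asarray(curve.rate_of_change)
    r_max = float(rates.max())
    if r_max <= 0.0:
        raise NoSensitivityError("no positive rate of ToF change anywhere")
    keep = np.flatnonzero(rates >= plateau_fraction * r_max)
    return float(curve.pressures[int(keep[-1]) + 1])
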