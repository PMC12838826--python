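"""Time-of-flight difference estimation between baseline and loaded A-scans.

Two estimators are provided, both with sub-sample (3-point parabolic)
refinement:

``envelope_peak``
    Track the analytic-signal envelope maximum of the back-wall echo in a
    search window and difference the arrival times.

``xcorr``
    Normalised cross-correlation of the windowed echoes; the default and
    the more noise-robust of the two.

Sign convention: tau > 0 when the loaded echo arrives *earlier* than the
baseline echo, i.e. the sample was compressed.  All downstream stiffness
math assumes this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate, hilbert

from .errors import (
    AlignmentError,
    IncompatibleSignalsError,
    InvalidSignalError,
    InvalidWindowError,
)
from .synthetic_echo import AScan

__all__ = [
    "TofMeasurement",
    "AlignmentResult",
    "envelope",
    "peak_time",
    "xcorr_delay",
    "tof_difference",
    "align_signals",
    "default_search_window",
]

#: Fraction of the record duration where the default echo window starts,
#: chosen to exclude the surface echo at t ~ 0.
_WINDOW_START_FRACTION = 0.25

#: Default max correlation lag as a fraction of the window span.
_MAX_LAG_FRACTION = 0.45

#: Surface-echo detection level for alignment, fraction of the envelope max.
_SURFACE_THRESHOLD = 0.5


@dataclass(frozen=True)
class TofMeasurement:
    """An estimated ToF difference tau at one load, relative to baseline."""

    load_label: str
    tof_difference_tau: float
    method: str
    uncertainty: float | None = None
    load_force_n: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("envelope_peak", "xcorr"):
            raise InvalidSignalError(f"unknown ToF method {self.method!r}")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise InvalidSignalError("uncertainty must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """Per-signal time shifts applied to co-register surface echoes."""

    shifts: list[float]
    reference_label: str


def _samples(signal: AScan | np.ndarray) -> np.ndarray:
    if isinstance(signal, AScan):
        return signal.samples
    return np.asarray(signal, dtype=float)


def envelope(signal: AScan | np.ndarray) -> np.ndarray:
    """Analytic-signal (Hilbert) envelope, same length as the input."""
    x = _samples(signal)
    if x.size < 8:
        raise InvalidSignalError("signal too short for envelope estimation")
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains non-finite samples")
    return np.abs(hilbert(x))


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    """Sub-sample offset of a peak from its three surrounding samples."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (y_m1 - y_p1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def default_search_window(signal: AScan) -> tuple[float, float]:
    """Default echo window: the final 75% of the record.

    Excludes the surface echo near t = 0 so that only the back-wall echo
    is tracked.
    """
    t0 = signal.time_origin
    return (t0 + _WINDOW_START_FRACTION * signal.duration, t0 + signal.duration)


def _window_indices(signal: AScan, window: tuple[float, float]) -> tuple[int, int]:
    t_lo, t_hi = window
    if not t_hi > t_lo:
        raise InvalidWindowError("search window is empty")
    t = signal.times
    i0 = int(np.searchsorted(t, t_lo, side="left"))
    i1 = int(np.searchsorted(t, t_hi, side="right"))
    if i1 - i0 < 3:
        raise InvalidWindowError(
            f"search window ({t_lo:g}, {t_hi:g}) s lies outside the signal "
            "or spans fewer than 3 samples"
        )
    return i0, i1


def peak_time(signal: AScan, search_window: tuple[float, float]) -> float:
    """Arrival time of the envelope maximum inside a window, in seconds.

    The discrete argmax (earliest sample on ties) is refined by 3-point
    parabolic interpolation.  A window whose envelope is perfectly flat has
    no unambiguous peak and raises ``InvalidSignalError``.
    """
    i0, i1 = _window_indices(signal, search_window)
    env = envelope(signal)
    seg = env[i0:i1]
    if np.all(seg == seg[0]):
        raise InvalidSignalError(
            "envelope is flat inside the search window; no unambiguous peak"
        )
    k = int(np.argmax(seg))
    delta = 0.0
    if 0 < k < seg.size - 1:
        delta = _parabolic_offset(seg[k - 1], seg[k], seg[k + 1])
    t = signal.time_origin + (i0 + k + delta) / signal.sampling_rate
    return float(np.clip(t, search_window[0], search_window[1]))


def xcorr_delay(
    reference: AScan | np.ndarray,
    signal: AScan | np.ndarray,
    max_lag: float,
    sampling_rate: float | None = None,
) -> float:
    """Delay of ``signal`` relative to ``reference`` by normalised
    cross-correlation, in seconds.

    Positive lag means the signal's content arrives *later* than the
    reference's.  The correlation peak inside ``+-max_lag`` is refined by
    parabolic interpolation; an exact integer-sample shift of a common
    waveform is recovered exactly because the correlation is then a
    shifted autocorrelation, which is even about its peak.
    """
    if isinstance(reference, AScan) and isinstance(signal, AScan):
        if reference.sampling_rate != signal.sampling_rate:
            raise IncompatibleSignalsError(
                "sampling rates differ between reference and signal"
            )
        fs = reference.sampling_rate
        origin_offset = signal.time_origin - reference.time_origin
    else:
        if sampling_rate is None:
            raise IncompatibleSignalsError(
                "sampling_rate is required for plain-array inputs"
            )
        fs = sampling_rate
        origin_offset = 0.0

    ref = _samples(reference)
    sig = _samples(signal)
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(sig))):
        raise InvalidSignalError("signals contain non-finite samples")
    e_ref = float(np.dot(ref, ref))
    e_sig = float(np.dot(sig, sig))
    if e_ref == 0.0 or e_sig == 0.0:
        raise InvalidSignalError("zero-energy signal; delay is undefined")
    common_duration = min(ref.size, sig.size) / fs
    if not 0.0 < max_lag < 0.5 * common_duration:
        raise InvalidWindowError(
            "max_lag must be positive and below half the common duration"
        )

    c = correlate(sig, ref, mode="full") / np.sqrt(e_ref * e_sig)
    lags = (np.arange(c.size) - (ref.size - 1)) / fs + origin_offset
    mask = np.abs(lags) <= max_lag
    if not np.any(mask):
        raise InvalidWindowError("no correlation lags inside +-max_lag")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmax(c[idx]))]
    delta = 0.0
    if 0 < k < c.size - 1:
        delta = _parabolic_offset(c[k - 1], c[k], c[k + 1])
    return float((k - (ref.size - 1) + delta) / fs + origin_offset)


def _window_copy(signal: AScan, window: tuple[float, float]) -> AScan:
    i0, i1 = _window_indices(signal, window)
    return AScan(
        samples=signal.samples[i0:i1].copy(),
        sampling_rate=signal.sampling_rate,
        time_origin=signal.time_origin + i0 / signal.sampling_rate,
        load_label=signal.load_label,
        seed=signal.seed,
    )


def tof_difference(
    baseline: AScan,
    loaded: AScan,
    method: str = "xcorr",
    search_window: tuple[float, float] | None = None,
    max_lag: float | None = None,
    load_force_n: float | None = None,
) -> TofMeasurement:
    """ToF difference ``tau`` between a baseline and a loaded A-scan.

    ``tau = (back-echo arrival, baseline) - (back-echo arrival, loaded)``,
    so compression gives tau >= 0.  The estimate uses either envelope-peak
    arrival times or the negative cross-correlation lag of the windowed
    echoes; the method tag is recorded on the result.
    """
    if baseline.sampling_rate != loaded.sampling_rate:
        raise IncompatibleSignalsError("baseline and loaded sampling rates differ")
    if search_window is None:
        search_window = default_search_window(baseline)

    if method == "envelope_peak":
        tau = peak_time(baseline, search_window) - peak_time(loaded, search_window)
    elif method == "xcorr":
        ref_seg = _window_copy(baseline, search_window)
        sig_seg = _window_copy(loaded, search_window)
        if max_lag is None:
            max_lag = _MAX_LAG_FRACTION * (search_window[1] - search_window[0])
        tau = -xcorr_delay(ref_seg, sig_seg, max_lag)
    else:
        raise InvalidSignalError(f"unknown ToF method {method!r}")
    return TofMeasurement(
        load_label=loaded.load_label,
        tof_difference_tau=float(tau),
        method=method,
        load_force_n=load_force_n,
    )


def _shift_with_zero_fill(x: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[k:] = x[:-k]
    else:
        out[:k] = x[-k:]
    return out


def _surface_index(signal: AScan, threshold_fraction: float, label: str) -> int:
    env = envelope(signal)
    peak = float(env.max())
    if peak <= 0.0:
        raise AlignmentError(f"signal {label!r}: no surface echo above threshold")
    crossings = np.flatnonzero(env >= threshold_fraction * peak)
    return int(crossings[0])


def align_signals(
    signals: list[AScan],
    reference_index: int = 0,
    threshold_fraction: float = _SURFACE_THRESHOLD,
) -> tuple[AlignmentResult, list[AScan]]:
    """Co-register A-scans on their surface echoes.

    Each signal is shifted (integer samples, zero fill) so that its first
    envelope crossing above ``threshold_fraction`` of the envelope maximum
    coincides with the reference's.  The reference is never shifted.
    Returns the per-signal shifts (seconds) and the shifted copies.
    """
    if len(signals) < 2:
        raise InvalidSignalError("alignment needs at least two signals")
    fs = signals[0].sampling_rate
    if any(s.sampling_rate != fs for s in signals):
        raise IncompatibleSignalsError("signals have mixed sampling rates")

    reference = signals[reference_index]
    idx_ref = _surface_index(
        reference, threshold_fraction, reference.load_label or str(reference_index)
    )
    shifts: list[float] = []
    shifted: list[AScan] = []
    for j, s in enumerate(signals):
        idx = _surface_index(s, threshold_fraction, s.load_label or str(j))
        k = idx_ref - idx
        shifts.append(k / fs)
        shifted.append(
            AScan(
                samples=_shift_with_zero_fill(s.samples, k),
                sampling_rate=fs,
                time_origin=s.time_origin,
                load_label=s.load_label,
                seed=s.seed,
            )
        )
    return (
        AlignmentResult(
            shifts=shifts,
            reference_label=reference.load_label or str(reference_index),
        ),
        shifted,
    )
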