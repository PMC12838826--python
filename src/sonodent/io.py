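"""Readers and writers for sonodent's on-disk formats.

A-scans travel as two-column CSV (``time_s,amplitude``, or headerless with
an explicit sampling rate), ToF measurements as CSV tables in display
units (kPa / microseconds), and fits, rankings and screen results as JSON.
Configuration files are JSON with SI units; the key layout is documented
in ``docs/config_schema.md``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .lesion_screening import LesionScreenResult
from .stiffness_model import LinearFit
from .synthetic_echo import (
    AScan,
    Inclusion,
    Indenter,
    LoadStep,
    PulseModel,
    TissuePhantom,
)
from .tof_estimation import TofMeasurement

__all__ = [
    "write_ascan_csv",
    "read_ascan_csv",
    "write_tof_csv",
    "read_tof_csv",
    "write_fit_json",
    "write_ranking_json",
    "write_screen_json",
    "read_config",
    "parse_pulse",
    "parse_indenter",
    "parse_phantom",
    "parse_loads",
    "parse_load_spec",
]


def write_ascan_csv(ascan: AScan, path, header: bool = True) -> None:
    """Write an A-scan as ``time_s,amplitude`` CSV (headerless on request)."""
    df = pd.DataFrame({"time_s": ascan.times, "amplitude": ascan.samples})
    df.to_csv(path, index=False, header=header, float_format="%.9g")


def read_ascan_csv(path, load_label: str | None = None) -> AScan:
    """Read an A-scan CSV (with or without header); sampling rate is
    inferred from the median sample spacing."""
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 0], str)
    df = pd.read_csv(path, header=0 if has_header else None)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError(f"{path}: need at least 2 samples")
    dt = float(t[-1] - t[0]) / (t.size - 1)
    if dt <= 0:
        raise InvalidInputError(f"{path}: time column must be increasing")
    # round to 9 significant digits so re-read signals compare as
    # having identical rates despite CSV float formatting
    sampling_rate = float(f"{1.0 / dt:.9g}")
    return AScan(
        samples=x,
        sampling_rate=sampling_rate,
        time_origin=float(t[0]),
        load_label=load_label or Path(path).stem,
    )


def write_tof_csv(measurements: list[TofMeasurement], path,
                  pressures_kpa: list[float] | None = None) -> None:
    """Write ToF measurements as CSV in display units (kPa, microseconds)."""
    rows = []
    for i, m in enumerate(measurements):
        rows.append(
            {
                "load_label": m.load_label,
                "pressure_kPa": (
                    pressures_kpa[i] if pressures_kpa is not None else np.nan
                ),
                "force_N": m.load_force_n if m.load_force_n is not None else np.nan,
                "tau_us": m.tof_difference_tau * 1e6,
                "method": m.method,
                "uncertainty_us": (
                    m.uncertainty * 1e6 if m.uncertainty is not None else np.nan
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_tof_csv(path) -> list[TofMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        force = row.get("force_N", np.nan)
        unc = row.get("uncertainty_us", np.nan)
        out.append(
            TofMeasurement(
                load_label=str(row["load_label"]),
                tof_difference_tau=float(row["tau_us"]) * 1e-6,
                method=str(row["method"]),
                uncertainty=None if pd.isna(unc) else float(unc) * 1e-6,
                load_force_n=None if pd.isna(force) else float(force),
            )
        )
    return out


def write_fit_json(fit: LinearFit, path, **extra) -> None:
    payload = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n": fit.n_points,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_ranking_json(groups: list[list[str]], path, **extra) -> None:
    payload = {"stiffest_first": groups, **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_screen_json(result: LesionScreenResult, path, **extra) -> None:
    payload = {
        "reference": dataclasses.asdict(result.tau_reference),
        "test": dataclasses.asdict(result.tau_test),
        "relative_reduction": result.relative_reduction,
        "separated": result.separated,
        "flagged": result.flagged,
        "low_confidence": result.low_confidence,
        "method": result.method,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# JSON configuration (SI units throughout; see docs/config_schema.md)

def read_config(path) -> dict:
    return json.loads(Path(path).read_text())


def parse_pulse(cfg: dict) -> PulseModel:
    return PulseModel(
        center_frequency=cfg.get("center_frequency_hz", 2.0e6),
        fractional_bandwidth=cfg.get("fractional_bandwidth", 0.6),
        amplitude=cfg.get("amplitude", 1.0),
    )


def parse_indenter(cfg: dict) -> Indenter:
    return Indenter(contact_radius_a=cfg.get("contact_radius_m", 0.01))


def parse_phantom(cfg: dict) -> TissuePhantom:
    inc_cfg = cfg.get("inclusion")
    inclusion = None
    if inc_cfg:
        inclusion = Inclusion(
            depth_fraction=inc_cfg["depth_fraction"],
            thickness_fraction=inc_cfg["thickness_fraction"],
            youngs_modulus_e_inc=inc_cfg["youngs_modulus_pa"],
        )
    return TissuePhantom(
        thickness_h=cfg["thickness_m"],
        sound_speed_v=cfg["sound_speed_m_s"],
        youngs_modulus_e=cfg["youngs_modulus_pa"],
        poisson_ratio_nu=cfg.get("poisson_ratio", 0.5),
        attenuation_alpha=cfg.get("attenuation_db_cm_mhz", 0.5),
        stiffening_beta=cfg.get("stiffening_beta", 0.0),
        inclusion=inclusion,
    )


def parse_loads(items: list[dict]) -> list[LoadStep]:
    steps = []
    for item in items:
        steps.append(
            LoadStep(
                label=item["label"],
                applied_pressure=item.get("pressure_pa"),
                applied_force_p=item.get("force_n"),
            )
        )
    return steps


def parse_load_spec(spec: str) -> list[LoadStep]:
    """Parse a CLI load range like ``0:35:5N`` or ``1:7:1kPa``.

    The format is ``start:stop:step`` followed by a unit (``N`` or
    ``kPa``); the stop value is included.
    """
    spec = spec.strip()
    if spec.endswith("kPa"):
        unit, scale, key = "kPa", 1e3, "pressure"
    elif spec.endswith("N"):
        unit, scale, key = "N", 1.0, "force"
    else:
        raise InvalidInputError(f"load spec {spec!r} must end in 'N' or 'kPa'")
    body = spec[: -len(unit)]
    parts = body.split(":")
    if len(parts) != 3:
        raise InvalidInputError(f"load spec {spec!r} must be start:stop:step<unit>")
    start, stop, step = (float(p) for p in parts)
    if step <= 0 or stop < start:
        raise InvalidInputError(f"load spec {spec!r} has an empty range")
    values = np.arange(start, stop + 0.5 * step, step)
    steps = []
    for v in values:
        label = f"{v:g}{unit}"
        if key == "force":
            steps.append(LoadStep(label=label, applied_force_p=float(v)))
        else:
            steps.append(LoadStep(label=label, applied_pressure=float(v) * scale))
    return steps
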