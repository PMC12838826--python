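"""End-to-end experiment orchestration: simulate -> estimate -> analyse.

An :class:`ExperimentConfig` (usually loaded from JSON) names one or more
phantoms, an indenter, a pulse, and a stepped load protocol.
:func:`run_experiment` simulates the sweep for every phantom, estimates
per-load ToF differences against the first (baseline) load, fits the
calibration line, optionally recovers the modulus, ranks the phantoms at
the top load, and runs the lesion screen when configured.  Everything is
deterministic given the config seed, and the seed plus the full config
are echoed into the report.

:func:`generate_fixtures` writes five named scenario bundles that mirror
the experiment families of the measurement protocol: a silicone hardness
series, a force sweep, a strain-stiffening ex vivo trio, a lesion pair,
and a relaxed/contracted muscle pair.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

from . import io as sio
from .errors import (
    InvalidInputError,
    NoSensitivityError,
    SonodentError,
)
from .lesion_screening import LesionScreenResult, screen_from_signals
from .stiffness_model import (
    LinearFit,
    estimate_modulus_from_sweep,
    fit_tof_vs_hardness,
    fit_tof_vs_load,
    rank_stiffness,
    select_operating_pressure,
    sensitivity_curve,
)
from .synthetic_echo import (
    Indenter,
    LoadStep,
    PulseModel,
    TissuePhantom,
    derive_seed,
    shore_to_young,
    simulate_ascan,
    simulate_sweep,
    with_inclusion,
)
from .tof_estimation import tof_difference

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "generate_fixtures",
    "scenario_configs",
    "SCENARIO_NAMES",
]

__version__ = "0.1.0"

SCENARIO_NAMES = (
    "silicone_hardness_series",
    "force_sweep",
    "exvivo_nonlinear",
    "lesion_pair",
    "muscle_states",
)


@dataclass
class ExperimentConfig:
    """Fully resolved experiment description (SI units)."""

    name: str
    phantoms: dict[str, TissuePhantom]
    loads: list[LoadStep]
    indenter: Indenter = field(default_factory=Indenter)
    pulse: PulseModel = field(default_factory=PulseModel)
    sampling_rate: float = 50e6
    snr_db: float | None = None
    method: str = "xcorr"
    seed: int = 0
    shore_hardness: dict[str, float] = field(default_factory=dict)
    estimate_modulus: bool = False
    screen: dict | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentConfig":
        phantoms = {
            label: sio.parse_phantom(p) for label, p in cfg["phantoms"].items()
        }
        hardness = {
            label: p["shore_hardness_ha"]
            for label, p in cfg["phantoms"].items()
            if "shore_hardness_ha" in p
        }
        analysis = cfg.get("analysis", {})
        return cls(
            name=cfg.get("name", "experiment"),
            phantoms=phantoms,
            loads=sio.parse_loads(cfg["loads"]),
            indenter=sio.parse_indenter(cfg.get("indenter", {})),
            pulse=sio.parse_pulse(cfg.get("pulse", {})),
            sampling_rate=cfg.get("sampling_rate_hz", 50e6),
            snr_db=cfg.get("snr_db"),
            method=cfg.get("method", "xcorr"),
            seed=cfg.get("seed", 0),
            shore_hardness=hardness,
            estimate_modulus=analysis.get("estimate_modulus", False),
            screen=analysis.get("screen"),
            raw=cfg,
        )

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        return cls.from_dict(sio.read_config(path))


@dataclass
class ExperimentReport:
    """All results of one experiment run, traceable to config + seed."""

    name: str
    seed: int
    version: str
    config: dict
    phantoms: dict[str, dict]
    ranking: list[list[str]] | None
    hardness_fit: dict | None
    screen: dict | None
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fit_to_dict(fit: LinearFit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n": fit.n_points,
    }


def _screen_to_dict(result: LesionScreenResult) -> dict:
    return {
        "reference": dataclasses.asdict(result.tau_reference),
        "test": dataclasses.asdict(result.tau_test),
        "relative_reduction": result.relative_reduction,
        "separated": result.separated,
        "flagged": result.flagged,
        "low_confidence": result.low_confidence,
        "method": result.method,
    }


def _load_axis(config: ExperimentConfig) -> tuple[list[float], str]:
    """x values for the calibration fit: forces in N, or pressures in kPa
    when the protocol is pressure-specified."""
    if all(step.applied_pressure is not None for step in config.loads):
        return [step.applied_pressure / 1e3 for step in config.loads], "kPa"
    return [step.resolve_force(config.indenter) for step in config.loads], "N"


def _run_phantom(
    config: ExperimentConfig, label: str, phantom: TissuePhantom, index: int
) -> tuple[dict, list, float]:
    scans = simulate_sweep(
        phantom,
        config.indenter,
        config.loads,
        pulse=config.pulse,
        sampling_rate=config.sampling_rate,
        snr_db=config.snr_db,
        seed=derive_seed(config.seed, 1000 + index),
    )
    forces = [step.resolve_force(config.indenter) for step in config.loads]
    measurements = [
        tof_difference(scans[0], scan, method=config.method, load_force_n=force)
        for scan, force in zip(scans, forces)
    ]
    xs, unit = _load_axis(config)
    fit = fit_tof_vs_load(xs, [m.tof_difference_tau for m in measurements])
    result = {
        "load_labels": [m.load_label for m in measurements],
        "load_axis": xs,
        "load_axis_unit": unit,
        "taus_us": [m.tof_difference_tau * 1e6 for m in measurements],
        "method": config.method,
        "fit_tau_vs_load": _fit_to_dict(fit),
        "modulus_pa": None,
        "modulus_fit": None,
        "sensitivity": None,
    }
    if config.estimate_modulus:
        e_hat, mfit = estimate_modulus_from_sweep(
            measurements,
            v=phantom.sound_speed_v,
            indenter=config.indenter,
            nu=phantom.poisson_ratio_nu,
        )
        result["modulus_pa"] = e_hat
        result["modulus_fit"] = _fit_to_dict(mfit)
    if unit == "kPa" and len(xs) >= 3:
        curve = sensitivity_curve(xs, [m.tof_difference_tau for m in measurements])
        try:
            knee = select_operating_pressure(curve)
        except NoSensitivityError:
            knee = None
        result["sensitivity"] = {
            "pressures_kpa": list(curve.pressures),
            "tau_us": [t * 1e6 for t in curve.tau_vs_baseline],
            "rate_us_per_kpa": [r * 1e6 for r in curve.rate_of_change],
            "operating_pressure_kpa": knee,
        }
    return result, measurements, measurements[-1].tof_difference_tau


def _run_screen(config: ExperimentConfig) -> dict:
    spec = config.screen
    for key in ("reference", "test"):
        if spec.get(key) not in config.phantoms:
            raise InvalidInputError(f"screen {key} phantom not in config")
    n_rep = int(spec.get("n_repeats", 8))
    baseline = config.loads[0]
    loaded = config.loads[-1]

    def _pairs(label: str, salt: int) -> list:
        phantom = config.phantoms[label]
        pairs = []
        for r in range(n_rep):
            kwargs = dict(
                pulse=config.pulse,
                sampling_rate=config.sampling_rate,
                snr_db=config.snr_db,
            )
            b = simulate_ascan(
                phantom, config.indenter, baseline,
                seed=derive_seed(config.seed, salt + 2 * r), **kwargs,
            )
            l = simulate_ascan(
                phantom, config.indenter, loaded,
                seed=derive_seed(config.seed, salt + 2 * r + 1), **kwargs,
            )
            pairs.append((b, l))
        return pairs

    result = screen_from_signals(
        _pairs(spec["reference"], salt=50_000),
        _pairs(spec["test"], salt=60_000),
        method=config.method,
        min_relative_reduction=spec.get("min_relative_reduction", 0.2),
    )
    return _screen_to_dict(result)


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    write_signals: bool = False,
) -> ExperimentReport:
    """Run a full experiment and optionally write its artefacts.

    Deterministic given ``config.seed``: reruns produce identical reports
    except for the timestamp field.  When ``out_dir`` is given, per-phantom
    ToF tables (CSV), the report (JSON) and, on request, every simulated
    A-scan (CSV) are written there.
    """
    logger.info(
        "experiment %r: %d phantom(s), %d load step(s), method=%s, seed=%d",
        config.name, len(config.phantoms), len(config.loads),
        config.method, config.seed,
    )
    phantom_results: dict[str, dict] = {}
    top_taus: dict[str, float] = {}
    all_scans: dict[str, list] = {}
    for index, (label, phantom) in enumerate(sorted(config.phantoms.items())):
        logger.info("stage simulate+estimate: phantom %r", label)
        result, measurements, top_tau = _run_phantom(config, label, phantom, index)
        phantom_results[label] = result
        top_taus[label] = max(top_tau, 0.0)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            sio.write_tof_csv(measurements, out / f"tof__{label}.csv")
            if write_signals:
                sig_dir = out / "signals"
                sig_dir.mkdir(exist_ok=True)
                scans = simulate_sweep(
                    phantom, config.indenter, config.loads,
                    pulse=config.pulse, sampling_rate=config.sampling_rate,
                    snr_db=config.snr_db,
                    seed=derive_seed(config.seed, 1000 + index),
                )
                for scan in scans:
                    sio.write_ascan_csv(
                        scan, sig_dir / f"{label}__{scan.load_label}.csv"
                    )
        all_scans[label] = measurements

    ranking = rank_stiffness(top_taus) if len(top_taus) >= 2 else None

    hardness_fit = None
    if len(config.shore_hardness) >= 2:
        labels = sorted(config.shore_hardness)
        hardness_fit = _fit_to_dict(
            fit_tof_vs_hardness(
                [config.shore_hardness[lb] for lb in labels],
                [top_taus[lb] for lb in labels],
            )
        )

    screen_result = None
    if config.screen:
        logger.info("stage screen: %r vs %r",
                    config.screen.get("reference"), config.screen.get("test"))
        screen_result = _run_screen(config)

    report = ExperimentReport(
        name=config.name,
        seed=config.seed,
        version=__version__,
        config=config.raw or _echo_config(config),
        phantoms=phantom_results,
        ranking=ranking,
        hardness_fit=hardness_fit,
        screen=screen_result,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    if out_dir is not None:
        (Path(out_dir) / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
    return report


def _echo_config(config: ExperimentConfig) -> dict:
    """Serialise a programmatically built config so no default is silent."""
    return {
        "name": config.name,
        "seed": config.seed,
        "sampling_rate_hz": config.sampling_rate,
        "snr_db": config.snr_db,
        "method": config.method,
        "pulse": dataclasses.asdict(config.pulse),
        "indenter": {"contact_radius_m": config.indenter.contact_radius_a},
        "phantoms": {
            lb: dataclasses.asdict(ph) for lb, ph in config.phantoms.items()
        },
        "loads": [dataclasses.asdict(step) for step in config.loads],
        "analysis": {
            "estimate_modulus": config.estimate_modulus,
            "screen": config.screen,
        },
    }


# ---------------------------------------------------------------------------
# Scenario fixtures

def _phantom_cfg(
    e_pa: float,
    thickness_m: float,
    sound_speed: float,
    beta: float = 0.0,
    hardness: float | None = None,
    inclusion: dict | None = None,
) -> dict:
    cfg = {
        "thickness_m": thickness_m,
        "sound_speed_m_s": sound_speed,
        "youngs_modulus_pa": e_pa,
        "poisson_ratio": 0.5,
        "attenuation_db_cm_mhz": 0.5,
        "stiffening_beta": beta,
    }
    if hardness is not None:
        cfg["shore_hardness_ha"] = hardness
    if inclusion is not None:
        cfg["inclusion"] = inclusion
    return cfg


def _force_loads(values) -> list[dict]:
    return [{"label": f"{v:g}N", "force_n": float(v)} for v in values]


def _pressure_loads(values_kpa) -> list[dict]:
    return [
        {"label": f"{v:g}kPa", "pressure_pa": float(v) * 1e3} for v in values_kpa
    ]


def scenario_configs(seed: int = 0) -> dict[str, dict]:
    """The five bundled scenario configurations, as plain config dicts.

    Each mirrors one experiment family: the silicone Shore-hardness series
    (0-60 HA, 0/15 N), the 0-35 N force sweep on a 10 HA sample, three
    strain-stiffening ex vivo tissues under 0-10 N, a host-vs-inclusion
    lesion pair at a matched 3 N load, and a relaxed/contracted muscle
    pair under a 1-5 kPa pressure escalation.
    """
    silicone_v = 1000.0  # m/s, soft silicone rubber
    tissue_v = 1540.0  # m/s, soft-tissue reference

    hardness_series = {
        f"HA{int(s):02d}": _phantom_cfg(
            shore_to_young(s), 0.010, silicone_v, hardness=float(s)
        )
        for s in range(0, 61, 10)
    }
    exvivo = {
        "bovine_lean": _phantom_cfg(45e3, 0.030, 1580.0, beta=3.0),
        "porcine_lean": _phantom_cfg(25e3, 0.030, 1540.0, beta=3.0),
        "porcine_fat": _phantom_cfg(12e3, 0.030, 1450.0, beta=3.0),
    }
    lesion_inclusion = {
        "depth_fraction": 0.3,
        "thickness_fraction": 0.35,
        "youngs_modulus_pa": 250e3,
    }
    return {
        "silicone_hardness_series": {
            "name": "silicone_hardness_series",
            "seed": derive_seed(seed, 1),
            "snr_db": 30.0,
            "method": "xcorr",
            "phantoms": hardness_series,
            "loads": _force_loads([0, 15]),
        },
        "force_sweep": {
            "name": "force_sweep",
            "seed": derive_seed(seed, 2),
            "snr_db": 30.0,
            "method": "xcorr",
            "phantoms": {
                "HA10": _phantom_cfg(
                    shore_to_young(10.0), 0.010, silicone_v, hardness=10.0
                )
            },
            "loads": _force_loads(range(0, 36, 5)),
            "analysis": {"estimate_modulus": True},
        },
        "exvivo_nonlinear": {
            "name": "exvivo_nonlinear",
            "seed": derive_seed(seed, 3),
            # noise-free: this bundle characterises the compression law
            # itself (concave tau(P)), not estimator robustness
            "snr_db": None,
            "method": "envelope_peak",
            "phantoms": exvivo,
            "loads": _force_loads(range(0, 11)),
        },
        "lesion_pair": {
            "name": "lesion_pair",
            "seed": derive_seed(seed, 4),
            "snr_db": 25.0,
            "method": "xcorr",
            "phantoms": {
                "host": _phantom_cfg(25e3, 0.030, tissue_v),
                "host_with_inclusion": _phantom_cfg(
                    25e3, 0.030, tissue_v, inclusion=lesion_inclusion
                ),
            },
            "loads": _force_loads([0, 3]),
            "analysis": {
                "screen": {
                    "reference": "host",
                    "test": "host_with_inclusion",
                    "n_repeats": 8,
                    "min_relative_reduction": 0.2,
                }
            },
        },
        "muscle_states": {
            "name": "muscle_states",
            "seed": derive_seed(seed, 5),
            "snr_db": 30.0,
            "method": "xcorr",
            "phantoms": {
                "relaxed": _phantom_cfg(15e3, 0.040, tissue_v),
                "contracted": _phantom_cfg(45e3, 0.040, tissue_v),
            },
            "loads": _pressure_loads([1, 2, 3, 4, 5]),
        },
    }


def generate_fixtures(
    out_dir: str | Path, seed: int = 0, force: bool = False
) -> Path:
    """Write the five scenario bundles (configs, signals, reports) to disk.

    Refuses to write into an existing non-empty directory unless ``force``
    is set.  Returns the path of the manifest file.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise SonodentError(
            f"{out} exists and is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    scenarios = scenario_configs(seed)
    for name, cfg in scenarios.items():
        scenario_dir = out / name
        scenario_dir.mkdir(parents=True, exist_ok=True)
        (scenario_dir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
        run_experiment(
            ExperimentConfig.from_dict(cfg), out_dir=scenario_dir,
            write_signals=True,
        )
    manifest = {"seed": seed, "scenarios": sorted(scenarios)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
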