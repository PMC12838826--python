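# Configuration file schema

All configuration files are JSON with SI units (m, Pa, Hz, N, s).

## Experiment config (`sonodent run --config`)

```json
{
  "name": "force_sweep",
  "seed": 42,
  "sampling_rate_hz": 5e7,
  "snr_db": 30.0,
  "method": "xcorr",
  "pulse": {
    "center_frequency_hz": 2e6,
    "fractional_bandwidth": 0.6,
    "amplitude": 1.0
  },
  "indenter": { "contact_radius_m": 0.01 },
  "phantoms": {
    "HA10": {
      "thickness_m": 0.010,
      "sound_speed_m_s": 1000.0,
      "youngs_modulus_pa": 412683.0,
      "poisson_ratio": 0.5,
      "attenuation_db_cm_mhz": 0.5,
      "stiffening_beta": 0.0,
      "shore_hardness_ha": 10.0,
      "inclusion": {
        "depth_fraction": 0.3,
        "thickness_fraction": 0.35,
        "youngs_modulus_pa": 250000.0
      }
    }
  },
  "loads": [
    { "label": "0N", "force_n": 0.0 },
    { "label": "1kPa", "pressure_pa": 1000.0 }
  ],
  "analysis": {
    "estimate_modulus": true,
    "screen": {
      "reference": "host",
      "test": "host_with_inclusion",
      "n_repeats": 8,
      "min_relative_reduction": 0.2
    }
  }
}
```

Notes:

- Every load step needs a `label` and at least one of `force_n` /
  `pressure_pa`; pressure maps to force through the indenter contact area.
  The first load step is the baseline and must be the lowest.
- `snr_db` is peak-signal-to-noise (dB); `null` or omitted means
  noise-free. `seed` drives every random stream deterministically.
- `method` is `"xcorr"` or `"envelope_peak"`.
- `shore_hardness_ha` and `inclusion` are optional per phantom;
  `analysis` and all its members are optional.

## Phantom config (`sonodent simulate --config`)

Either a bare phantom object (the keys of one `phantoms` entry above) or
`{"phantom": {...}, "indenter": {...}, "pulse": {...},
"sampling_rate_hz": ...}`.

## A-scan CSV

`time_s,amplitude` with header (default) or headerless two-column
(`--no-header`). One file per load step, named `<label>.csv`.

## ToF CSV

Columns `load_label,pressure_kPa,force_N,tau_us,method,uncertainty_us`;
display units (kPa, microseconds), missing values empty.
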