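# sonodent

**Ultrasonic-indentation stiffness sensing, in software.**

Soft-tissue stiffness changes with muscle state, fatigue, inflammation and
many pathologies, but the clinical standard — manual palpation — is
subjective and poorly reproducible. A compact alternative uses a
single-element pulse-echo transducer whose flat face doubles as an
indenter: pressing it into the tissue with a controlled pressure thins the
tissue column, the back-wall echo returns earlier, and the round-trip
time-of-flight (ToF) difference τ between loaded and baseline states
becomes a quantitative stiffness proxy.

`sonodent` implements the complete analysis chain for this measurement,
with a physics-based synthetic signal generator standing in for the
wearable hardware. It is aimed at researchers developing or validating
indentation-based stiffness sensors who need a tested, reproducible
reference implementation of the signal processing and inversion.

## The model

For a rigid flat cylindrical punch of radius *a* indenting an elastic
half-space (Young's modulus *E*, Poisson's ratio *ν*) with force *P* to a
depth *w*:

```
E = (1 − ν²) / (2a) · P / w
```

and the acoustic link between depth and the round-trip ToF difference at
sound speed *v*:

```
w = v · τ / 2
```

So at a fixed pressure differential, a stiffer tissue deforms less and
shows a smaller τ — a comparison that needs no knowledge of *v*. With *v*
known, a stepped load sweep lets the package recover *E* absolutely by
regressing *w* on *P* through the origin.

The package has five parts:

| module | what it does |
|---|---|
| `synthetic_echo` | seeded A-mode echo simulation: Gabor pulses, two-interface geometry, attenuation, flat-punch mechanics with optional strain stiffening and stiff inclusions |
| `tof_estimation` | sub-sample ToF difference estimation (envelope peak and normalised cross-correlation), surface-echo alignment |
| `stiffness_model` | contact-law inversion, calibration fits, stiffness ranking, sensitivity-curve knee (operating pressure) |
| `lesion_screening` | repeated-measurement statistics and a reproducible stiffening screen |
| `pipeline` / `cli` | end-to-end experiments, scenario fixtures, and the `sonodent` command line |

## Worked example

Simulate a stepped indentation sweep of a 30 mm, 10 kPa tissue block at
30 dB SNR, estimate the ToF differences, and recover the modulus:

```python
from sonodent import (Indenter, TissuePhantom, LoadStep, simulate_sweep,
                      tof_difference, estimate_modulus_from_sweep,
                      fit_tof_vs_load)

indenter = Indenter(contact_radius_a=0.01)          # 10 mm transducer face
phantom = TissuePhantom(thickness_h=0.03, sound_speed_v=1540.0,
                        youngs_modulus_e=10e3)      # 30 mm, 10 kPa block
forces = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4]   # N
loads = [LoadStep(f"{f:g}N", applied_force_p=f) for f in forces]

scans = simulate_sweep(phantom, indenter, loads, snr_db=30.0, seed=42)
measurements = [tof_difference(scans[0], s, load_force_n=f)
                for s, f in zip(scans, forces)]
for m in measurements:
    print(f"{m.load_label:>6}  tau = {m.tof_difference_tau*1e6:6.3f} us")

fit = fit_tof_vs_load(forces, [m.tof_difference_tau for m in measurements])
print(f"slope = {fit.slope*1e6:.3f} us/N, R^2 = {fit.r_squared:.5f}")

e_hat, _ = estimate_modulus_from_sweep(measurements, v=1540.0,
                                       indenter=indenter)
print(f"recovered E = {e_hat/1e3:.2f} kPa")
```

Output:

```
    0N  tau = -0.000 us
  0.2N  tau =  0.976 us
  0.4N  tau =  1.951 us
  0.6N  tau =  2.923 us
  0.8N  tau =  3.898 us
    1N  tau =  4.874 us
  1.2N  tau =  5.844 us
  1.4N  tau =  6.818 us
slope = 4.870 us/N, R^2 = 1.00000
recovered E = 10.00 kPa
```

τ grows linearly with load (this phantom is linear-elastic), the
calibration line is essentially perfect at this noise level, and the
inversion returns the configured 10 kPa. Each 0.2 N step compresses the
block by about 0.75 mm, i.e. ~0.97 μs of round-trip advance at 1540 m/s.

The same chain is available from the shell:

```
sonodent fixtures --out fx/ --seed 0            # five scenario bundles
sonodent run --config fx/force_sweep/config.json --out out/
sonodent estimate --baseline b.csv --loaded l1.csv --out tof.csv
sonodent lesion --reference ref.csv --test test.csv --out screen.json
```

Config formats are documented in `docs/config_schema.md`; the modelling
choices and their limits in `docs/methods.md`.

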