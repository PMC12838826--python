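# Methods

## The measurement principle

A single-element pulse-echo transducer whose flat circular face doubles as
an indenter is pressed into soft tissue with a controlled force or cuff
pressure. Compression thins the tissue column under the face, so the echo
from the far interface returns earlier. With sound speed *v* and an
indentation depth *w*, the round-trip time-of-flight (ToF) difference
between the loaded state and a low-load baseline is

    tau = 2 w / v,        i.e.   w = v tau / 2.

The contact mechanics of a rigid flat cylindrical punch of radius *a* on an
elastic half-space relate force *P*, depth *w* and Young's modulus *E*:

    E = (1 - nu^2) / (2 a) * P / w,

with Poisson's ratio *nu* (0.5 by default: incompressible soft tissue).
Combining the two, tau measured at a fixed pressure differential is a
monotone proxy for compliance — a stiffer tissue deforms less and shows a
smaller tau — and this proxy works without knowing *v*, since *v* cancels
from any comparison at matched loads within the same tissue. Absolute
modulus recovery, by contrast, requires *v* as an explicit input, and the
package keeps that requirement explicit rather than assuming a value.

## The synthetic A-scan generator

`synthetic_echo` replaces the wearable hardware. Its model is deliberately
minimal, because the analysis chain only ever uses one tracked echo's
arrival time:

- **Pulse.** A Gabor pulse (Gaussian-windowed sinusoid), default 2 MHz
  centre frequency and 0.6 fractional (-6 dB) bandwidth, rendered with a
  sine carrier so the sampled waveform is exactly zero-mean; peak amplitude
  is normalised to the configured value.
- **Geometry.** One-dimensional, two interfaces: a fixed-amplitude surface
  echo at t = 0 and a back-wall echo at `2 (h - w) / v`. No multiple
  reflections, no diffraction, no beam profile. The echo is evaluated in
  continuous time on the sample grid, so arrival times are not quantised
  to samples.
- **Attenuation.** Amplitude factor `10^(-alpha d_cm f_MHz / 20)` over the
  round-trip path, default alpha = 0.5 dB/(cm MHz), a soft-tissue textbook
  value. Attenuation affects amplitude only, never timing.
- **Mechanics.** Linear flat-punch compression `w = (1 - nu^2) P / (2 a E)`
  with an optional single-coefficient strain-stiffening extension
  `P = 2 a E w (1 + beta w / h) / (1 - nu^2)`, solved by bisection on
  `[0, 0.95 h]` to 1e-10 relative tolerance. `beta = 0` recovers the linear
  law exactly; `beta > 0` produces the concave tau(P) seen in real tissue.
  Depth is capped at 95% of the resting thickness with an explicit
  bottomed-out flag, since the contact model is meaningless near full
  compression.
- **Inclusions.** A stiff (or soft) layer at a given depth/thickness
  fraction stiffens the column through a series-spring composite,
  `E_eff = 1 / (f_host/E + f_inc/E_inc)`. The inclusion has no acoustic
  signature of its own — only its mechanical effect on *w* is modelled,
  which is the quantity the screening method actually uses.
- **Loads.** A step is specified as force (N) or applied pressure (Pa);
  pressure maps to force through the indenter contact area `pi a^2`. This
  is the physically minimal mapping and is isolated in one function
  (`LoadStep.resolve_force`) so an alternative (e.g. chamber-area) mapping
  is a one-line change.
- **Noise and seeding.** Additive white Gaussian noise calibrated to peak
  SNR: `20 log10(peak / rms_noise) = snr_db`. Sweep scans derive per-load
  seeds from a base seed and the load index through `SeedSequence`, so any
  run is bit-reproducible from its config and seed.
- **Shore hardness.** Silicone-like calibration phantoms are
  parameterised through the Gent relation
  `E(MPa) = 0.0981 (56 + 7.62336 S) / (0.137505 (254 - 2.54 S))`. This is
  simulator metadata — a standard durometer-to-modulus conversion — not a
  measured property of any sample.

What the generator does *not* emulate: transducer ring-down, couplant and
standoff variation, substrate (finite-thickness) stiffening under large
strain, viscoelasticity (creep/hysteresis), anisotropy, speckle from
internal scatterers, and B-mode imaging. Tests passing on this generator
therefore demonstrate the correctness of the estimation and inversion
chain under the stated elastic model, not the behaviour of the method on
real tissue.

## ToF estimation

The estimator is intentionally redundant — two methods with a recorded
method tag:

- `envelope_peak`: time of the analytic-signal (Hilbert) envelope maximum
  in a search window, refined by 3-point parabolic interpolation. Handles
  arbitrarily large shifts; more noise-sensitive because a broad envelope
  peak localises poorly.
- `xcorr` (default): normalised cross-correlation of the windowed echoes,
  parabolic sub-sample refinement of the correlation peak. More
  noise-robust, but the recoverable shift is bounded by `max_lag` (which
  must stay below half the window span), so very large strains are better
  served by `envelope_peak`.

Numerical conventions: the default echo window is the final 75% of the
record, excluding the surface echo; `max_lag` defaults to 0.45 of the
window span; discrete argmax ties break toward the earliest sample, and a
perfectly flat window is an error rather than a silent pick; parabolic
offsets are clamped to half a sample. Sign convention throughout:
tau > 0 when the loaded echo arrives earlier (compression).

Alignment (`align_signals`) co-registers scans on the first envelope
crossing above half the per-signal envelope maximum — a surface-echo
reference that is robust to back-echo attenuation — using integer-sample
shifts with zero fill.

An information-theoretic note that shaped the tests: for a single 2 MHz
Gabor echo at 20 dB peak SNR sampled at 50 MHz, the Cramer-Rao bound on
delay estimation is roughly 0.1 sample, so sub-0.05-sample accuracy is
only meaningful for signals with more integrated energy (longer
band-limited records); the randomized shift-recovery suite is built
accordingly, and A-scan-level robustness is instead expressed as tau
scatter staying well below a carrier period.

## Calibration, ranking, operating pressure

- Calibration lines (tau vs load, tau vs Shore hardness) are ordinary
  least squares with intercept. `R^2` is defined as 0 when the response is
  constant.
- Modulus recovery regresses `w = v tau / 2` on *P* through the origin
  (the contact law forces a zero intercept) and inverts the slope; this
  averages noise across the sweep instead of inverting single points.
  Loads in the bundled studies are chosen per phantom to keep peak strain
  near 20%, inside the small-strain regime where the flat-punch law is
  meaningful.
- `rank_stiffness` orders labels by ascending tau (stiffest first) and
  reports exact ties as groups instead of breaking them silently.
- `select_operating_pressure` formalises the sensitivity-curve knee: the
  largest pressure whose incoming rate of ToF change is still at least
  `plateau_fraction` (default 0.25) of the maximum rate. On a curve steep
  through the 5 kPa level and flat after — the documented behaviour of the
  physical system — this returns 5 kPa.

## Lesion screening

The screen turns a pre/post (or site/contralateral) comparison into a
reproducible decision rule. With repeated tau measurements per condition
(summarised as mean and SE = s/sqrt(n)):

- `relative_reduction = 1 - mean(test) / mean(reference)`;
- flag when the reduction exceeds a threshold (default 0.2) **and** the
  `mean +- 2 SE` intervals do not overlap;
- with a single repeat on either side the reduction alone decides and the
  result carries a low-confidence marker;
- the screen is one-sided (stiffening only) by construction; softening
  yields a negative reduction and never flags.

The 0.2 default sits well below the ~0.5 contrasts a stiff inclusion
produces in the bundled scenarios and well above the repeat scatter of
the estimator at the modelled noise levels.

## Bundled study conditions

The five fixture scenarios (`generate_fixtures` / `scenario_configs`)
mirror the experiment families the method is designed for: a 0-60 HA
silicone hardness series at 0/15 N (10 mm thick, v = 1000 m/s), a 0-35 N
force sweep of a 10 HA sample, three strain-stiffening tissue analogues
(45/25/12 kPa, beta = 3, 30 mm thick) under 0-10 N, a 25 kPa host with and
without a 10x stiffer inclusion (thickness fraction 0.35, ~31% deformation
reduction) at a matched 3 N load with 8 repeats at 25 dB SNR, and a
relaxed/contracted muscle pair (15 vs 45 kPa, 40 mm) under a 1-5 kPa
pressure escalation. The strain-stiffening bundle is generated noise-free
because it characterises the concavity of the compression law itself, not
estimator robustness. Sampling rate is 50 MHz throughout (25x the
carrier), which comfortably resolves the sub-microsecond shifts involved.

## Known limitations

- The tau-vs-hardness relation of the simulator is `tau ~ 1/E(S)` and the
  Gent relation spans a 23x modulus range over 0-60 HA, so that curve is
  strongly convex: a straight line fits it with R^2 ~ 0.68 (and no
  stiffening coefficient raises this above ~0.84). Real silicone blocks
  measured at ~36% strain on a rigid backing behave more linearly because
  of substrate stiffening and large-strain effects that this two-layer
  elastic model deliberately omits; the package reports the fit it
  actually measures.
- Absolute modulus estimates inherit every assumption of the flat-punch
  model (isotropy, homogeneity, frictionless contact, half-space
  geometry) and require the sound speed as input; tau-based comparisons at
  matched loads are the robust mode of use.
- The anatomical identity of the tracked back-wall interface in vivo is an
  abstraction; the simulator's "back wall" stands for whichever interface
  the device tracks.
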