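# ofr-brf

Spatial-summation analysis of short-latency **ocular following responses
(OFR)** — the reflexive tracking eye movements evoked at ~55 ms latency in
macaque monkeys by sudden motion of a large grating. The package maps the
**behavioral receptive field (bRF)** that drives these responses: a small
excitatory integration center surrounded by a broader suppressive field.

It is aimed at oculomotor/visual-motion researchers who want a tested,
reproducible implementation of the full analysis chain:

* a **synthetic-data generator** that emulates 1 kHz eye-position recordings
  for disk, ring, and annulus-mask grating stimuli (per-trial traces,
  response latency, position noise, blank catch trials with slow drift,
  interleaved leftward/rightward motion);
* **trace processing**: trial rejection (fixation breaks, saccades), blank
  subtraction, windowed open-loop amplitude measures (10/20 ms windows in
  the 60–120 ms open-loop period), differentiation to velocity and
  acceleration, first-acceleration-peak extraction, and summation-curve
  construction;
* **model-free indices** of center–surround organisation — grating summation
  area (GSA), surround extent (SExt), surround suppression index (SSI), and
  annular minimal diameter (AMD) — plus their time course across windows;
* **model fitting**: the difference-of-Gaussians (DoG) summation law and the
  exponential eccentricity-decay law, with normalized χ² goodness of fit;
* **spatial-frequency tuning**: how the fitted extents, gains and decay
  constants change with grating spatial frequency.

## The models

For a grating disk of diameter *D* centered on fixation, the response
amplitude follows the integral of a DoG sensitivity profile across the
stimulus:

```
R(D) = g_e · erf( D / (2√2 σ_e) ) − g_i · erf( D / (2√2 σ_i) )
```

with excitatory/inhibitory extents σ_e ≤ σ_i (degrees) and gains g_e, g_i
(degrees of eye-position change). The curve rises to an optimum near the
center's extent and then declines toward the asymptote g_e − g_i when the
surround is engaged. For a ring stimulus (60° aperture whose center is
occluded out to inner diameter *x*), the response decays exponentially:

```
R(x) = g_r · e^(−x/τ) + r_0
```

where the decay size constant τ (degrees, bounded at 100°) quantifies how
quickly peripheral motion loses its drive. Both models are fitted with
bounded least squares from a multi-start grid, weighting residuals by the
per-point standard errors.

## Worked example

Simulate a noiseless size-series session at 0.36 cpd, build the summation
curves, and recover the generating parameters:

```python
from ofr_brf import (default_truth, BRFTruth, make_condition_grid,
                     simulate_session, fit_dog, model_free_indices)
from ofr_brf.traces import build_summation_curve

base = default_truth()
truth = BRFTruth(dog=base.dog, decay=base.decay, noise_sd=0.0, drift_sd=0.0)
session = simulate_session(make_condition_grid(1), truth,
                           n_trials_per_condition=2, seed=42)
disk = build_summation_curve(session, "disk", (85, 105))
ring = build_summation_curve(session, "ring", (85, 105))
c = next(c for c in disk if c.direction == "rightward")
r = next(c for c in ring if c.direction == "rightward")
fit = fit_dog(c.diameters, c.amp)
idx = model_free_indices(c, r)
print(f"sigma_e = {fit.params.sigma_e:.3f} deg, sigma_i = {fit.params.sigma_i:.3f} deg")
print(f"g_e = {fit.params.g_e:.4f} deg,  g_i = {fit.params.g_i:.4f} deg,  chi2_n = {fit.chi2_n:.2e}")
print(f"GSA = {idx.gsa} deg, SExt = {idx.sext} deg, SSI = {idx.ssi:.3f}, AMD = {idx.amd} deg")
```

prints

```
sigma_e = 4.180 deg, sigma_i = 7.600 deg
g_e = 0.0170 deg,  g_i = 0.0090 deg,  chi2_n = 7.62e-36
GSA = 14.2 deg, SExt = 31.95 deg, SSI = 0.169, AMD = 53.25 deg
```

The fit recovers the generating DoG parameters to machine precision
(noiseless self-consistency), and the model-free indices read the curve
directly: the response saturates by ~14° diameter, settles within 5% of its
large-stimulus asymptote by ~32°, is suppressed by ~17% at the largest
sizes, and ring responses reach their floor only at the largest central
occlusion tested.

## Command line

```
ofr-brf simulate --experiment 1 --n-trials 150 --seed 42 --out run/
ofr-brf process  --in run/ --windows 65-85,85-105
ofr-brf indices  --in run/
ofr-brf fit      --in run/
ofr-brf tuning   --in run/
```

or run everything from a JSON config (`seed` required):

```
ofr-brf run --config run.json --out run/
```

Every output is plain CSV/JSON; `run_manifest.json` records the config and
a SHA-256 hash of each file, and reruns with the same config are
bit-identical.

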