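# Methods

## The problem and the forward model

Short-latency ocular following is driven by motion pooled over a restricted
central region of the visual field and suppressed by motion in a broader
surround. Because amplitude-versus-size curves are the only behavioral
observable, the spatial structure of this behavioral receptive field must be
inferred from two stimulus families: grating disks of increasing diameter
(summation) and grating rings whose center is occluded out to an increasing
inner diameter (peripheral drive).

The package's generator is an explicit forward model of those measurements.
A ground-truth object (`BRFTruth`) holds, per spatial frequency:

* a DoG summation law for disks — the response to a centered disk of
  diameter D is the integral of a difference-of-Gaussians sensitivity
  profile across the stimulus,
  `R(D) = g_e·erf(D/(2√2 σ_e)) − g_i·erf(D/(2√2 σ_i))`;
* an exponential eccentricity-decay law for rings,
  `R(x) = g_r·e^(−x/τ) + r_0`;
* annulus-mask controls (a thin 3.4°-wide mean-luminance ring over the full
  60° grating) respond at the full-disk level independent of mask
  eccentricity, reflecting the finding that the line endings such masks
  introduce do not modulate the early response.

Leftward and rightward motion produce sign-flipped responses; analysis
operates on response magnitude per direction.

### Integration geometry

The summation integral is one-dimensional, across the stimulus diameter.
This is the convention under which the integral of a Gaussian profile is
exactly an error function, and it is the standard erf-based formulation in
the ocular-following literature. A two-dimensional radial integration would
instead produce `1 − exp` terms; it is deliberately not offered, so that
fitted σ values remain comparable to published erf-based fits.

## The synthetic trial

Each simulated trial is a 1 kHz horizontal/vertical eye-position pair from
100 ms before to 250 ms after stimulus onset (the stimulus epoch itself is
220 ms). The temporal template of the response is a cubic smoothstep rise in
velocity starting at the response latency (default 55 ms, the monkey value)
and reaching a constant-velocity plateau 40 ms later. No published
functional form exists for this profile; any smooth monotone rise would do,
and smoothstep was chosen for its closed-form integral. The trace is scaled
so the noiseless position change over the reference 85–105 ms window equals
the amplitude law exactly — this scaling contract is what makes noiseless
parameter recovery testable to machine precision.

Noise model: i.i.d. Gaussian position noise per sample (default SD 0.005°),
plus, on blank catch trials, a random linear drift (slope SD 0.1°/s). These
defaults keep the standard error of a 150-trial mean small relative to the
response amplitudes, matching the regime in which the real measurements
operate (error bars smaller than plot symbols). The vertical channel is
pure noise: stimuli move horizontally only.

Randomness: one master seed; the interleaving order and each trial's noise
stream derive deterministically from `(seed, trial_index)` via
`numpy.random.SeedSequence`, so sessions are reproducible and individual
trials are independent of session composition.

### Default ground-truth values

Disk laws use the per-SF parameter means of the six-SF summation dataset
(0.12–1.41 cpd). The 0.72 cpd row is excluded by default: its printed
surround gain (0.16) is internally inconsistent with its printed gain ratio
(0.56, which implies ≈0.009); no corrected value is assumed, and the row can
be included explicitly via `include_suspect=True`.

Ring laws have printed decay constants only at 0.18 cpd (97.2°) and
1.41 cpd (39.5°). Defaults for the other SFs interpolate with the same
exponential-decay family through those two anchors, clipped at the 100°
bound used during fitting (giving 100, 97.2, 85.2, 65.5, 51.0, 39.5° across
the six SFs). The ring gains are set so the ring response at inner diameter
0 equals the disk asymptote `g_e − g_i` for the same SF, split 95%/5%
between `g_r` and `r_0` so a small positive floor remains at the largest
occlusions.

The supplementary small-diameter disk set (used at the three highest SFs,
where the main 3.55° minimum is too coarse to resolve the rising limb) is
{1.0, 1.78, 2.37, 3.55, 5.33, 7.1}°: six log-spaced values sharing two
diameters with the main grid so that merging at the common 7.1° point
yields a 16-point curve.

## Trace analysis

* **Rejection.** Trials are dropped if any pre-stimulus sample exceeds the
  1° fixation window on either channel, or if eye speed (central
  differences, both channels) exceeds 100°/s anywhere in the epoch. The
  saccade threshold is a conventional offline choice — the original online
  criterion used electronic windows and is not fully specified — and is
  configurable.
* **Blank subtraction.** The pointwise mean of catch-trial traces is
  subtracted from every amplitude measure: a trial's window amplitude is
  `Δx(trial) − Δx(blank mean)` over the same window. This removes any drift
  common to stimulus and catch trials exactly (an invariant under test).
* **Windows.** 10 ms windows spanning 60–120 ms, or 20 ms windows at
  45–65 / 65–85 / 85–105 ms; the 85–105 ms window is the reference (highest
  signal-to-noise while still open-loop).
* **Differentiation.** Central differences on the 1 ms grid, one-sided at
  endpoints (`numpy.gradient`, applied twice for acceleration). Exact for
  quadratics; second-order accurate otherwise. No smoothing by default —
  the generator does not need it and real recordings are hardware low-pass
  filtered — but a Savitzky–Golay option exists for noisy imported data.
* **First acceleration peak.** First local maximum after a 40 ms search
  start, earliest-time tie-break; a monotone profile has no local maximum
  and returns the global maximum with a warning flag.

## Model-free indices

All criteria pick the tested data point closest to the criterion level — no
interpolation, so resolution is limited by the diameter grid (this is the
point of the model-free method; the model-based fits refine it).

* GSA: smallest diameter with amplitude ≥ 95% of the curve maximum R_opt.
* SExt: smallest diameter at/beyond the GSA within ±5% of the asymptote
  R_asy (the amplitude at the largest tested diameter). The search starts
  at the GSA so the rising limb cannot satisfy the band. Undefined when
  R_asy = 0.
* SSI: (R_opt − R_asy)/R_opt.
* AMD: first ring inner diameter with amplitude ≤ 1.05 × the floor R_min
  (amplitude at the largest inner diameter). The criterion is phrased
  several slightly different ways in the literature; the "within 5% of the
  floor" reading is the default and a "≤ 5% of the peak" alternative is
  available (`mode='peak'`). A ring curve that does not decay is flagged
  undefined.

All indices are invariant under positive rescaling of the amplitudes.
Indices are computed per (dataset, direction) and then averaged; time
courses regress each index on window midpoint by OLS (slope, intercept, r²,
df, two-sided p from the t distribution on N − 2 df).

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`),
SE-weighted residuals by default (unit weights when SEs are absent or zero,
flagged). The DoG fit keeps μ = 0 (stimuli are centered on fixation; a free
μ exists behind a flag) and enforces σ_i ≥ σ_e by parameterising
σ_i = σ_e + δ, δ ≥ 0, which keeps center and surround identifiable.
Multi-start: σ_e ∈ {2, 5, 10}°, σ_i initialised at 2σ_e, g_e from the curve
maximum and g_i from maximum-minus-asymptote; the lowest-cost start wins.
The decay fit bounds τ in (0, 100°] — reading the stated 100° amplitude cap
as a bound on the only degree-valued parameter that approaches it — with
multi-start τ ∈ {10, 30, 80}°. Goodness of fit is the normalized χ²,
Σ[(obs − pred)/se]² / (N − P). Parameter standard errors come from the
SVD-based Gauss–Newton covariance scaled by the reduced χ². Degenerate
cases are flagged rather than errored: g_i ≈ 0 marks σ_i unidentifiable; a
flat ring curve marks τ at bound.

Per-SF datasets are fitted independently (a joint fit across SFs was
reported not to improve on independent fits and is out of scope).

## Spatial-frequency tuning

Per-replicate fits and indices are aggregated by SF (means ± SD across
datasets/directions; ratio columns σ_i/σ_e and g_i/g_e computed per
replicate, then averaged). Extents and decay constants are summarised by
the same exponential-decay family `a·e^(−sf/b) + c`. Gain tuning min-max
normalises each replicate's gain series to [0, 1] and fits a Gaussian in
linear SF space; amplitude and an additive offset are left free so that an
affinely renormalised Gaussian is recovered exactly. The σ_i–σ_e relation
is plain OLS.

## Problem sizes used in the checks

The self-consistency checks are noiseless and run in seconds. The
Monte-Carlo recovery study uses 100 replicate multi-SF sessions at 150
trials per condition; replicate window amplitudes are drawn with an exact
amplitude-level sampler (`simulate_window_amplitudes`) that produces the
same distribution as the full 1 kHz trace path — each trial's window change
is the template-scaled amplitude plus the difference of two position-noise
samples, blank-corrected by a simulated catch-trial mean — and whose
agreement with the trace path is itself under test. Pipeline-determinism
checks run the full trace path at reduced trial counts; noiseless curve
amplitudes are independent of trial count (an invariant under test), so the
reduced runs exercise the identical code path.

## Known limitations

* The generator's trials contain no saccades, blinks, pupil artifacts,
  torsion, or closed-loop visual feedback, and no binocular signals; the
  rejection stage is therefore exercised by synthetic injections rather
  than realistic artifact statistics.
* The smoothstep response template is a convenience; only the
  window-scaling contract (not the template shape) is guaranteed to match
  real dynamics. Acceleration-peak values depend on the template and should
  not be compared quantitatively to recorded data.
* Passing recovery tests shows the analysis chain is self-consistent and
  unbiased under the assumed noise model — not that real recordings satisfy
  that model. Headline indices from real monkey data (e.g. mean GSA or SSI
  values) cannot be reproduced here because no recordings are deposited;
  only the extraction procedures are implemented.
* The printed stimulus surface areas in the source condition tables are
  consistent with area = π·d²/2 (twice the true disk area); the generator
  uses true geometry and makes no use of those figures.
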