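# Methods

This note documents the models behind `nirsdcs`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Time-domain reflectance model

The TD-NIRS forward model is the semi-infinite homogeneous diffusion
approximation with the extrapolated-boundary (image dipole) condition —
the standard choice for a single-distance measurement at ρ = 2.5 cm:

- photon diffusion coefficient D = 1/(3 μs′) (absorption excluded from D);
- isotropic source depth z₀ = 1/μs′, extrapolated boundary at
  z_b = 2D·(1+R_eff)/(1−R_eff) with the Groenhuis/Haskell polynomial
  R_eff(n) = −1.440/n² + 0.710/n + 0.668 + 0.0636 n;
- refractive index default n = 1.4 (soft tissue and the silicone phantom),
  giving v = c/n.

The late-time log-slope of R(ρ,t) tends to −μₐv; the property suite checks
convergence within 2% on a long grid, with the residual −5/(2t) power-law
term explaining the approach rate.

**Discretization.** 2048 bins spanning one laser period (18.868 ns at
53 MHz). Because the excitation is repetitive, the model DTOF is the
*circular* convolution of the analytic curve with the IRF over the period;
a delta IRF reproduces the analytic curve bin-for-bin (tested). The IRF
default is a Gaussian, FWHM 200 ps centred at 3.9 ns, matching the scale of
the characterized hardware (barycenter ≈ 3.9 ns). Actual bin width and
histogram span of the real timing electronics are not public; these values
are this package's assumption and are configurable.

## DTOF fit

Poisson-weighted least squares of (model ⊛ IRF) against the measured
histogram:

- background: mean and sd over a pre-peak window (default first 100 bins);
  mean subtracted before fitting, sd defines the dynamic range
  DR = max(DTOF)/sd(background);
- fit window: 80% of peak on the rising edge to 1% of peak on the falling
  edge (common TD-NIRS convention; configurable);
- weights 1/√max(counts, 1); amplitude solved analytically (variable
  projection) at every iteration, so only (log μₐ, log μs′) are free;
- Levenberg-Marquardt (scipy `least_squares`, method `lm`) from
  μₐ = 0.1 cm⁻¹, μs′ = 10 cm⁻¹, tolerances 1e-10, ≤ 200 iterations.
  Non-convergence is flagged in the diagnostics, never raised.

The optimizer is cross-checked against a brute-force 2-D grid search over
the identical objective (`dtof_objective`) on random instances.

Fitting and simulation share the same forward model (a deliberate inverse
crime): the recovery tests quantify noise- and window-induced error only,
not model mismatch against real tissue.

## Chromophores

μₐ at 685/828 nm is inverted through a fixed 2×2 molar-extinction system
(ln 10 · ε · C, C in μM). The embedded ε values are linear interpolations
of the standard Gratzer/Kollias compilation (Prahl's tabulation):

| λ (nm) | ε_HbO₂ | ε_HbR (cm⁻¹/M) |
|--------|--------|-----------------|
| 685    | 283.0  | 2229.9          |
| 785    | 736.5  | 997.0           |
| 828    | 958.4  | 692.4           |

A water term (fixed volume fraction × pure-water μₐ; default fraction 0
for the phantom, intended ~0.7 for tissue) is subtracted before inversion.
Negative concentrations are returned with a warning flag. The phantom's
"effective" tHb/StO₂ QC metrics use the same inversion with water 0.

Properties at the DCS wavelength (785 nm) are linearly interpolated in
wavelength from the fitted 685/828 values.

## DCS model and fit

g₁(τ) is the semi-infinite correlation-diffusion Green's-function ratio
with decay wavenumber K²(τ) = 3μₐμs′ + 6μs′²k₀²·BFI·τ (k₀ = 2πn/λ),
i.e. Brownian red-blood-cell dynamics, BFI = αD_b — the field standard.
The dual-source injection geometry is collapsed to one effective 2.5 cm
separation (both arcs are centred on that distance); its intensity doubling
appears only as a count-rate factor in the simulator.

The fit minimizes 1 + β·g₁²(τ; BFI) − g₂(τ) jointly over (log BFI, β),
β bounded in (0, 1]. β is fitted rather than fixed from early lags so the
per-measurement β statistics used for quality trending come from the same
estimator. Lags where the estimated |g₁|² < 0.01 are excluded (noise only);
a curve with no measurable decay returns a non-converged flag. The
correlator's lag grid is a configurable logarithmic grid (default 128 lags,
10⁻⁷–10⁻² s); the real hardware lag structure (multi-tau vs linear) is not
public.

Baseline DCS quality integrates raw 26 ms curves into 10 s blocks over a
60 s window and reports median/sd of the Siegert-intercept β and of the
count rate, with flags below β = 0.4 or outside the count-rate band.

## Synthetic data: what it emulates, and what it does not

- **DTOFs**: theory ⊛ IRF scaled to the target signal counts (default 10⁶,
  the instrument's equalization target), uniform dark floor (default
  1 kcps), independent Poisson counts per bin.
- **g₂**: Siegert curve plus zero-mean Gaussian noise with per-lag sd
  β(1+g₁²)/√N, N = count rate × averaging time. This reproduces the 1/√N
  scaling of correlator noise; it is *not* the full multi-tau covariance
  (no inter-lag correlation), which the real correlator would produce. The
  noise model is this package's design choice; nothing in the analysis
  depends on its exact form.
- **VOT traces**: piecewise-analytic — baseline plateau; linear
  desaturation (default −4.6 %/min, floored at 40%); linear reoxygenation
  (default 1.1 %/s) to a hyperemic peak (+8% over baseline); exponential
  relaxation (τ = 50 s) toward baseline with a small undershoot (0.5%)
  clamped at baseline. The undershoot makes the second baseline crossing
  happen in finite time — a pure exponential never re-crosses and would
  leave the AUC undefined on noiseless traces. BFI: near-zero (3% of
  baseline) during occlusion, 3.5× peak at release, τ = 45 s chosen so the
  overshoot resolves before the 60 s recovery-baseline window. Defaults
  are the healthy-cohort group values (baseline StO₂ 70.3%, BFI
  0.53×10⁻⁸ cm²/s); Gaussian channel noise (0.5% StO₂, 8% relative BFI).
  Not emulated: cardiac pulsatility (unresolved at 1 Hz by design), motion
  artifacts, probe-pressure effects, adipose-layer partial-volume effects.
- **Sessions**: phantom (20 repetitions per wavelength at 1 s), IRF,
  VOT, test-retest (5 repositionings × 200 s with a between-repositioning
  variability term tuned to inter-test CVs of ~1.2% StO₂ / ~12.6% BFI),
  stepped partial-occlusion (holds at 40/60/80/100% of the limb occlusion
  pressure with noise inversely tied to the light level), and the
  quality-assessment phase (60 s equalization then alternating 10 s
  ON/OFF segments with configurable dark and cross-talk levels).

Passing recovery tests on these generators demonstrates the *inversion
chain* is unbiased under the assumed noise; it does not validate the
diffusion model against heterogeneous tissue.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, one child per independent stream in a fixed order; identical
(kind, config, seed) give bit-identical sessions.

## VOT biomarkers

- Pre-occlusion baseline: mean over the 30 s before inflation. Recovery
  ("second") baseline: mean over the final 60 s of recovery — the window
  is this package's definition; upstream practice distinguishes the second
  baseline without fixing a window.
- DeO₂: OLS slope over [inflation, +60 s], reported per minute.
- ReO₂: OLS slope from the occlusion StO₂ minimum (ties → latest sample
  before deflation) to the first sample at/above the recovery baseline,
  per second. No crossing → flagged excluded, not raised.
- AUC: trapezoid of (signal − recovery baseline) between the first upward
  and next downward crossing, crossings located by linear interpolation;
  both AUCs are referenced to the *recovery* baseline (the schematic
  shading upstream is ambiguous between the two baselines; one convention
  was fixed and documented). A signal that never exceeds baseline has zero
  excursion, hence AUC 0; a signal that exceeds it but never returns is
  excluded.
- Markers are trusted over nominal durations (sessions may be extended in
  30 s steps); absent markers are inferred from the cuff-pressure
  half-maximum crossings.
- MMRO₂ = [Hb]·(SpO₂−StO₂)/(γ·SpO₂)·BFI and OEF = 100·(SpO₂−StO₂)/(γ·SpO₂).
  γ defaults to 0.75 (common venous-fraction convention; configurable).
  The OEF formula is an inference — upstream reports OEF values but not
  the formula; with γ ≈ 1 it approximates reported cohort values.

## Quality phase and statistics

- QP bands are pass-inclusive at the band edges (10–200 kHz DCS signal,
  0.8–1.2 Mcps TD-NIRS) and strict at the dark/cross-talk ceilings
  (< 2 kHz, < 3 kHz, < 30 kcps); the mixed notation upstream forced a
  convention, documented here. Segment means use the central 8 s of each
  10 s segment to skip switching transients.
- CVs use the sample (n−1) standard deviation throughout; CV of a
  zero-mean series is flagged undefined.
- Spearman p-values: exact permutation enumeration for n ≤ 8, large-sample
  approximation above (full enumeration beyond 8 is disproportionate to
  its accuracy gain at these n).
- Bland-Altman: bias = mean(a−b), limits ±1.96 sd, plus the OLS slope of
  difference on mean as the proportional-bias test.
- Device resampling is nearest-preceding (sample-and-hold), mimicking a
  slow display device; linear interpolation by flag.
- Group comparison: Mann-Whitney U (unpaired) / Wilcoxon signed-rank
  (paired) at α = 0.05; all-zero paired differences return p = 1.

## Problem sizes

The recovery analyses use 20 DTOFs per wavelength at 10⁶ counts and 60 g₂
curves at 50 kHz × 1 s — one session's worth of phantom repetitions and
one baseline minute of averaged curves, the same sizes the device protocol
produces. The null-calibration check of the rank test uses 500
simulations at n = 20 per group.

## Known limitations

- Homogeneous semi-infinite model only: no layered/depth-resolved fitting,
  no absolute radiometric calibration, no moment/gated analyses.
- Single effective DCS separation; no multi-distance or time-domain DCS,
  no software correlator from raw photon arrivals, no pulsatile waveform
  analysis.
- The g₂ noise model ignores inter-lag correlation (see above).
- The extinction table fixes one literature compilation; a different table
  shifts absolute tHb/StO₂ by a few percent (the inversion is exactly
  linear in the table).
- The oximeter quality flag is treated as an opaque boolean; no PPG
  quality algorithm is implemented.
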