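# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order data flows through it.

## Generative model (simulator)

Particles are independent Brownian walkers (variance 2·D·dt per axis per
step) in a periodic box that must enclose at least ±5·(w₀, w₀, z₀); each
carries a two-state label and switches free→bound with per-step probability
1 − exp(−k*on*·dt) and bound→free with 1 − exp(−k_off·dt).  Bound particles
do not move.  Binding sites are spatially uniform and unsaturable
(pseudo-first-order kinetics), so no site positions exist — this matches
the fitted model, which has no site-density parameter.  Photons are drawn
per time step as Poisson with rate `brightness · MDE(x, y, z)`, with the
molecular detection efficiency MDE = exp(−2(x²+y²)/w₀² − 2z²/z₀²).  The
ground-truth molecule number N (in V_eff = π^{3/2} w₀² z₀) maps exactly to
the particle count through n = N·V_box/V_eff, making N exact rather than
estimated.

Numerical specifics, all statistically exact or bounded:

* **State switching** is sampled event-wise with geometric waiting times,
  which is distribution-identical to per-step Bernoulli switching.
* **Far-field jumps**: where MDE < 10⁻⁵ of peak the emission is treated as
  zero and a particle advances n steps in one Gaussian jump of variance
  2·D·n·dt (Brownian self-similarity makes this exact for the positions);
  n is chosen so the jump stays 3σ short of the emission ellipsoid along
  the ray to the focus.  Trajectories that graze the ellipsoid edge between
  jump endpoints are missed with probability ≲ 3·10⁻³ per jump, but those
  grazes could only emit at ≤ 10⁻⁵ of peak rate, so the bias on the trace
  is far below counting noise.
* **Time step**: the constructor enforces dt ≤ min(w₀²/(20·D),
  1/(20·(k*on*+k_off))).  The default dt = 2·10⁻⁴ s resolves the lateral
  diffusion time of the fastest preset (τ_D ≈ 1.4 ms) seven-fold and the
  exchange time (≈ 27 ms) 130-fold.  Positions at the sampled times are
  exact Brownian increments, so the simulated ACF needs no dt → 0
  extrapolation; only the binding–diffusion interleaving carries an
  O((k*on*+k_off)·dt) ≈ 0.7 % error.
* **Determinism**: every stream (initial positions, Gaussian increments,
  state switches, Poisson counts, drift) derives from the configuration
  seed; identical configurations give bit-identical traces.
* **Drift** is multiplicative sinusoidal, counts·(1 + a·sin 2πt/P), applied
  by deterministic scaling by default (a re-Poissonised mode exists); the
  mean is preserved to a²/2 relative.  A period shorter than a third of the
  3-s detrending window triggers a warning because such drift cannot be
  separated from signal.
* **Photon-level output** (for lifetime-filter testing) realises an
  inhomogeneous Poisson process with piecewise-constant rate at dt
  resolution: per-bin Poisson counts with uniform arrival times within the
  bin.  TCSPC micro-times are drawn per photon from class-conditional decay
  histograms.

What the generator deliberately omits: triplet blinking, photobleaching,
detector afterpulsing and dead time, anomalous diffusion, multiple mobile
species, and any optical detail beyond the 3-D Gaussian profile.  Passing
parameter-recovery tests therefore demonstrates the statistical machinery
of the pipeline, not robustness to these real-data complications.

### Condition presets

The two named presets encode the study conditions: "water"
(N = 48, D = 3.5 µm²/s, k_on = 3.5 µM⁻¹s⁻¹, k_off = 35 s⁻¹) and
"cryptogein" (N = 32, D = 8.4 µm²/s, k_on = 14.1 µM⁻¹s⁻¹, k_off = 35 s⁻¹);
k*on* follows as k_on·c(N) ≈ 1.73 and 4.63 s⁻¹.  The per-molecule
brightness is not constrained by the study; the default of 5 kHz/molecule
at beam centre (≈ 85 kHz total count rate for the water preset) is the
midpoint of the plausible 2–10 kHz in-cell two-photon range.  Acquisition
duration presets are 30/60/120 s.

## Correlator

Preprocessing order: lifetime filtering of photons, then moving-average
detrending of the binned trace, then correlation.

* **FLCS weights** W = (Mᵀ diag(1/h) M)⁻¹ Mᵀ diag(1/h) (patterns M,
  normalised observed histogram h) satisfy W·M = I to solver precision;
  near-collinear pattern sets are refused with the offending pair named.
* **Detrending** subtracts a centred moving average (default window 3 s)
  and re-adds its mean, preserving the global mean exactly.  Edges use a
  shrinking window rather than invented padding; the transfer analysis
  below assumes the interior behaviour, and the ≈ w/2 edge regions (5 % of
  a 60-s trace) are a documented approximation.
* **ACF estimator**: multiple-tau, 16 lags per octave with pairwise bin
  averaging per octave, symmetric normalisation (per-lag overlapping-support
  means), lags from one bin to duration/10.  The estimator is tested to
  agree with a direct O(n²) evaluation exactly (10⁻¹⁰) at unrebinned lags.
  Standard errors are the SD over 10 equal segments / √10; they are
  diagnostics, not fit weights.

## Autocorrelation model and its evaluation

The mode decomposition (φ, k₁, k₂) was validated against a 2×2 matrix
exponential of the linearised reaction–diffusion system (machine
precision) and pinned by two limits: at k*on* = 0 the rates reduce to
{max, min}(D q², k_off) with all weight on the diffusive rate, and at
q = 0 to (k*on*+k_off, 0) with all weight on the conserved mode.

* **Continuum quadrature**: the (q_r, q_z) integral is evaluated on
  composite Gauss–Legendre panels log-spaced in u = q_r² (10⁻⁹…3·10³ µm⁻²)
  and q_z (10⁻⁶…20 µm⁻¹), 10 nodes per decade-panel.  A single-scale rule
  (Gauss–Laguerre/Hermite, or one Legendre rectangle) fails at large lags
  because the integrand support shrinks below the node spacing; the
  log-panel grid keeps the worst-case error ≤ 10⁻⁵ relative over
  τ ∈ [10⁻⁶, 10] s and changes by < 10⁻⁴ when the node count is doubled
  (the convergence criterion exposed on the grid object).
* **Detrend transfer**: moving-average detrending is linear, so its exact
  effect on each covariance mode e^{−kτ} is computable in closed form
  (window integrals of exponentials; constants are annihilated, fast modes
  lose ≈ 2/(k·w)).  Curves measured from detrended traces are fitted with
  this transfer applied to the model rather than pretending the data were
  untouched — without it the recovered exchange rates are biased several-fold
  upward, because the detrending depression (≈ 2Θ/w with Θ = ∫G dτ)
  mimics faster decorrelation exactly in the reaction band.
* **Periodic-box spectrum**: for simulator-generated curves the correct
  forward model is the discrete mode sum over box wave vectors
  (k = 0 excluded), G(τ) = (1/M) Σ_k w_k·mix(k², τ).  This reproduces two
  real features of closed-box data that the continuum integral lacks: the
  canonical-ensemble amplitude offset −1/M (fixed particle number) and the
  spectral gap of the slowest box mode (D·(2π/L)², ≈ 35 ms for the minimum
  box — inside the reaction band).  The fitter switches to this spectrum
  automatically when the curve metadata records the generating box;
  experimental (open-medium) data use the continuum quadrature.

## Fitting

Unweighted least squares over the multiple-tau grid, minimised with
bounded trust-region-reflective iterations; D, k*on*, k_off in log space,
N linear; bounds N ∈ [0.1, 10⁴], D ∈ [10⁻³, 10³] µm²/s, rates
∈ [10⁻³, 10⁵] s⁻¹.  A weighted mode (1/SE) exists behind a flag but the
unweighted objective is the default.  The fitted lag range is capped at
window/10 (0.3 s for the 3-s window) when the curve was detrended: beyond
that the moving-average transfer dominates the tiny residual signal.
Starts: amplitude and half-decay heuristics for (N, D); a deterministic
4×4 coarse scan over the exchange-rate plane whose three best cells seed
local optimisations, plus seeded jittered starts — the objective is
multimodal along a kon*–koff ridge and single-start fits land on arbitrary
ridge points.  Standard errors come from the final Gauss–Newton Jacobian
with a delta-method back-transform for the log-space parameters; when the
kon*–koff correlation exceeds 0.99 or a parameter sits on a bound the fit
is flagged non-identifiable.  Flat curves (amplitude indistinguishable
from noise) are flagged non-converged rather than silently fitted.

The exchange-rate pair of a single 60-s acquisition is intrinsically noisy
(the binding signature of the control condition is a ≈ 5 % bound fraction);
per-condition values are therefore medians over replicate acquisitions,
and per-fit values scatter substantially — visible in the standard errors
and expected of the measurement, not an optimiser defect.

**Calibration** fits the closed-form diffusion ACF to a reference-dye curve
with the dye's D fixed (default 540 µm²/s) and (N, w₀) free, z₀ fixed or
slaved to an aspect ratio.  The dye D value's temperature consistency is
the caller's responsibility (a Stokes–Einstein rescaling utility is
provided); the value used is recorded in the diagnostics.

**Derived quantities** per fit: c = N/(N_A·V_eff), k_on = k*on*/c,
K_d = k_off/k_on (absent when k*on* = 0, never infinity), bound fraction
k*on*/(k*on*+k_off).  K_d is derived per measurement and then averaged like
any other parameter — the mean of ratios, not the ratio of means — so a
condition's mean K_d need not equal mean(k_off)/mean(k_on).

## Group statistics

The unit of analysis is the nucleus: converged measurements are averaged
per nucleus, nuclei without converged fits are dropped with a warning, and
conditions are compared per parameter with a two-sided Welch t-test at
α = 0.005 (Student's pooled test behind a flag; no multiple-testing
correction by default, Holm behind a flag).  A per-measurement mode exists
because reported group sizes in such experiments do not always equal
nuclei × measurements; the tables report whatever n survives the stated
filters.

## Problem sizes used in the shipped checks

The test suite and the acceptance script favour many short, statistically
controlled runs: parameter-recovery experiments use 8 replicate 60-s
acquisitions per condition at dt = 2·10⁻⁴ s, unit tests use low-occupancy
configurations (N = 5) and seconds-long traces, and the end-to-end
statistics check reuses the recovery fits as 8 nuclei × 1 measurement per
condition.  The water condition's exchange rates are at the edge of what a
single 60-s acquisition resolves (bound fraction ≈ 5 %): per-fit k*on*
estimates are heavy-tailed and the median over 8 replicates still carries
a sampling scatter of roughly ×1.5, which the reported standard errors and
the identifiability flag make visible.  The type-I-error control of the comparison
stage is verified at the statistics level over 200 resimulated null
datasets.  These sizes are the package's own test design; the library
itself has no limits beyond memory.

## Known limitations

* The moving-average transfer is exact only in the trace interior; edge
  regions are untreated (≈ 5 % of a 60-s trace).
* The box-spectrum correction assumes the generator's geometry; real data
  from media with boundaries (a nucleus is one!) would need their own
  confinement model — the open-medium model is the standard approximation.
* Fast-exchange regimes (k*on*+k_off ≫ 4D/w₀²) leave only the effective
  diffusion coefficient identifiable; the fitter flags but cannot cure
  this.
* The simulator's Poisson emission ignores detector saturation; count
  rates ≫ 1 MHz would not be realistic.
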