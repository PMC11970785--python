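# fcsbind

Fluorescence correlation spectroscopy (FCS) analysis of nuclear protein
dynamics when the protein both diffuses and binds immobile partners —
the situation of a GFP-tagged chromatin-interacting factor (e.g. the
AAA-ATPase CDC48/p97) measured in live-cell nuclei under two experimental
conditions (control vs. elicitor treatment).

The package provides the complete chain from raw photon records to
condition-level statistics:

* a Brownian-dynamics **photon-trace simulator** (free diffusion +
  reversible binding to immobile sites in a 3-D Gaussian two-photon
  observation volume, Poisson photon emission, optional slow drift and
  short-lifetime background) so that the entire pipeline can be exercised
  and validated without experimental data;
* a **correlator**: photon binning, fluorescence-lifetime (FLCS)
  statistical filtering, 3-s moving-average detrending, and a multiple-tau
  autocorrelation estimator (16 lags/octave, symmetric normalisation,
  segment-based standard errors);
* the **diffusion–binding autocorrelation model** and its fitting by
  bounded trust-region-reflective least squares, including observation-volume
  calibration from a reference dye and conversion of the pseudo-first-order
  association rate to molar units;
* **group statistics**: per-nucleus aggregation and Welch t-tests between
  conditions at α = 0.005.

## The model

Molecules with diffusion coefficient D bind immobile sites with
pseudo-first-order rate k*on* (s⁻¹) and unbind with k*off* (s⁻¹).  In a
Gaussian observation volume with lateral/axial 1/e² extents w₀, z₀, each
spatial frequency q² = q_r² + q_z² of the concentration field relaxes
bi-exponentially with rates

    k₁,₂(q²) = ½ [ S ± √(S² − 4 D q² k_off) ],   S = D q² + k*on* + k_off

mixed with weights (1 ∓ φ)/2, where
φ = [(k*on*+k_off)² + (k*on*−k_off) D q²] / [(k*on*+k_off) √(S² − 4Dq²k_off)].
The measured autocorrelation is the Gaussian-weighted integral over q of
this mixture, normalised so G(0⁺) = 1/N with N the number of molecules in
the effective volume V_eff = π^{3/2} w₀² z₀.  Derived quantities:

    c = N / (N_A V_eff),   k_on = k*on*/c  (M⁻¹s⁻¹),   K_d = k_off / k_on,
    bound fraction = k*on*/(k*on* + k_off).

At k*on* = 0 the model reduces exactly to the closed-form free-diffusion
ACF — this limit, together with the amplitude anchor, is enforced by the
test suite to better than 10⁻³ relative.

## Worked example

Simulate one 60-s nuclear acquisition under the control ("water")
condition, preprocess, and fit:

```python
from fcsbind import (SimulationConfig, get_preset, simulate_binding_trace,
                     detrend, autocorrelate, BindingDiffusionModel, FitConfig)

truth = get_preset("water")        # N=48, D=3.5 um^2/s, kon*=1.73/s, koff=35/s
cfg = SimulationConfig(duration=60.0, dt=2e-4, seed=1)
trace = simulate_binding_trace(cfg, truth)        # ~85 kHz count rate
curve = autocorrelate(detrend(trace, window=3.0)) # multiple-tau ACF
fit = BindingDiffusionModel(curve, truth.volume).fit(FitConfig(seed=1))
print(fit.summary())
```

```
Diffusion-binding FCS fit
============================================================
converged: True   (`gtol` termination condition is satisfied.)
points fitted: 53   RSS: 8.1736e-07
volume: w0 = 0.22 um, z0 = 0.6 um (V_eff = 1.6170e-16 L)
------------------------------------------------------------
parameter         estimate       std err
N                   46.674        0.2099  molecules
D                   3.5406       0.07525  um^2/s
kon_star           0.67236        0.2566  1/s
koff                15.355         4.118  1/s
------------------------------------------------------------
c   = 0.4793 uM
kon = 1.403 1/(uM s)
Kd  = 10.95 uM
bound fraction = 0.04195
```

The fitted N and D land on the generator's ground truth; the exchange-rate
pair (k*on*, k_off) is the least identifiable combination in a single
60-s acquisition (note its standard errors — here both rates come out low
while their ratio, the bound fraction, stays close to the true 4.7 %).
Condition-level values are therefore medians over replicate acquisitions.

A full two-condition in-silico experiment, ending in a per-parameter
mean ± SD table with Welch t-tests, is one call:

```python
from fcsbind import RunConfig, run_pipeline
report = run_pipeline(RunConfig(out_dir="demo", n_nuclei=5,
                                n_measurements=3, duration=30.0, seed=1))
print(report["summary"].to_text())
```

The same stages are exposed as a CLI: `fcsbind simulate`, `correlate`,
`calibrate`, `fit`, `compare`, `run`.

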