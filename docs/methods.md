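# Methods

## Models

`fdgkin` models the kinetics of 2-deoxy-2-[¹⁸F]fluoro-D-glucose (¹⁸F-FDG)
in lung regions of interest (ROIs) during dynamic PET. All models are
linear, driven by the plasma input function C_p(t), with zero initial
conditions.

**Sokoloff three-compartment model** (blood, extra-vascular precursor C_e,
metabolized C_m):

    dC_e/dt = k1·C_p − (k2 + k3)·C_e
    dC_m/dt = k3·C_e

**Four-compartment model** adds an extra-vascular extra-cellular pool C_ee
— tracer in lung water that is not available for phosphorylation —
exchanging with the precursor compartment at rates k5 (in) and k6 (out):

    dC_e/dt  = k1·C_p − (k2 + k3 + k5)·C_e + k6·C_ee
    dC_ee/dt = k5·C_e − k6·C_ee
    dC_m/dt  = k3·C_e

The observable is C_ROI(t) = F_B·C_p + C_e + C_m (+ C_ee), and each PET
frame records the within-frame time-average of C_ROI. Derived quantities:

    Ki  = k1·k3/(k2 + k3)        net uptake rate (1/min)
    F_e = k1/(k2 + k3)           precursor distribution volume (F_ei in
                                 the four-compartment model); F_e·k3 = Ki
    F_ee = F_ei·k5/k6            extra-cellular distribution volume

Ki has the same closed form in both models: in quasi-steady state the
extra-cellular pool is in equilibrium with the precursor pool and carries
no net flux into the trapped compartment. The package verifies this by
simulation (a constant input held for five hours drives k3·C_e/C_p to Ki
in both models).

Assumptions inherited from the model class: no dephosphorylation (k4 = 0),
plasma and whole-blood activity collapsed into one input curve, activities
decay-corrected, ROIs homogeneous.

## Numerical integration

Forward Euler at a fixed step, 0.1 s by default. The Euler recursion is
evaluated exactly as a linear constant-coefficient difference equation
(`scipy.signal.lfilter` with the recursion's z-transform coefficients), so
the result is identical to a per-step loop — unit tests confirm agreement
with a naive loop at machine precision — but costs microseconds. Frame
averages use the trapezoidal cumulative integral of C_ROI differenced at
frame edges.

Accuracy at the default step: against an independent matrix-exponential
(zero-order-hold) solution of the same system, the final-frame activity
agrees to ~3·10⁻⁴ %. Halving the step changes the frame vector by less
than 0.01% in relative L2 norm. Per-frame relative changes at the *first*
30-s frame are an order of magnitude larger (~0.01–0.04%) because the
left-endpoint rectangle rule meets the infusion ramp there; this is
inherent to first-order fixed-step integration and immaterial at the
precision of the estimators.

Stability is monitored by sign: a step too coarse for the rates produces
negative compartment activities, which abort the simulation with a
diagnostic. The error-sweep additionally caps k6 at 50/min (a grid point
with a tiny k5/k6 ratio would otherwise imply an arbitrarily fast
extra-cellular exchange that the fixed-step integrator cannot follow).

## Synthetic data

No experimental curves ship with the package; the generator reproduces the
study conditions:

* **Frame schedule** — 32 frames over 75 min (6×30 s, 7×60 s, 15×120 s,
  1×300 s, 3×600 s).
* **Plasma input** — a 60-s constant-rate infusion (box) convolved with a
  tri-exponential clearance, evaluated in closed form. Default rates
  (2.0, 0.12, 0.008)/min with fractions (0.75, 0.15, 0.10): a fast
  redistribution phase, an intermediate exchange phase, and a slow terminal
  phase, normalized to peak at the end of the infusion and decay to ~10% of
  peak by 75 min — a standard FDG plasma shape. The amplitude is arbitrary;
  every estimator is invariant to it (tested).
* **Ground-truth parameters** — rate-constant sets for a healthy
  non-dependent region ("LPS-Lav-", low uptake: Ki_F ≈ 0.73·10⁻³/min) and
  a dependent region injured by endotoxin plus saline lavage ("LPS+Lav+",
  high uptake: Ki_F ≈ 15.3·10⁻³/min).
* **Noise** (optional, off by default) — zero-mean Gaussian with variance
  proportional to activity/frame-duration, the usual PET count-statistics
  weighting. The error study itself is noiseless by design.

What the generator does **not** emulate: image-derived input functions and
their calibration against blood samples, partial-volume and spill-over
effects, respiratory motion, and ROI heterogeneity. Passing tests
therefore demonstrate correctness of the estimators under ideal sampling,
not robustness to those experimental confounds.

## Estimators

**Patlak.** Ordinary least squares of y = C_ROI/C_p against
x = ∫₀ᵗC_p/C_p at frame mid-times, restricted to frames with mid-time ≥ 15
min (configurable). The mid-time convention is the package's choice; ∫C_p
is computed on the fine input grid. Slope = Ki_P, intercept = reversible
distribution volume.

**Compartment-model fits.** Bound-constrained nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, Jacobian-based
parameter scaling) of the forward model's frame averages against the TAC,
globalized by multi-start. Starts are drawn from a scrambled Sobol sequence
over the search box — Sobol rather than Latin-hypercube because Sobol draws
are prefix-nested at a fixed seed, which makes the best SSE provably
non-increasing in the number of starts. Defaults: 32 starts, forward-model
step 0.5 s, F_B ∈ [0, 0.5], each rate ∈ [0, 5]/min (a generous
physiological envelope containing all reference values). Ties in SSE break
toward smaller k5 (parsimony). Non-convergence of every start raises;
partial convergence is flagged on the result, never hidden.

With k1 = 0 the remaining rates have exactly zero gradient, so a fit of an
identically zero TAC pins k1 (and hence Ki) at zero but leaves the other
rates wherever the winning start had them — they are unidentifiable, not
estimated.

**AIC.** Least-squares form, n·ln(SSE/n) + 2(p+1), with +1 for the error
variance. Only differences at equal n are interpreted. SSE = 0 is a
degenerate perfect fit and is signalled rather than scored.

## Error study

For each condition the four-compartment k1, k2, k3, F_B are held at their
reference values while k5 and the ratio k5/k6 sweep a 9×9 grid,
i/9·max for i = 1..9, with maxima 0.139/min and 1.24 (the zero step is
excluded: k6 = k5/ratio diverges there). At each point the noiseless
four-compartment TAC is generated (step 0.1 s), Patlak and Sokoloff
estimates are computed, and errors are recorded as Δ_X = X_est − X_true
and ε_X = 100·Δ_X/X_true, with the generating truth stored alongside for
audit. Reallocation ratios ∫C_x(Sokoloff fit)/∫C_x(four-comp truth) for
the precursor and metabolized compartments quantify where the
extra-cellular tracer is absorbed by the misspecified model.

Sweep fits use 8 Sobol starts plus one warm start at the generating
condition's rate constants, with a 1.0-s forward-model step — problem
sizes chosen so the full 162-point sweep (including four-compartment fits
for the AIC comparison) completes in a few minutes on one CPU; recovery
tests confirm that the reduced-start configuration still reaches the
global minimum on these kinetics. All per-fit seeds derive from the single
sweep seed, and repeated runs are byte-identical.

Because the experimental plasma input functions behind the original error
surfaces are not available, error *magnitudes* from this synthetic input
are not comparable to the study's tables; only signs and orderings are
asserted (Sokoloff Ki bias positive and larger than Patlak's; relative Ki
error larger in the low-uptake region while absolute error is larger in
the high-uptake region; F_e error proportionally larger in the injured
region; metabolized-to-substrate reallocation crossover along k5).

**Supporting statistics.** Hampel identifier (|v − median| > 5·MAD) for
degenerate k5/k3 ratios; Bland-Altman paired differences summarized as
median [25–75% IQR]; Wilcoxon rank-sum comparisons between conditions are
delegated to `scipy.stats`.

## Known limitations

* The Patlak window interacts with the slow extra-cellular pool: Ki_P on a
  75-min acquisition of a *Sokoloff* low-uptake region is already ~5–7%
  below the asymptotic Ki (transient bias that vanishes with scan length —
  tested at 4× duration). Errors reported by the sweep fold this finite-
  window bias into Δ_KiP, as the graphical method does in practice.
* k5 and k6 are weakly identified when their ratio is small or their
  time-scale approaches the scan length; fitted k5/k6 values should be
  screened with the Hampel rule as in the reference analysis.
* The fixed search box caps rates at 5/min; kinetics outside that envelope
  (not observed in lung data) would require widening the bounds.
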