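# Methods

## Circuit model

The forward model is the standard modified Randles network:
`Z(ω) = R_s + [1/Z_CPE + 1/(R_ct + Z_W)]⁻¹` with
`Z_CPE = 1/(Q(jω)^α)` and the semi-infinite Warburg element
`Z_W = Z_w ω^{-1/2}(1−j)` (constant −45° phase).  Capacitive impedance
carries a negative imaginary part internally; Nyquist exports flip the sign
of the imaginary axis, following electrochemical convention.  Phase is kept
in radians everywhere inside the package; degrees exist only at explicit
I/O boundaries.  `α = 1` (ideal capacitor) is allowed, `α ≤ 0` rejected.
The Warburg element is the conventional semi-infinite form — equivalent to
a CPE with exponent 1/2 and rescaled magnitude.

Frequency grids are log-spaced with a configurable points-per-decade
density (default 10) over the instrument range 0.05 Hz–10 kHz.  The point
count is `round(ppd·log10(f_max/f_min)) + 1`, which yields the familiar
54-point sweep for that range and exact per-decade spacing on whole-decade
ranges.

## Likelihood and maximum-likelihood fitting

Fitting is performed on the polar (Bode) form of the data, never on raw
complex residuals: complex-plane least squares over-weights the very large
low-frequency impedances.  Phase and magnitude residuals are modelled as
iid Gaussian with separate standard deviations σ₁ (rad) and σ₂ (Ω), which
are fitted alongside the five circuit parameters, so the likelihood is a
proper 7-parameter density and the posterior widths are
noise-level-calibrated.

The scale parameters (R_s, R_ct, Z_w, Q, σ₂) span orders of magnitude and
are handled in log10 space; α and σ₁ stay in natural space.  Hard box
boundaries (defaults: R_s ∈ [0.1, 1e5] Ω, R_ct ∈ [1, 1e7] Ω,
Z_w ∈ [1, 1e6] Ω·s^(−1/2), Q ∈ [1e−9, 1e−3] Ω⁻¹·s^α, α ∈ [0.4, 1],
σ₁ ∈ [1e−5, 1] rad, σ₂ ∈ [1e−2, 1e5] Ω, all overridable by config file)
are enforced by a logistic-sigmoid reparameterization, so every optimizer
proposal is feasible without penalty terms.

The optimizer is a compact in-package CMA-ES (standard weighted-recombination
strategy with cumulative step-size adaptation and rank-one/rank-mu
covariance updates; population `4 + ⌊3 ln d⌋ = 9` at `d = 7`).  Starts are
at the box centre with initial step 0.5 in the unbounded coordinate; a run
stops when the best value improves by less than 1e−8 over 50 consecutive
generations, within a budget of 2×10⁴ evaluations.  Because the surface has
occasional local optima (typically corner solutions with inflated noise
parameters), independent starts are repeated until the two best objective
values agree to within 0.1 log-likelihood units — evidence the same basin
was found twice — up to four starts; the best is returned and the
convergence flag reports whether any start met the stagnation tolerance.
Spectra with fewer than 7 points are rejected outright (the model would be
unidentifiable).

On noiseless 54-point synthetic spectra this recovers all five circuit
parameters to well within 1%; at the default scenario's noise level the
median `R_ct` error over seeded replicates is a few tenths of a percent,
and the fitted σ₁, σ₂ estimate the generating values within a factor of
1.5.

## Posterior sampling

The posterior is the same polar likelihood plus a prior uniform over the
CMA-ES boxes in *natural* space.  Sampling runs in the log10-transformed
coordinates used for fitting, with the log-Jacobian `ln(10)·Σ θ_scale`
added so the natural-space prior stays uniform; proposals outside the box
have density zero.  Three chains (default) are initialised at the
maximum-likelihood point and run for 10 000 iterations, with the first
3000 discarded per chain before pooling — the conservative reading of
"pooled samples with the first 3000 discarded".

The sampler is a Haario-style adaptive Metropolis: after a 100-iteration
non-adaptive warm-up, the proposal covariance tracks the equal-weight
running covariance of the full post-warm-up history, while a separate
global log-scale factor is nudged toward the ~0.234 optimal acceptance rate
with a `t^{-0.6}` learning rate.  The equal-weight covariance matters: an
exponentially-weighted variant whose effective window is short relative to
the chain's autocorrelation time systematically underestimates the target
covariance and was measurably biased in moment checks, so it was rejected.
A chain whose acceptance collapses to zero is flagged, not raised.

Convergence is summarised by the split-chain Gelman-Rubin statistic
(each retained chain halved, `R̂ = sqrt(((n−1)/n·W + B/n)/W)`), with a
default pass threshold of 1.05, plus an effective-sample-size estimate from
chain-averaged autocorrelations truncated by Geyer's initial positive
sequence.  The implementation is cross-checked against arviz's split-R̂ and
against the emcee ensemble sampler on analytic targets in the test suite.

Two posterior-QC utilities operationalize visual checks used in titration
practice: `rct_separation` reports the symmetrized fraction of each
posterior's draws inside the other's central 99% interval (distinct when
below 0.01 — a quantitative version of "the distributions show no
overlap"), and `electrode_amalgamation_qc` selects the largest subset of
electrodes whose protein-free `R_ct` values lie within ±35% (default) of
the subset median before titrations are pooled across electrodes; that
default tolerance pools a 7.7/10.4/12.9 kΩ trio.

## Binding and coverage analyses

The response variable is always the fractional change
`y_i = (R_ct,i − R_ct,0)/R_ct,0`, which makes both isotherm fits invariant
to rescaling all resistances.  The Langmuir analysis uses the linearised
form `y = C/K_d` with a through-origin least-squares slope
`Σ(C·y)/ΣC²`, so `K_d = 1/slope`; a non-positive slope (no binding signal)
is an error, not a number.  The Hill fit is nonlinear least squares of
`y = A·C^n/(K_A^n + C^n)` (scipy `curve_fit`, positivity bounds, starting
from n = 1 and the geometric mid-concentration); it needs ≥ 4 points and a
non-flat response.  With n = 1 the Hill model nests the Langmuir regime:
on weakly-saturating data the two analyses agree through the identifiable
ratio `K_A/A ≈ K_d`.

`k_app = RT/(n²F²·A·C·R_ct)` uses R = 8.314 J mol⁻¹ K⁻¹, F = 96 485 C mol⁻¹,
disk area `A = π(d/2)²`, and defaults to 298 K.  Mass-to-molar conversion
is `μg mL⁻¹ / kDa × 1000 = nM`; note that 18.5 μg mL⁻¹ at 26 kDa is
711.5 nM by this arithmetic (values near 713 nM imply a slightly different
molecular weight was assumed upstream).

Voltammetric surface coverage fits a cubic polynomial to the current inside
user-supplied baseline potential windows (≥ 4 points, excluding the peak),
subtracts it, integrates the residual over potential, divides by the scan
rate to get charge, and by `nF` to get moles.  The subtraction is exact
(to quadrature tolerance) whenever the true background is a polynomial of
degree ≤ 3.

## Synthetic data

Generators are pure functions of (truth, seed).  Spectrum noise is applied
in polar coordinates — Gaussian on phase and magnitude — mirroring the
likelihood's error model, so estimator consistency holds by construction;
a perturbation that would make a magnitude non-positive is resampled
(keeping retained noise unbiased) with a warning.  Titrations follow
`R_ct,i = R_ct,0(1 + y(C_i))(1 + ε_i)` with relative Gaussian ε; electrode
populations are log-normal with a specified median and log10-scale SD;
voltammograms are a cubic background plus a Gaussian faradaic peak whose
time-integrated charge is specified exactly.

The default scenario uses plausible synthetic values chosen to resemble a
modified screen-printed gold electrode read out with ferricyanide:
R_s = 200 Ω, R_ct = 15 kΩ, Z_w = 3 kΩ·s^(−1/2), Q = 5×10⁻⁷ Ω⁻¹·s^α,
α = 0.9, σ₁ = 0.01 rad, σ₂ = 150 Ω, 0.05 Hz–10 kHz at 10 points/decade;
Langmuir K_d = 6.3 μg mL⁻¹ over 15–30 μg mL⁻¹, Hill (A = 3,
K_A = 18.5 μg mL⁻¹, n = 5.7), a 0.35 pmol one-electron ferrocene peak on a
microampere-scale cubic background at 0.1 V s⁻¹.  These are testing values,
not measurements.  What the generators deliberately do **not** emulate:
electrode fouling or drift between incubations, non-Gaussian instrument
artefacts, frequency-correlated noise, and non-specific adsorption physics.
Passing recovery tests therefore demonstrates internal consistency of the
estimator chain under its own error model, not robustness to real-world
model misspecification.

## Problem sizes and numerical choices

Test and acceptance runs use 54-point spectra, 20-seed recovery studies and
3×2000-iteration chains (600 burn-in) for the repeated coverage checks,
with the single full-length 3×10 000/3000 configuration exercised on the
analytic Gaussian target; these sizes give stable pass/fail behaviour at
desk scale.  Degenerate inputs fail loudly rather than silently: empty
grids, non-monotone frequency sweeps, single-chain convergence diagnostics,
flat titration responses, all-equal ages and under-determined spectra each
raise with a specific message.  Ties in the electrode-pooling subset search
are broken toward the smallest relative spread.

## Known limitations

- Only the single modified-Randles topology is supported; no
  Kramers–Kronig validation, finite-length Warburg variants or model
  comparison between circuit topologies.
- The phase residual is taken as a plain difference (no wrapping); this is
  safe for capacitive spectra whose phases stay within (−π/2, 0) but would
  need care for inductive artefacts.
- `rct_separation`'s 0.01 overlap threshold and the 35% pooling tolerance
  are pragmatic defaults, both exposed in the API.
- The Hill and Langmuir parameters are only jointly identifiable when the
  concentration range brackets saturation; weakly-saturating designs leave
  `A` and `K_A` determined mainly through their ratio.
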