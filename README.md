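# eisfit

Bayesian equivalent-circuit analysis for impedimetric biosensors.

Label-free electrochemical biosensors report analyte binding as a change in
the charge-transfer resistance `R_ct` of an electrode, measured by
electrochemical impedance spectroscopy (EIS) against a redox probe such as
ferricyanide.  Extracting `R_ct` requires fitting an equivalent circuit to
the measured spectrum, and deciding whether two `R_ct` values differ
requires knowing the uncertainty of that fit — especially on disposable
screen-printed electrodes, whose device-to-device spread can be large.
`eisfit` provides that workflow end to end for glycan/lectin-type sensors
(e.g. galectin-3 detection on glycofluoroform-modified gold electrodes),
but nothing in it is specific to a particular receptor chemistry.

## The model

Spectra are described by a modified Randles circuit: solution resistance
`R_s` in series with a constant phase element (CPE, impedance
`1/(Q(jω)^α)`) in parallel with the faradaic branch `R_ct + Z_W`, where
`Z_W = Z_w ω^{-1/2}(1−j)` is the semi-infinite Warburg diffusion element.
Observations are the polar (Bode) components, assumed to carry iid Gaussian
noise with standard deviations `σ₁` on the phase (rad) and `σ₂` on the
magnitude (Ω), giving the log-likelihood

```
L(θ) = −N ln 2π − N ln σ₁ − N ln σ₂
       − Σ (φ_obs − φ_mod)²/2σ₁² − Σ (|Z|_obs − |Z|_mod)²/2σ₂²
```

over the seven parameters θ = (R_s, R_ct, Z_w, Q, α, σ₁, σ₂).  The maximum
is found by CMA-ES inside hard parameter boundaries; posteriors come from
three adaptive-covariance Metropolis chains started at the maximum-likelihood
point, with a prior uniform over the same boundaries.  Downstream, `R_ct`
titrations are converted to binding constants via the linearised Langmuir
isotherm `(R_ct,i − R_ct,0)/R_ct,0 = C/K_d` (through-origin regression, so
the gradient is `1/K_d`) or the Hill equation
`y = A C^n/(K_A^n + C^n)`; mean resistances convert to apparent
electron-transfer rate constants `k_app = RT/(n²F²·A·C·R_ct)`; and
surface-confined ferrocene voltammetry integrates to a coverage
`Γ = Q/(nF)` after cubic baseline subtraction.

## Worked example

Simulate a spectrum from the default scenario (true `R_ct` = 15 kΩ,
0.05 Hz–10 kHz, σ₁ = 0.01 rad, σ₂ = 150 Ω), fit it, and convert two mean
resistances into rate constants:

```sh
$ eisfit simulate spectrum --seed 3 --out spec.csv
$ eisfit fit --input spec.csv --seed 4 --out fit.txt
R_s = 201.5
R_ct = 1.494e+04
Z_w = 3003
Q = 4.879e-07
alpha = 0.9032
log-likelihood = -175.9213
$ eisfit kapp --rct 2800
k_app = 3 um/s
$ eisfit kapp --rct 34200
k_app = 0.25 um/s
```

The fitted `R_ct` of 14.94 kΩ recovers the generating 15 kΩ to 0.4% at this
noise level.  The two `kapp` calls show the rate-constant conversion for a
2 mm disk in 10 mM ferricyanide: a bare electrode averaging 2.8 kΩ
corresponds to ~3 μm s⁻¹, and a receptor-modified one at 34.2 kΩ to
~0.2 μm s⁻¹ — a ~12-fold decrease in apparent electron-transfer rate upon
surface modification.

Posterior sampling continues from the fit record:

```sh
$ eisfit mcmc --input spec.csv --init fit.txt --chains 3 --iters 10000 \
      --burnin 3000 --seed 5 --out posterior.csv
```

which writes per-chain draws plus a summary with 95% credible intervals,
split-chain Gelman-Rubin statistics and the parameter correlation matrix
(the strong `Q`–`α` anticorrelation of the CPE is the expected dominant
term).  `titrate`, `coverage` and `cohort` handle the binding, coverage and
multi-electrode analyses; every command records its seed and input digests
in a JSON manifest next to its output.

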