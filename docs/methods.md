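# Methods

## Model and assumptions

The package implements an empirical model of the wash-in of desflurane
delivered in O₂ through a circle breathing system:

    F_A(FGF, F_D, t, Ht) = 1/(ht_scale·Ht) ·
        [ a_fgf·FGF + scale · R(FGF, F_D) · g_time · (1 − e^(−t/τ)) ]

    R(FGF, F_D) = (1 − e^(k1·FGF)) + c_reb·(1 − e^(−k2·FGF))·d_reb·F_D

It is a descriptive fit, not a mass-balance model: the coefficients have
no direct physiological interpretation, and the functional form encodes
three qualitative assumptions — F_A rises mono-exponentially in time
(time constant τ), F_A is proportional to the dial setting at fixed flow
and time (the equation is linear in F_D), and the flow effect is
exponential, with a negative term (`1 − e^(k1·FGF)`, k1 > 0) that makes
F_A fall again at high flows, mimicking reduced vaporizer output from
cooling. Patient height enters as a 1/Ht prefactor; weight and age carry
no effect. The model is valid for FGF 0.5–5 L·min⁻¹, dial 6–18%, 1–5 min
after opening the vaporizer, and end-expired concentrations up to 8%;
outside that box the code evaluates the formula anyway but emits a
`ValidityWarning` (the published surfaces themselves sweep full grids).
Note the model does not pass through zero at t = 0: the direct fresh-gas
term a_fgf·FGF remains, which is one reason validity starts at 1 min.

## Parameters

| name      | meaning                                   | unit          | default |
|-----------|-------------------------------------------|---------------|---------|
| a_fgf     | direct fresh-gas coefficient              | % per L·min⁻¹ | 2.55    |
| scale     | global scale of the rebreathing term      | —             | 1348    |
| k1        | circuit-term flow rate constant           | per L·min⁻¹   | 0.23    |
| k2        | dial-term flow rate constant              | per L·min⁻¹   | 0.24    |
| c_reb     | rebreathing multiplier                    | —             | 2.49    |
| d_reb     | dial weight                               | per %         | 0.39    |
| g_time    | time-term scale                           | —             | 0.03    |
| tau       | wash-in time constant                     | min           | 4.08    |
| ht_scale  | height divisor factor                     | per cm        | 0.1     |
| k_lump1/2 | lumped constants of the published inverse | %             | 40.46 / 39.29 |

The closed-form dial equation only involves the products scale·g_time
and scale·g_time·c_reb·d_reb. The published inverse prints these as
40.46 and 39.29, although the structural product is 40.44; both are
carried: `solve_dial(mode="derived")` uses the unrounded products (and
round-trips the forward equation to machine precision), while
`mode="printed"` is a verbatim transcription of the published
expression. The two agree within 0.08 dial-% over the validity domain
(tested against a 0.15 band).

Planner constants: the desflurane vaporizer's ceiling is 18% and its
resolution 0.5%; dial rounding rounds ties (x.25/x.75) half up, a choice
made here since only "the nearest value" is specified for the device.
`min_feasible_fgf` scans at 0.01 L·min⁻¹ (the reporting resolution of
the feasibility claims), refines the boundary by bisection to 1e-4, and
rounds up to the grid so the reported flow is always feasible.

## Fitting

Estimation minimises the unweighted pooled sum of squared residuals over
all usable samples with `scipy.optimize.least_squares` (trust-region
reflective, bounded to (1e-8, 10× the initial value) per coefficient),
restarted from the initial values plus log-uniform ±30% jitters
(10 restarts by default, seeded); the best SSR wins. Usable samples are
those at or after 60 s (near-zero early readings carry no information
about the 1–5 min window the model serves) and at or below 8%; a record
must contribute at least 3 usable samples.

Only six coefficients are identifiable: scale/g_time and c_reb/d_reb
enter purely as products, so g_time and d_reb are held at their initial
values by default and (a_fgf, scale, k1, k2, c_reb, tau) are estimated;
the lumped constants of a fitted parameter set are the exact structural
products. Approximate standard errors come from the Gauss–Newton
covariance σ²(JᵀJ)⁻¹ at the optimum and are reported by `summary()`;
they are conditional on the fixed coefficients.

Covariate parsimony replaces a population-modelling objective-function
comparison with its Gaussian equivalent: −2·log-likelihood is
n·log(SSR/n) up to a constant, each candidate covariate X (age, height,
weight) extends a covariate-free base model by a normalised power factor
(X/X̄)^θ with θ estimated, and a candidate is retained when the
objective drops by more than 3.84 (χ², 1 df, 5%). For
height-structured data the fitted exponent lands at θ ≈ −1, the model's
1/Ht form. All candidates are tested against the same covariate-free
base; with a strong unmodelled height effect in the base, candidates
correlated with height in a small sample can absorb variance, so the
calibrated guarantees are: height is detected essentially always on
height-structured data, and each candidate false-positives at the
nominal ~5% rate on covariate-free data (both tested).

## Synthetic data

The generators emulate the derivation protocol: truncated-normal
demographics (height 166 ± 9 cm, weight 70 ± 14 kg, age 52 ± 15 y,
truncated at ±3 sd, normality assumed since only means and sds are
reported); FGF drawn uniformly on the 0.1 L·min⁻¹ device grid over
[0.5, 5] and dial on the 0.5% grid over [6, 18], with combinations
predicted (noise-free, at the 166 cm reference height) to give less than
1% at 2 min or less than 2% at 5 min rejected and redrawn; 10-s sampling
over 0–5 min truncated at the first sample above 8%.

Noise defaults are a design choice (no residual distribution is
published): additive Gaussian with sd 0.25% desflurane, roughly
consistent with a ±20% band at mid-range concentrations. Between-patient
uptake variability — reported to span almost 170% across patients — is
emulated as a log-normal multiplier (mean 1, configurable CV) on the
rebreathing term only, since rebreathing is where individual uptake
feeds back into the inspired mixture; with CV 0.5 the simulated
prospective MDAPE inflates markedly at low flows, reproducing the
reported direction of the low-flow error. The generators do not emulate:
breath-by-breath mechanics, analyzer drift, within-patient serial
correlation of measurement error, vaporizer output error (available
optionally via the cubic PE curve), or any pathophysiology — so passing
tests certify the statistical machinery under the model's own
assumptions, not clinical performance in real patients.

Vaporizer calibration data are generated from the reference line
output = −0.72 + 1.075·dial with Gaussian noise whose sd is solved from
the target r² and the realised regressor variance
(sd = sd_signal·√((1−r²)/r²)), since r² is the reported quantity.

## Performance statistics

PE = 100·(measured − predicted)/predicted with the target concentration
as the denominator (in the prospective design the prediction *is* the
target at the specified time); APE = |PE|; MDPE and MDAPE are medians
across patients, one PE per patient, with even-count medians averaging
the central pair. The simulated trial draws a flow per patient, inverts
for the dial, skips patients whose dial exceeds the 18% ceiling (those
flows cannot be tested), rounds to the 0.5% resolution, and measures F_A
at the exact target time (the nearest-10-s-sample alternative is not
used). The clinical groups' MDPE/MDAPE values are not reproducible —
the underlying patient data were never deposited — so the trial
machinery is validated by construction: exactly zero bias at zero noise
without rounding, |MDPE| ≤ 3% with rounding (bounded by the 0.25 dial-%
maximum rounding error times the dial→F_A sensitivity), and bit-level
seed reproducibility.

## Problem sizes and numerics

Default test problem sizes follow the study design where one exists
(50-patient derivation cohorts, n = 229 calibration points) and are
otherwise chosen as the smallest sizes at which the targeted statistical
behaviour is stable: 20-seed recovery studies, 100 replicates for
selection power, 200 for null calibration, 8-patient cohorts per
selection replicate. Feasibility searches resolve flows to 0.01 L·min⁻¹.
Degenerate inputs are errors, not silent results: empty time grids,
non-increasing sample times, constant regressors, all-filtered records,
zero denominators in the inverse (FGF or time term vanishing), and
all-infeasible trial groups each raise a named exception; a negative
required dial (target already exceeded by the carrier term, possible
only for near-zero targets) is returned with a warning.

## Known limitations

Single agent (desflurane), single carrier (O₂), single machine family;
coefficients are not transferable. Fixed ventilation is assumed. The
maintenance phase (beyond 5 min) is out of scope. The fitter estimates
fixed effects only — between-patient variability is a generator concept,
not a mixed-effects model. The structural form is fixed; no model-form
search is attempted.
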