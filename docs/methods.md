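# Methods

## Generative model

### Neuronal dynamics

Each region carries one scalar activity state `x_n`.  The neuronal flow is
exactly linear,

    dx_n/dt = A x_n + eps_f(t),

with `A` the effective-connectivity matrix in Hz under the (target-row,
source-column) convention: `A[y-1, x-1]` holds `a_xy`, the influence
exerted by region `x` onto region `y`.  Off-diagonal entries are free
parameters.  Self-connections are parameterized as `-0.5 * exp(a_xx)` with
`a_xx` free and prior mean 0, so the diagonal is negative for every real
parameter value and the prior-mean circuit is stable.  `eps_f` is
endogenous noise with a global and a region-specific component (below).
No exogenous inputs are modelled (resting state); the noise input map `B`
routes one endogenous-noise channel into each region's neuronal state.

### Hemodynamics and observation

Neuronal activity drives the balloon model per region:

    s' = x_n - kappa s - gamma (u - 1)
    u' = s
    tau v' = u - v^(1/alpha)
    tau q' = u E(u, E0)/E0 - v^(1/alpha) q/v,   E(u, E0) = 1 - (1-E0)^(1/u)

The observation is the BOLD signal change

    lambda(q, v) = V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]
    k1 = 4.3 theta0 E0 TE,  k2 = epsilon r0 E0 TE,  k3 = 1 - epsilon,

reported in percent (the observation multiplies `lambda` by 100; resting
BOLD fluctuations are conventionally quoted in percent signal change, and
the percent scale keeps the synthetic signals in the regime where the
balloon nonlinearity is mild).

Defaults (all configurable): kappa = 0.64 s^-1, gamma = 0.32 s^-1,
tau = 2 s, alpha = 0.32, E0 = 0.4, V0 = 0.04; theta0 = 40.3 s^-1,
r0 = 25 s^-1, epsilon = 1, TE = 40 ms.  These are the standard
balloon-model values; the 3T and 7T presets shipped in
`FIELD_STRENGTH_PRESETS` are literature-derived placeholders (theta0
roughly linear in B0, r0 super-linear, epsilon falling with field) and are
explicitly non-authoritative configuration, to be overridden with
calibrated values for quantitative multi-field work.

**State coordinates.**  Internally `u`, `v`, `q` are propagated as
logarithms (state layout per region: `x_n, s, ln u, ln v, ln q`), so
positivity is structural and the resting state is exactly the zero vector
— which is therefore the expansion point of the spectral linearization.
Fitted hemodynamic parameters act multiplicatively:
`tau_eff = tau * exp(transit_r)` with `transit_r` a free per-region
log-scaling.

### Noise spectra

State and measurement noise are stationary with power-law (scale-free)
one-sided densities in frequency:

    S_ef,r(f) = (exp(alpha_global) + exp(alpha_region_r)) f^(-beta)
    S_eg(f)   = exp(alpha_meas) f^(-beta)        (identical across channels)

Both are diagonal (uncorrelated noise); the state-noise diagonal varies
across regions through `alpha_region_r` while the measurement-noise
diagonal is shared.  A single exponent `beta` (default prior mean 1, i.e.
1/f) is shared by state and measurement noise; separate exponents are
available via `NoiseSpectraParams(beta_state=..., beta_meas=...)`.

## Spectral forward model

The composed flow is linearized at the fixed point by central finite
differences (step 1e-5; the flow is vectorized so this is two batched
evaluations).  Stability (all eigenvalues of `J` strictly in the left half
plane) is verified and an `UnstableModelError` names the offending
eigenvalue.  An optional Gaussian perturbation of the expansion point
(scale ~1e-10) is provided for differentiation backends that cannot handle
the degenerate (repeated-eigenvalue) structure of the resting Jacobian; it
changes the Jacobian by well under 1e-6 relative and is off by default.

The predicted observation CSD is

    S_y(f) = K(f) S_ef(f) K(f)^H + S_eg(f),
    K(f) = G (2 pi i f I - J)^(-1) B,

computed by batched linear solves over the grid.  `K` is the Fourier
transform of the causal kernel `G exp(J tau) B`; the tests verify this
against direct time-domain quadrature to 1e-6 and against the Lorentzian
closed form for a scalar Ornstein-Uhlenbeck process to 1e-8.  All public
interfaces use frequency in Hz under the one-sided per-Hz convention (the
integral of the density over (0, Nyquist) is the process covariance);
angular-frequency factors are internal.

The default analysis band for fMRI is 32 linearly spaced frequencies on
[1/128, 0.25] Hz, truncated at the data Nyquist — the standard
resting-state band between the high-pass cutoff conventionally applied in
preprocessing (128 s) and the Nyquist frequency of a TR = 2 s acquisition.

## CSD estimation

Observed series are mean-centered and linearly detrended (no windowing —
the parametric estimate needs none), an MVAR model of fixed order 8 is
fitted by conditional maximum likelihood (ordinary least squares on the
lagged regression, via statsmodels' VAR; the innovation covariance is the
ML residual covariance), and the spectrum follows analytically:

    S(f) = 2 dt H(f) Sigma H(f)^H,
    H(f) = (I - sum_k A_k e^(-2 pi i f k dt))^(-1).

This is deliberately a plain ML fit rather than a Bayesian (shrinkage) AR
fit; the two differ at small sample sizes, where the ML estimate is
noticeably noisier.  Order 8 is the field's fixed convention and is kept
as the default.

## Variational Laplace

Complex spectra are handled by stacking real and imaginary parts of all
`(f, i, j)` entries into one real feature vector of length
`2 n_f n_ch^2`.  Inference maximizes the free energy

    F = -1/2 e' Pi e - 1/2 tr(Sigma_q J' Pi J) + 1/2 logdet Pi
        - n_e/2 log 2 pi
        - KL[N(mu, Sigma_q) || N(m_p, Sigma_p)]
        - KL[N(lam, Sigma_lam) || N(m_h, Sigma_h)]   (if lambda is free)

over the posterior mean `mu` (damped Gauss-Newton: proposals
`(J' Pi J + Sigma_p^-1 + damping I)^-1 (J' Pi e - Sigma_p^-1 (mu - m_p))`,
rejected unless they increase F), the posterior covariance
`Sigma_q = (J' Pi J + Sigma_p^-1)^-1`, and the log-precision
hyperparameters `lam` (Fisher-scored M-step with backtracking, so the
recorded F is non-decreasing over accepted iterations).  On
linear-Gaussian problems the scheme reproduces the exact posterior and the
maximized F equals the log evidence (tested to 1e-6/1e-4).

Optimizer defaults: damping starts at 1/32, x4 on rejection, x1/2 on
acceptance (floor 1e-8); at most 128 iterations; convergence when |dF| <
1e-2 over 4 consecutive accepted (or provably stalled) steps.  The feature
Jacobian uses central differences with step 1e-3 on the prior-whitened
scale, with automatic step shrinking if a perturbed model is unstable; the
differentiation backend is pluggable (any callable with the same
contract).

### Error model for MVAR-estimated spectra

The default precision over CSD features (built by
`spdcm.pipeline.calibrated_hyperparameters`) is diagonal with

* **shape** `1 / (S_ii(f) S_jj(f))` from the data CSD diagonal — the
  sampling variance of spectral estimates is proportional to the product
  of the corresponding auto-spectra, so this approximately whitens
  features whose magnitudes span ~4 orders of magnitude across the band
  (a single flat precision lets the largest, noisiest low-frequency
  features dominate and destroys recovery);
* **scale** calibrated by a parametric bootstrap of the fitted MVAR model
  (32 surrogate series re-estimated through the same pipeline), divided by
  the redundancy factor `rho = n_features / (2 (p k^2 + k(k+1)/2))`: the
  stacked features are smooth functionals of only `p k^2 + k(k+1)/2` MVAR
  parameters (plus exact Hermitian duplication), so counting them as
  independent observations would overstate the information ~rho-fold —
  visible as posterior standard deviations several times smaller than the
  actual across-realization scatter, and as spurious free-energy rewards
  (tens of nats) for over-parameterized models;
* the log-precision is **fixed** at this calibrated scale: if it is
  estimated, the same redundant features pull it straight back to the
  uncalibrated level.

Uniform (unweighted) precision remains available as
`Hyperparameters(components=None)`, with a weakly informative N(0, 32)
hyperprior on the single log-precision.

### Model comparison

Excluding a parameter sets its prior mean and variance to zero; it is
removed from the tunable subspace (avoiding a singular prior) and
contributes no KL term.  Clearing the `tunable` flag instead freezes a
parameter at its — possibly nonzero — prior mean.  Free energies of
competing models are compared only when the underlying data hashes match.

## Synthetic data generator

The generator emulates a standard three-region validation setting:

* generative connectivity `a12 = -0.2`, `a21 = 0.4`, `a32 = -0.3`,
  `a23 = 0.2`, `a13 = a31 = 0` Hz; transit-time factors
  `exp(transit) = (1.2499, 1.2374, 1.0743)`;
* connection priors zero-mean with variance 1/128 (self-connections
  1/128, transit 1/256, noise parameters 1/64, centered on the nominal
  noise level);
* noise amplitudes `exp(alpha_global) = exp(alpha_region) = 1e-5`,
  `exp(alpha_meas) = 1.6e-3` (percent^2/Hz), `beta = 1`, chosen once so
  the simulated BOLD SD is ~0.35% (physiological resting-state range) with
  measurement noise about a quarter of the signal SD;
* Euler-Maruyama integration at dt = 0.1 s of the full nonlinear model,
  driven by spectrally synthesized noise (white Fourier coefficients
  scaled by sqrt(S(f))); observations decimated to TR = 2 s after
  discarding a 32 s transient; measurement noise sampled directly at the
  scan times.

Two deliberate spectral-support choices keep the generator consistent
with the stationary forward model:

* endogenous noise is **band-limited to the scan Nyquist** (0.5/TR):
  supra-Nyquist neuronal power would alias into the analysis band, which
  the continuous-frequency forward model does not represent (near the
  Nyquist frequency the folded power would be up to 3x the in-band
  prediction);
* the power law is **flattened below the analysis band edge** (1/128 Hz)
  rather than below 1/duration: a 1/f law extended to ever-slower scales
  accumulates variance ~log(duration), so the generated statistics would
  drift with run length (and very long runs can push the log-coordinate
  integrator into stiffness); flattening at the band edge makes the
  conditions duration-invariant and leaves all in-band spectra untouched.

The default scenario length is 4096 volumes.  This is a validation-scale
run, not a realistic single-scan duration: it is chosen so that the
maximum-likelihood AR reduction delivers posterior standard deviations of
~0.02 Hz on the connections — the information regime in which the
reference implementations of this method demonstrate recovery — thereby
compensating for the extra sampling variance of the ML (versus Bayesian)
AR estimator.  Shorter series run fine but recover proportionally less
precisely (at 512 volumes, expect occasional sign failures on the weaker
connections).

**What passing tests do and do not show.**  The generator shares the
forward model's structural assumptions (linear neuronal dynamics, balloon
observation, power-law noise); success on it demonstrates the internal
consistency and calibration of the pipeline, not robustness to the
mis-specification present in real fMRI (non-neuronal physiological
rhythms, motion residuals, spatially correlated noise, regional
hemodynamic variability beyond transit time, nonstationarity).

## Known limitations

* The order-8 ML-AR reduction has an irreducible asymptotic bias at the
  lowest analysis frequencies (an order-8 rational spectrum cannot track
  the knee at the 1/128 Hz band edge of a spectrum spanning ~4 decades);
  forward/backward spectral agreement therefore plateaus at a
  band-aggregate relative error of roughly 0.15 however long the
  simulation, and estimated connections remain slightly attenuated even
  asymptotically.
* The bootstrap-calibrated diagonal precision corrects the *scale* of the
  feature information but not the correlation structure of the AR
  sampling error; free-energy differences between models of equal fit are
  accurate only to a few nats, and an over-parameterized model can
  occasionally (roughly 2 seeds in 10) edge out the true structure.
* The hyperparameter structure, damping schedule and convergence
  tolerances are this package's own choices; free-energy *values* are
  therefore not bit-comparable across implementations, only free-energy
  *differences* between models fitted here.
* Only the linear neural mass is shipped.  The forward machinery is
  written against a minimal state-space protocol (`expansion_point`,
  vectorized `flow`/`observe`, `noise_input_map`), so other region models
  (e.g. canonical microcircuits with lead-field observations) can be
  plugged in, but none is implemented or tested here.
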