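# Methods

## The observer model

The observer faces a binary classification of a scalar stimulus S into
"small" (−1) vs "large" (+1) relative to an internal class boundary. The
generative model the observer assumes has three ingredients, all normal:

* a prior over stimulus value, S ~ N(μ₀, σ₀²) — the observer's long-term
  belief about what stimuli occur;
* a sensory measurement of the current stimulus, m_t ~ N(S_t, σ_m²);
* memory recalls of past stimuli, r_{t−i} ~ N(S_{t−i}, σ_r(i)²), whose
  noise grows with elapsed trials as a power law,
  σ_r(i) = σ_m (1 + κ)^i with decay rate κ > 0.

Per trial the observer computes

* the stimulus posterior: ŝ_t = (σ₀² m_t + σ_m² μ₀)/(σ₀² + σ_m²),
  σ_s = σ₀σ_m/√(σ₀² + σ_m²);
* the boundary posterior from up to n = 7 recalls (the window is longer
  than any detectable lagged stimulus effect): b̂_t = β₀μ₀ + Σᵢ βᵢ r_{t−i},
  where β are the normalized precisions of the prior and recalls, so
  βᵢ ∝ (1+κ)^{−2i} and Σβ = 1; the posterior SD is σ_b = 1/√(σ₀⁻² +
  Σᵢ σ_r(i)⁻²), identical to the weighted-sum expression
  √(β₀²σ₀² + Σβᵢ²σ_r(i)²) (asserted in tests to 1e−10);
* the decision: v_t = Φ((ŝ_t − b̂_t)/√(σ_s² + σ_b²)) is the posterior
  probability that the stimulus exceeds the boundary; the choice is +1 when
  v_t > 0.5 and −1 otherwise (v = 0.5 is sent to −1 for determinism; the
  event has measure zero), and u_t = min(v_t, 1 − v_t) = Φ(−|ŝ−b̂|/√(σ_s²+σ_b²))
  is the probability the choice is incorrect.

Because recent recalls carry the most precision, the boundary is attracted
to recent stimuli; this single mechanism produces both the repulsive bias
in choices and the pre-congruence effect on decision uncertainty.

**Variants.** `constant_boundary` (ŝ ~ N(S_t, σ_m), σ_s = σ_m, b̂ = μ₀,
σ_b = 0; two parameters), `last_only` (only the lag-1 recall informs the
boundary), `equal_weights` (κ pinned to 0, recall noise flat in lag),
`future` (recalls of upcoming stimuli — a causality control). All share the
decision rule.

**Conventions the model commits to.**

* *Fresh recalls*: recalls are re-drawn from N(S_{t−i}, σ_r(i)) on every
  trial rather than carried forward as propagating noisy copies, because
  recall noise is defined as a function of lag at retrieval time.
* *Early trials and run boundaries*: the memory window does not cross run
  boundaries, and trials with fewer than 7 predecessors use only the
  available recalls plus the prior (the conjugate posterior over whatever
  sources exist). This keeps σ_b = 1/√Z exact at every trial.
* *Units*: all computation is in the native stimulus scale; continuous
  stimulus tables are z-scored per subject before modelling so priors are
  comparable across granularities. Feedback sessions are modelled
  identically — the model has no feedback term.

## Analytic choice likelihood

ŝ_t − b̂_t is a linear combination of independent Gaussians, hence Gaussian
with mean M_t = wS_t + (1−w)μ₀ − β₀μ₀ − Σβᵢ S_{t−i} (w = σ₀²/(σ₀²+σ_m²))
and variance V_t = w²σ_m² + Σβᵢ²σ_r(i)², so p(C_t = +1 | Θ) = Φ(M_t/√V_t).
The likelihood is therefore evaluated in closed form (and cross-checked
against Monte-Carlo choice rates at 10⁵ repetitions in the tests);
simulation remains available but is never needed for fitting. Probabilities
are clipped to [1e−12, 1−1e−12] inside the log-likelihood.

## Fitting

Per-subject maximum likelihood over a uniform box: μ₀ within the observed
stimulus range ± 2 SD, σ₀ and σ_m in (1e−3, 10 × stimulus SD), κ in
(1e−4, 5). σ₀, σ_m, κ are searched in log space to enforce positivity.
The optimizer is two-stage Nelder–Mead: `n_starts` random initial points
with a 50-evaluation cap, then the `n_top` best refined at tolerance 1e−7,
the refinement repeated once from its own optimum. The reference scheme is
1000 starts / top 20 / 100 000 evaluations; the library defaults (100 / 5 /
10 000) and the recovery-test configuration (32 / 4 / 2000) are desk-scale
reductions chosen so a full fit takes seconds at ~2000 trials — pass the
reference values through `FitConfig` to reproduce the full scheme.

Target-trial exclusions: the first trial of every run (it has no
predecessor) and trials answered in under 0.3 s (too hasty to reflect a
normal decision). Excluded rows keep feeding memory recalls and lagged
regressors; they are only dropped as likelihood/regression targets.

**Known limitation — the (μ₀, σ₀) ridge.** When σ₀ grows, the prior's
influence on both posteriors vanishes and μ₀ becomes unidentified, so the
likelihood has a ridge along which fits occasionally drift to the μ₀ bound
(at a few hundred to a few thousand trials the ridge can even beat the
generating parameters by a couple of log-likelihood units). The
consequences are mild: σ_m and κ remain well recovered, and the
uncertainty states re-simulated from a ridge fit correlate with the
reference states at R² ≈ 0.99 — but point estimates of μ₀ and σ₀ at this
data scale should be interpreted with care.

## Decision-uncertainty estimation

The latent u_t of a subject is estimated by re-running the (fitted)
observer `n_reps` times on the subject's own stimulus sequence and
averaging the simulated u over the repetitions whose simulated choice
matches the observed choice C_t. The default n_reps = 10⁴ puts the
Monte-Carlo SE of each û_t near 0.005 (the reference scheme used 10⁶;
purely a precision choice). Trials where no repetition matches are flagged
NaN rather than fatal. The unconditional estimator (averaging all
repetitions) equals the choice-rate-weighted mixture of the two
conditioned estimators (law of total expectation; asserted in tests).

Note that the conditioned estimate is a conditional *mean*: in a fully
symmetric configuration it is equal for either observed choice but below
0.5, since conditioning on the matched choice truncates the decision
variable's distribution.

## Variable recovery test

Validates the chain simulate → fit → re-simulate: for each cell of a
parameter grid × stimulus sequence, synthetic choices are drawn from the
generating parameters; the *true* u series is the choice-matched estimate
under the generating parameters; the parameters are refit to the synthetic
choices; the *recovered* series is the choice-matched estimate under the
fitted parameters; the cell's score is the squared Pearson correlation
between the two series over target trials. (The choice-matched reference —
rather than the single generative pass — is the estimand the procedure can
recover; against a single pass even the generating parameters score only
R² ≈ 0.26, the irreducible draw noise of one realization.)

The default grid takes values at interior quantiles of an a-priori
"realistic observer" reference range on the unit stimulus scale — μ₀ ∈
±0.4 (near-unbiased), σ₀ ∈ [0.6, 2] (prior spread about the stimulus
spread), σ_m ∈ [0.35, 0.9] (mid-range accuracy), κ ∈ [0.3, 1.2] (history
effects over ~2–5 trials) — uniform for μ₀ and log-uniform for the scale
parameters. Quantiles of the *fitting* box were rejected as a reference:
its lower decades produce observers with deterministic choices and
zero-variance uncertainty, for which the cell R² is undefined. The
scaled-down configuration used by `scripts/acceptance.py` is 2 values per
parameter (16 cells) on one 624-trial three-level sequence (24 runs of 26
trials, the main protocol's run length), 32-start fits and 3000-repetition
estimation; it yields mean R² ≈ 0.98 in ~2 minutes. A broader check (4
sequences, 64 cells) gives 0.975 (95% CI 0.971–0.980): narrow-range
synthetic observers at ~600 trials are recovered somewhat more cleanly
than a heterogeneous human-derived grid would be.

## History regressions

Choices are coded ±1; 3-level stimuli −1/0/+1, 5-level −2…+2; continuous
stimuli and continuous responses are z-scored per subject. The congruence
of a history variable is its product with the current signed choice.
Two families of per-subject models, each followed by a two-sided one-sample
t-test of the coefficients across subjects (no correction across lags;
this mirrors per-coefficient reporting):

* logistic: C_t ~ S_t + S_{t−i} + C_{t−i}, i = 1…L (repulsive bias:
  negative lagged-stimulus coefficients). Perfect separation is flagged
  and coefficients capped at ±10 to keep group t-tests finite.
* linear: standardized response ~ S_t·C_t + S_{t−i}·C_t + C_{t−i}·C_t,
  optionally + RT_{t−1} and its two lag-1 interaction terms (the extended
  model controlling for previously known sequential effects).

RT is normalized per subject as the z-score of log RT by default
(configurable raw / linear-z / log-z; the normalization is a convention,
not a claim). Default lag depth L = 5; effects are detectable out to about
lag 3–5. Unique explained variance is reported as the signed R²:
sign(β_factor) × (R²_full − R²_without-factor); magnitudes are invariant
to regressor scaling, and in an orthogonal design each factor's ΔR² equals
its squared simple correlation with the response. Ratio statistics
(a factor's ΔR² as a percentage of the current-congruence ΔR²) are only
reported when the denominator is positive.

## Physiological pipeline

**Pupil.** Samples are flagged as blink-contaminated when pupil data are
missing for either eye, the pupil jumps by more than 50 recorder units
between samples, or gaze deviates more than 20° from center, with the mask
dilated ±200 ms. Pupil and gaze (x, y, d = √(x²+y²)) are linearly
interpolated across masked spans, linearly detrended, band-passed 0.01–4 Hz
(2nd-order zero-phase Butterworth; the order is a numerical choice),
resampled to 10 Hz; each eye's trace is orthogonalized against the 12 gaze
regressors (x, y, d to powers 1–4), z-scored, the eyes averaged, epochs cut
around stimulus onset (or choice) and baseline-corrected by the 0–500 ms
post-onset mean. Trials with more than half their raw samples masked are
flagged. A residual whose SD falls below 1e−9 of the recording scale is
treated as numerically constant and set to zero rather than re-amplified.

**GLM.** Channel × time signals (BOLD-like, or any uncertainty correlate)
are regressed on three vectors: the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 6) convolved with per-trial impulses scaled by u_t;
the identically built constant-event regressor; and an intercept. The u
coefficient per channel is the effect of interest; p-values are corrected
across channels by Benjamini–Hochberg FDR at 0.05, with an optional
minimum-cluster rule (default 15 contiguous channels) applied only when a
channel adjacency structure is supplied. Time-resolved peak selection is
left to the caller rather than hard-coding a post-onset latency.

## Synthetic data

The generator emulates the binary classification protocols: balanced
pseudo-randomized levels within each run (3-level runs of 26 trials by
default; 5-level and continuous-normal variants), several runs per
session, optional trial-to-trial feedback. The physiological links are
explicit and controllable:

* RT = 0.5 + 1.2·u_t + N(0, 0.15) s, floored at 0.15 s — the simplest
  monotone (linear) uncertainty→RT link; the slope is sized so the
  pre-congruence/current-congruence unique-variance ratio lands in the
  empirically observed 10–46% band (~35% at the defaults). The intercept
  and noise place a small fraction of trials under the 0.3 s exclusion
  floor so the filtering path is always exercised.
* Pupil: 500 Hz binocular traces, baseline 3000 units, per-trial dilation
  kernels (Erlang-shaped, peak ~0.93 s) scaled by u_t, a smooth gaze
  wander whose squared eccentricity leaks into pupil size (the artifact
  the orthogonalization must remove), and a Poisson blink process
  (0.1 s⁻¹, 150 ms) producing missing samples.
* BOLD-like channels at TR 2.2 s: γ·(standardized u-regressor) + a common
  event response + unit Gaussian noise, with a stated fraction of null
  (γ = 0) channels for FDR checks.

What the generator does *not* emulate: sensory transduction detail,
non-stationary parameters or learning across sessions, the empirical RT
distribution's shape beyond a linear-plus-noise link, structured
physiological noise (cardiac/respiratory), or spatial correlation between
channels. Tests passing on these synthetics therefore certify the
*estimators* — identifiability, bias, error control — not the realism of
any particular human dataset, and no attempt is made to reproduce the
human datasets' exact parameter values or effect sizes.

## Problem sizes used in the shipped checks

Parameter recovery runs at ~2000 trials (77 runs) and 10 seeds; the
recovery test at 16 cells × 624 trials; the history-effect signature on 20
subjects × 156 trials; the GLM checks at 50–200 channels × 260 samples.
These sizes make the full suite run in a couple of minutes while keeping
every Monte-Carlo tolerance comfortably non-binding.
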