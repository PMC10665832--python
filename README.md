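# bmbu — boundary-updating observer models for binary classification

When people sort a stream of stimuli into two classes ("small" vs "large",
"low" vs "high"), the criterion that splits the classes is not given — it
has to be inferred from memory of recent stimuli. Because recent memories
are the most precise, the inferred class boundary is continually attracted
to recent stimuli, which biases the next choice *away* from them (the
**repulsive bias**) and, less obviously, modulates **decision uncertainty**:
a choice that agrees in sign with recent stimuli is made against a boundary
that has crept closer, so it is more likely to be wrong (the
**pre-congruence effect**).

This package implements a Bayesian model of that boundary-updating process
and the full analysis chain around it, for researchers in perceptual
decision-making and model-based cognitive neuroscience:

* **Observer model** (`bmbu.core`). Four parameters Θ = (μ₀, σ₀, σ_m, κ):
  a normal prior N(μ₀, σ₀²) over stimulus value, sensory measurement noise
  σ_m, and memory-decay rate κ, with the recall of the stimulus from lag
  *i* carrying noise σ_r(i) = σ_m (1+κ)^i. Per trial the observer forms the
  stimulus posterior from the measurement, the boundary posterior as the
  precision-weighted average of the prior mean and up to 7 recalls
  (weights β_i ∝ σ_r(i)⁻²), and chooses "large" when the stimulus estimate
  exceeds the boundary estimate; v = Φ((ŝ−b̂)/√(σ_s²+σ_b²)) is the decision
  variable and u = min(v, 1−v) the probability the choice is wrong.
  Handicapped variants (constant boundary, last-stimulus-only, equal
  weights, future stimuli) are included for model comparison, plus an
  analytic choice likelihood p(Cₜ | Θ).
* **Fitting** (`bmbu.fitting`). Per-subject maximum likelihood with a
  two-stage multi-start scheme (many short local searches, tight refinement
  of the best candidates run twice), trial exclusions (first of each run,
  responses faster than 0.3 s), log-space search for the positive
  parameters.
* **Uncertainty estimation** (`bmbu.uncertainty`). Trial-to-trial decision
  uncertainty by re-simulating the fitted observer on the subject's own
  stimulus sequence and averaging over repetitions whose simulated choice
  matches the observed one; plus the **variable recovery test**
  (simulate → refit → re-simulate → R²).
* **History statistics** (`bmbu.history`). Congruence coding (history
  variable × current signed choice), per-subject logistic and linear
  history regressions with group t-tests, signed-R² variance partitioning,
  psychometric grids.
* **Physiology** (`bmbu.physio`). Pupil preprocessing (blink detection and
  interpolation, 0.01–4 Hz band-pass, 10 Hz resampling, gaze
  orthogonalization with 12 regressors, baseline-corrected epochs) and a
  canonical-HRF trial-wise GLM with Benjamini–Hochberg FDR for localizing
  uncertainty correlates in channel × time signals.
* **Synthetic data** (`bmbu.synth`). Balanced pseudo-randomized 3- or
  5-level or continuous stimulus protocols, model-governed observers, and
  RT / pupil / BOLD-like signals coupled to the latent uncertainty through
  explicit links — every estimator can be validated against ground truth.

## Worked example

Fit a simulated observer (μ₀ = 0.1, σ₀ = 1.0, σ_m = 0.5, κ = 0.7; 77 runs
of 26 three-level trials), recover its uncertainty states, and test the
history-effect signature on a 20-subject cohort:

```python
import bmbu
from scipy import stats

observer = bmbu.ObserverParams(mu0=0.1, sigma0=1.0, sigma_m=0.5, kappa=0.7)
data = bmbu.generate_observer_dataset(bmbu.ProtocolSpec(n_runs=77), observer, seed=7)

fit = bmbu.fit_mle(data["trials"], bmbu.FitConfig(n_starts=32, n_top=4, seed=0))

table = bmbu.filter_trials(data["trials"])
true_u = bmbu.estimate_uncertainty(table, observer, n_reps=5000, seed=99)
rec_u = bmbu.estimate_uncertainty(table, fit.params_hat, n_reps=5000, seed=0)

cohort = bmbu.generate_cohort(20, bmbu.ProtocolSpec(n_runs=6), observer, seed=42)
design = bmbu.build_history_design(cohort["trials"], "rt", lags=3)
res = bmbu.linear_history_regression(design)
```

prints (see `docs/methods.md` for why μ₀ and σ₀ are reported with care):

```
fitted sensory noise sigma_m = 0.513 (true 0.500)
fitted memory decay  kappa   = 0.554 (true 0.700)
NLL = 789.0 over 1870 trials
uncertainty recovery R^2 = 0.988
RT ~ current congruence  (S_t*C_t):   -0.522  p = 5.5e-15
RT ~ pre-congruence  (S_t-1*C_t):     +0.276  p = 1.0e-09
pre/current unique-variance ratio = 35%
```

The sensory-noise and memory-decay parameters come back close to truth;
re-simulating with the fitted parameters reproduces the trial-to-trial
uncertainty states at R² = 0.99. At the cohort level, response times rise
when the current choice is congruent with the previous stimulus (positive
pre-congruence coefficient) and fall when it is congruent with the current
stimulus (negative current-congruence coefficient), with the pre-congruence
effect explaining ~35% as much unique RT variance as the current-congruence
effect — the qualitative signature of boundary updating.

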