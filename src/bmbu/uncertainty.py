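"""Trial-to-trial decision-uncertainty estimation and the variable
recovery test.

Decision uncertainty is latent: it is recovered by re-running the fitted
observer many times on the subject's own stimulus sequence and averaging
the simulated uncertainty over repetitions whose simulated choice matches
the observed choice.  The recovery test validates the whole chain
(simulate -> fit -> re-simulate) by measuring the R-squared between
uncertainty series generated with known parameters and the series
recovered after refitting those parameters from the synthetic choices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ObserverParams, _simulate_ensemble, simulate_trials
from .fitting import FitConfig, fit_mle

__all__ = [
    "UncertaintySeries",
    "RecoveryReport",
    "REFERENCE_RANGES",
    "estimate_uncertainty",
    "recovery_grid",
    "recovery_test",
]


@dataclass
class UncertaintySeries:
    """Per-trial choice-conditioned uncertainty estimates."""

    u_hat: np.ndarray      # mean simulated uncertainty (probability units)
    v_hat: np.ndarray      # mean decision variable, all repetitions
    c_rate: np.ndarray     # simulated "large" rate, all repetitions
    n_matched: np.ndarray  # repetitions whose choice matched the observed one
    n_reps: int

    @property
    def unmatched(self) -> np.ndarray:
        """Trials where no simulated choice matched the observed one."""
        return self.n_matched == 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"u_hat": self.u_hat, "v_hat": self.v_hat,
             "c_rate": self.c_rate, "n_matched": self.n_matched}
        )


def estimate_uncertainty(table: pd.DataFrame, params: ObserverParams,
                         n_reps: int = 10_000, seed: int | np.random.Generator = 0,
                         condition_on_choice: bool = True) -> UncertaintySeries:
    """Simulate the observer ``n_reps`` times on the subject's stimulus
    sequence and average the uncertainty over choice-matched repetitions.

    ``table`` needs ``stimulus`` and ``run`` columns, plus ``choice`` when
    ``condition_on_choice`` is on.  Trials where no repetition matched the
    observed choice get ``u_hat = NaN`` and are flagged, not fatal.
    Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stimuli = table["stimulus"].to_numpy(dtype=float)
    runs = table["run"].to_numpy() if "run" in table.columns else None
    v, c, u = _simulate_ensemble(stimuli, params, n_reps, rng, runs=runs)
    if condition_on_choice:
        observed = table["choice"].to_numpy()
        match = c == observed[None, :]
        n_matched = match.sum(axis=0)
        with np.errstate(invalid="ignore"):
            u_hat = np.where(n_matched > 0, (u * match).sum(axis=0) / np.maximum(n_matched, 1), np.nan)
        if np.any(n_matched == 0):
            warnings.warn(f"{int((n_matched == 0).sum())} trial(s) had no choice-matched "
                          "simulation; u_hat set to NaN", stacklevel=2)
    else:
        n_matched = np.full(stimuli.size, n_reps)
        u_hat = u.mean(axis=0)
    return UncertaintySeries(u_hat=u_hat, v_hat=v.mean(axis=0),
                             c_rate=(c > 0).mean(axis=0), n_matched=n_matched,
                             n_reps=n_reps)


# ---------------------------------------------------------------------------
# Variable recovery test
# ---------------------------------------------------------------------------

#: A-priori reference ranges for a realistic observer on the unit stimulus
#: scale (discrete levels at -1/0/+1 or z-scored continuous stimuli):
#: near-unbiased long-term mean, prior spread about the stimulus spread,
#: sensory noise giving mid-range accuracy, moderate memory decay.
REFERENCE_RANGES = {
    "mu0": (-0.4, 0.4),
    "sigma0": (0.6, 2.0),
    "sigma_m": (0.35, 0.9),
    "kappa": (0.3, 1.2),
}


@dataclass
class RecoveryReport:
    cells: pd.DataFrame = field(repr=False)  # per-cell true/fitted params and R^2
    mean_r2: float = np.nan
    ci95: tuple = (np.nan, np.nan)

    def summary(self) -> str:
        lo, hi = self.ci95
        return (f"uncertainty recovery over {len(self.cells)} cells: "
                f"mean R^2 = {self.mean_r2:.3f} (95% CI {lo:.3f}-{hi:.3f})")


def recovery_grid(n_values: int = 4, ranges: dict | None = None) -> list[ObserverParams]:
    """Full factorial grid of generating parameters.

    Each parameter takes ``n_values`` values at the interior quantiles
    i/(n_values+1) of a uniform (mu0) or log-uniform (sigma0, sigma_m,
    kappa) reference distribution over ``ranges``.
    """
    ranges = {**REFERENCE_RANGES, **(ranges or {})}
    qs = np.arange(1, n_values + 1) / (n_values + 1)
    axes = {}
    for name, (lo, hi) in ranges.items():
        if name == "mu0":
            axes[name] = lo + qs * (hi - lo)
        else:
            axes[name] = np.exp(np.log(lo) + qs * (np.log(hi) - np.log(lo)))
    return [
        ObserverParams(mu0=m, sigma0=s0, sigma_m=sm, kappa=k)
        for m, s0, sm, k in itertools.product(
            axes["mu0"], axes["sigma0"], axes["sigma_m"], axes["kappa"])
    ]


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan
    return float(stats.pearsonr(x[ok], y[ok])[0] ** 2)


def recovery_test(grid: list[ObserverParams] | None = None,
                  sequences: list[pd.DataFrame] | None = None,
                  fit_config: FitConfig | None = None,
                  n_reps: int = 3000, seed: int = 0,
                  refit: bool = True) -> RecoveryReport:
    """Simulate -> fit -> re-simulate validation of the uncertainty estimator.

    For every grid cell x stimulus sequence: synthetic choices are drawn
    from the generating parameters, the *true* uncertainty series is the
    choice-matched estimate under those generating parameters, the four
    parameters are refit to the synthetic choices by maximum likelihood
    (skipped when ``refit`` is off — the self-recovery control), the
    *recovered* series is the choice-matched estimate under the fitted
    parameters, and the squared Pearson correlation between the two series
    (target trials only) is the cell's R^2.  Fitting failures are recorded
    per cell without aborting the grid.

    ``sequences`` are trial tables with ``stimulus`` and ``run`` columns
    (see :func:`bmbu.synth.generate_stimulus_sequence`).
    """
    from .fitting import filter_trials  # local import to avoid cycle noise
    from .synth import ProtocolSpec, generate_stimulus_sequence

    if grid is None:
        grid = recovery_grid()
    if sequences is None:
        sequences = [generate_stimulus_sequence(ProtocolSpec(n_runs=24), seed=seed + 900_000)]
    rng = np.random.default_rng(seed)
    rows = []
    for i_cell, true_params in enumerate(grid):
        for i_seq, seq in enumerate(sequences):
            cell_seed = int(rng.integers(2 ** 31 - 1))
            table = seq.copy()
            sim = simulate_trials(table["stimulus"].to_numpy(dtype=float), true_params,
                                  seed=cell_seed, runs=table["run"].to_numpy())
            table["choice"] = sim["choice"]
            table = filter_trials(table)
            row = {"cell": i_cell, "sequence": i_seq,
                   **{f"true_{k}": getattr(true_params, k)
                      for k in ("mu0", "sigma0", "sigma_m", "kappa")}}
            try:
                if refit:
                    cfg = fit_config or FitConfig()
                    cfg = FitConfig(**{**cfg.__dict__, "seed": cell_seed})
                    fit = fit_mle(table, cfg, variant=true_params.variant)
                    fitted = fit.params_hat
                    row.update({f"fit_{k}": getattr(fitted, k)
                                for k in ("mu0", "sigma0", "sigma_m", "kappa")},
                               neg_log_lik=fit.neg_log_lik)
                else:
                    fitted = true_params
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    true_u = estimate_uncertainty(table, true_params, n_reps=n_reps,
                                                  seed=cell_seed + 1)
                    rec_u = estimate_uncertainty(table, fitted, n_reps=n_reps,
                                                 seed=cell_seed + 2)
                mask = table["is_target"].to_numpy(dtype=bool)
                row["r2"] = _r_squared(true_u.u_hat[mask], rec_u.u_hat[mask])
            except Exception as exc:  # keep the grid alive on per-cell failures
                row["r2"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
    cells = pd.DataFrame(rows)
    r2 = cells["r2"].dropna().to_numpy()
    if r2.size == 0:
        return RecoveryReport(cells=cells)
    mean = float(r2.mean())
    if r2.size > 1 and np.std(r2) > 0:
        lo, hi = stats.t.interval(0.95, r2.size - 1, loc=mean,
                                  scale=stats.sem(r2))
    else:
        lo = hi = mean
    return RecoveryReport(cells=cells, mean_r2=mean, ci95=(float(lo), float(hi)))
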