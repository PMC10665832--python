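"""Bayesian observer model of boundary updating for binary classification.

The observer classifies a scalar stimulus as "small" or "large" relative to
an internal class boundary that is itself inferred, trial by trial, from
noisy memory recalls of recent stimuli.  The generative model has four
parameters, Theta = (mu0, sigma0, sigma_m, kappa):

* ``mu0``, ``sigma0`` — mean and SD of the normal prior over stimulus value
  (the observer's long-term belief about the stimulus distribution);
* ``sigma_m`` — SD of the sensory measurement of the current stimulus;
* ``kappa`` — memory-decay rate: the recall of the stimulus seen ``i``
  trials ago carries noise ``sigma_r(i) = sigma_m * (1 + kappa)**i``.

On every trial the observer (1) infers the current stimulus from the noisy
measurement and the prior, (2) infers the class boundary as the posterior
mean of the stimulus distribution given up to ``n_memory`` noisy recalls of
past stimuli, and (3) chooses "large" when the stimulus estimate exceeds
the boundary estimate.  Decision uncertainty is the probability that this
choice is incorrect given both posteriors.

Because recent recalls are the least noisy, the boundary is attracted to
recent stimuli; this produces the repulsive bias in choices and history
effects on decision uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "VARIANTS",
    "ObserverParams",
    "TrialInference",
    "memory_noise_sd",
    "boundary_weights",
    "infer_stimulus",
    "infer_boundary",
    "decide",
    "simulate_trials",
    "choice_probability",
]

#: Model variants.  ``full`` is the boundary-updating observer; the others
#: are the handicapped comparison models: a fixed boundary at ``mu0``
#: (``constant_boundary``), a boundary informed only by the immediately
#: preceding stimulus (``last_only``), recall noise that does not grow with
#: lag (``equal_weights``, i.e. kappa pinned to 0), and a boundary built
#: from upcoming instead of past stimuli (``future``, a causality control).
VARIANTS = ("full", "constant_boundary", "last_only", "equal_weights", "future")


@dataclass(frozen=True)
class ObserverParams:
    """Generative-model parameters Theta = (mu0, sigma0, sigma_m, kappa)."""

    mu0: float = 0.0
    sigma0: float = 1.0
    sigma_m: float = 0.6
    kappa: float = 0.7
    variant: str = "full"
    n_memory: int = 7

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be > 0")
        if not self.sigma_m > 0:
            raise ValueError("sigma_m must be > 0")
        if self.kappa < 0 or (self.kappa == 0 and self.variant != "equal_weights"):
            raise ValueError("kappa must be > 0 (kappa = 0 only for the equal_weights variant)")
        if self.n_memory < 1:
            raise ValueError("n_memory must be >= 1")

    @property
    def kappa_eff(self) -> float:
        """Effective decay rate: the equal-weights variant pins kappa to 0."""
        return 0.0 if self.variant == "equal_weights" else self.kappa

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu0": self.mu0,
                "sigma0": self.sigma0,
                "sigma_m": self.sigma_m,
                "kappa": self.kappa,
                "variant": self.variant,
                "n_memory": self.n_memory,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ObserverParams":
        return cls(**json.loads(text))

    def with_(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialInference:
    """Latent state of a single decided trial."""

    m: float
    r: np.ndarray
    s_hat: float
    s_sd: float
    b_hat: float
    b_sd: float
    v: float
    c: int
    u: float


def memory_noise_sd(params: ObserverParams, lag) -> np.ndarray | float:
    """SD of the recall of the stimulus seen ``lag`` trials ago.

    sigma_r(lag) = sigma_m * (1 + kappa)**lag, strictly increasing in lag
    for kappa > 0: older stimuli are remembered less precisely.
    """
    lag_arr = np.asarray(lag)
    if np.any(lag_arr < 1) or not np.issubdtype(lag_arr.dtype, np.integer) and np.any(lag_arr != np.floor(lag_arr)):
        raise ValueError("lag must be a positive integer")
    out = params.sigma_m * (1.0 + params.kappa_eff) ** lag_arr
    return out if out.ndim else float(out)


def _available_mask(params: ObserverParams, available=None) -> np.ndarray:
    n = params.n_memory
    if available is None:
        avail = np.ones(n, dtype=bool)
    else:
        avail = np.asarray(available, dtype=bool)
        if avail.shape != (n,):
            raise ValueError(f"availability mask must have length n_memory = {n}")
    if params.variant == "last_only":
        last = np.zeros(n, dtype=bool)
        last[0] = avail[0]
        avail = last
    return avail


def boundary_weights(params: ObserverParams, available=None) -> np.ndarray:
    """Precision weights (beta_0, beta_1..beta_n) of the boundary posterior.

    beta_0 weights the prior mean, beta_i the recall from lag i; the weights
    are the normalized precisions 1/sigma**2 of the respective sources, so
    they sum to one and decay geometrically with lag (proportional to
    (1 + kappa)**(-2 i)).  ``available`` marks which lags have a recall
    (early-session trials have fewer); unavailable lags get zero weight and
    their precision is simply absent from the normalizer, i.e. the posterior
    uses the prior plus whatever recalls exist.
    """
    n = params.n_memory
    avail = _available_mask(params, available)
    prec0 = params.sigma0 ** -2
    lag_sd = params.sigma_m * (1.0 + params.kappa_eff) ** np.arange(1, n + 1)
    prec = np.where(avail, lag_sd ** -2.0, 0.0)
    z = prec0 + prec.sum()
    return np.concatenate(([prec0 / z], prec / z))


def infer_stimulus(m, params: ObserverParams):
    """Posterior mean and SD of the current stimulus given measurement ``m``.

    Conjugate normal update of the prior N(mu0, sigma0) with the likelihood
    N(m, sigma_m); the estimate is shrunk from ``m`` toward ``mu0``.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("measurement must be finite")
    v0, vm = params.sigma0 ** 2, params.sigma_m ** 2
    s_hat = (v0 * m + vm * params.mu0) / (v0 + vm)
    s_sd = params.sigma0 * params.sigma_m / np.sqrt(v0 + vm)
    return (float(s_hat) if s_hat.ndim == 0 else s_hat, float(s_sd))


def infer_boundary(recalls, params: ObserverParams):
    """Posterior mean and SD of the class boundary from memory recalls.

    ``recalls[i-1]`` is the recalled value of the stimulus from lag ``i``;
    NaN marks an unavailable recall (early in a session).  The boundary is
    the precision-weighted average of the prior mean and the recalls; its SD
    equals the conjugate posterior SD 1/sqrt(sum of precisions).
    """
    r = np.asarray(recalls, dtype=float)
    if r.shape != (params.n_memory,):
        raise ValueError(f"expected {params.n_memory} recalls, got shape {r.shape}")
    avail = np.isfinite(r)
    w = boundary_weights(params, available=avail)
    b_hat = w[0] * params.mu0 + np.nansum(w[1:] * np.where(avail, r, 0.0))
    lag_sd = params.sigma_m * (1.0 + params.kappa_eff) ** np.arange(1, params.n_memory + 1)
    b_var = w[0] ** 2 * params.sigma0 ** 2 + np.sum(
        np.where(_available_mask(params, avail), (w[1:] * lag_sd) ** 2, 0.0)
    )
    return float(b_hat), float(np.sqrt(b_var))


def decide(s_hat, s_sd, b_hat, b_sd):
    """Choice, decision variable and decision uncertainty of one trial.

    v = Phi((s_hat - b_hat) / sqrt(s_sd**2 + b_sd**2)) is the posterior
    probability that the stimulus exceeds the boundary; the choice is
    "large" (+1) when v > 0.5, otherwise "small" (-1; ties go to "small").
    Uncertainty u = min(v, 1 - v) is the probability the choice is wrong.
    """
    s_hat = np.asarray(s_hat, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    denom = np.sqrt(np.asarray(s_sd, dtype=float) ** 2 + np.asarray(b_sd, dtype=float) ** 2)
    if np.any((denom == 0) & (s_hat == b_hat)):
        raise ValueError("degenerate decision: zero posterior spread with s_hat == b_hat")
    with np.errstate(divide="ignore"):
        z = np.where(denom > 0, (s_hat - b_hat) / np.where(denom > 0, denom, 1.0),
                     np.inf * np.sign(s_hat - b_hat))
    v = ndtr(z)
    c = np.where(v > 0.5, 1, -1)
    u = np.minimum(v, 1.0 - v)
    if v.ndim == 0:
        return float(v), int(c), float(u)
    return v, c.astype(int), u


# ---------------------------------------------------------------------------
# Sequence-level machinery
# ---------------------------------------------------------------------------

def _lag_matrix(stimuli: np.ndarray, runs: np.ndarray | None, n: int, future: bool = False):
    """(T, n) matrix of lagged true stimulus values, NaN where the lag would
    cross a run boundary or the edge of the sequence."""
    s = np.asarray(stimuli, dtype=float)
    t_len = s.size
    if t_len == 0:
        raise ValueError("empty stimulus sequence")
    runs_arr = np.zeros(t_len) if runs is None else np.asarray(runs)
    lag_mat = np.full((t_len, n), np.nan)
    idx = np.arange(t_len)
    for i in range(1, n + 1):
        src = idx + i if future else idx - i
        ok = (src >= 0) & (src < t_len)
        ok &= runs_arr[np.clip(src, 0, t_len - 1)] == runs_arr
        lag_mat[ok, i - 1] = s[np.clip(src, 0, t_len - 1)[ok]]
    return lag_mat


def _posterior_pieces(stimuli, runs, params: ObserverParams):
    """Per-trial boundary-posterior constants shared by the analytic
    likelihood and the simulator: lag matrix, availability, weights, Z."""
    n = params.n_memory
    lag_mat = _lag_matrix(stimuli, runs, n, future=params.variant == "future")
    avail = np.isfinite(lag_mat)
    if params.variant == "last_only":
        avail[:, 1:] = False
    lag_sd = params.sigma_m * (1.0 + params.kappa_eff) ** np.arange(1, n + 1)
    prec = np.where(avail, lag_sd ** -2.0, 0.0)
    z = params.sigma0 ** -2 + prec.sum(axis=1)
    beta = prec / z[:, None]
    beta0 = params.sigma0 ** -2 / z
    return lag_mat, avail, lag_sd, beta0, beta, z


def choice_probability(stimuli, params: ObserverParams, runs=None) -> np.ndarray:
    """Analytic per-trial probability of a "large" choice given the true
    stimulus history.

    The difference s_hat - b_hat is a linear combination of the Gaussian
    measurement and recalls, hence itself Gaussian with mean
    M_t = w*S_t + (1-w)*mu0 - beta0*mu0 - sum_i beta_i*S_{t-i}
    (w = sigma0**2 / (sigma0**2 + sigma_m**2)) and variance
    V_t = w**2*sigma_m**2 + sum_i beta_i**2*sigma_r(i)**2, so
    P(large) = Phi(M_t / sqrt(V_t)).  To evaluate a single trial, pass its
    history window (last n_memory+1 true stimuli) and take the last element.
    """
    s = np.asarray(stimuli, dtype=float)
    if s.size == 0:
        raise ValueError("empty stimulus sequence")
    if params.variant == "constant_boundary":
        return ndtr((s - params.mu0) / params.sigma_m)
    lag_mat, avail, lag_sd, beta0, beta, z = _posterior_pieces(s, runs, params)
    w = params.sigma0 ** 2 / (params.sigma0 ** 2 + params.sigma_m ** 2)
    mean = (
        w * s
        + (1.0 - w) * params.mu0
        - beta0 * params.mu0
        - np.nansum(beta * np.where(avail, lag_mat, 0.0), axis=1)
    )
    var = (w * params.sigma_m) ** 2 + ((beta * lag_sd) ** 2 * avail).sum(axis=1)
    return ndtr(mean / np.sqrt(var))


def _simulate_ensemble(stimuli, params: ObserverParams, n_reps: int, rng: np.random.Generator,
                       runs=None, max_chunk_elems: int = 20_000_000):
    """Simulate ``n_reps`` independent observers on one stimulus sequence.

    Returns (v, c, u) arrays of shape (n_reps, T).  Fresh measurement and
    recall draws on every trial and repetition.
    """
    s = np.asarray(stimuli, dtype=float)
    t_len = s.size
    if t_len == 0:
        raise ValueError("empty stimulus sequence")
    v_out = np.empty((n_reps, t_len))
    if params.variant == "constant_boundary":
        for lo in range(0, n_reps, max(1, max_chunk_elems // t_len)):
            hi = min(n_reps, lo + max(1, max_chunk_elems // t_len))
            s_hat = s + params.sigma_m * rng.standard_normal((hi - lo, t_len))
            v_out[lo:hi] = ndtr((s_hat - params.mu0) / params.sigma_m)
    else:
        lag_mat, avail, lag_sd, beta0, beta, z = _posterior_pieces(s, runs, params)
        lag0 = np.where(avail, lag_mat, 0.0)
        b_sd = 1.0 / np.sqrt(z)
        v0, vm = params.sigma0 ** 2, params.sigma_m ** 2
        s_sd = params.sigma0 * params.sigma_m / np.sqrt(v0 + vm)
        pooled = np.sqrt(s_sd ** 2 + b_sd ** 2)
        chunk = max(1, max_chunk_elems // (t_len * (params.n_memory + 1)))
        for lo in range(0, n_reps, chunk):
            hi = min(n_reps, lo + chunk)
            m = s + params.sigma_m * rng.standard_normal((hi - lo, t_len))
            eps = rng.standard_normal((hi - lo, t_len, params.n_memory)) * lag_sd
            recalls = lag0 + np.where(avail, eps, 0.0)
            b_hat = beta0 * params.mu0 + np.einsum("tn,rtn->rt", beta, recalls)
            s_hat = (v0 * m + vm * params.mu0) / (v0 + vm)
            v_out[lo:hi] = ndtr((s_hat - b_hat) / pooled)
    c = np.where(v_out > 0.5, 1, -1)
    u = np.minimum(v_out, 1.0 - v_out)
    return v_out, c, u


def simulate_trials(stimuli, params: ObserverParams, seed: int | np.random.Generator = 0,
                    runs=None):
    """One generative pass of the observer over a stimulus sequence.

    Draws a measurement m ~ N(S_t, sigma_m) and fresh recalls
    r_i ~ N(S_{t-i}, sigma_r(i)) on every trial, runs the inference chain
    and records the full latent state.  Returns a dict of per-trial arrays
    with keys ``m, recalls, s_hat, s_sd, b_hat, b_sd, v, choice, u``.
    Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(stimuli, dtype=float)
    t_len = s.size
    if t_len == 0:
        raise ValueError("empty stimulus sequence")
    n = params.n_memory
    if params.variant == "constant_boundary":
        s_hat = s + params.sigma_m * rng.standard_normal(t_len)
        out = {
            "m": s_hat.copy(),
            "recalls": np.full((t_len, n), np.nan),
            "s_hat": s_hat,
            "s_sd": np.full(t_len, params.sigma_m),
            "b_hat": np.full(t_len, params.mu0),
            "b_sd": np.zeros(t_len),
        }
        v = ndtr((s_hat - params.mu0) / params.sigma_m)
    else:
        lag_mat, avail, lag_sd, beta0, beta, z = _posterior_pieces(s, runs, params)
        m = s + params.sigma_m * rng.standard_normal(t_len)
        recalls = np.where(avail, lag_mat + rng.standard_normal((t_len, n)) * lag_sd, np.nan)
        b_hat = beta0 * params.mu0 + np.nansum(beta * np.where(avail, recalls, 0.0), axis=1)
        b_sd = 1.0 / np.sqrt(z)
        s_hat_arr, s_sd = infer_stimulus(m, params)
        out = {
            "m": m,
            "recalls": recalls,
            "s_hat": np.asarray(s_hat_arr),
            "s_sd": np.full(t_len, s_sd),
            "b_hat": b_hat,
            "b_sd": b_sd,
        }
        v = ndtr((out["s_hat"] - b_hat) / np.sqrt(s_sd ** 2 + b_sd ** 2))
    out["v"] = v
    out["choice"] = np.where(v > 0.5, 1, -1)
    out["u"] = np.minimum(v, 1.0 - v)
    return out
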