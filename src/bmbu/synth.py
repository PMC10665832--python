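"""Synthetic experiments: stimulus protocols, model-governed observers and
uncertainty-coupled physiological signals.

Emulates binary size/pitch classification protocols — pseudo-randomized
3-level or 5-level stimulus sequences balanced within runs, or continuous
normally-distributed stimuli — and generates complete datasets from
observers whose choices follow the boundary-updating model with known
parameters.  Response time, pupil and BOLD-like channel signals are coupled
to the simulated decision uncertainty through explicit, controllable links,
so that every downstream estimator can be validated against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ObserverParams, simulate_trials
from .physio import PupilRecording, hrf_regressor

__all__ = [
    "ProtocolSpec",
    "LinkSpec",
    "generate_stimulus_sequence",
    "generate_observer_dataset",
    "generate_cohort",
    "write_trials",
    "read_trials",
]

_LEVELS = {"levels3": (-1.0, 0.0, 1.0), "levels5": (-2.0, -1.0, 0.0, 1.0, 2.0)}


@dataclass(frozen=True)
class ProtocolSpec:
    """Experimental protocol of one synthetic session.

    Defaults follow the main 3-level ring protocol (26-trial runs); the
    inter-trial interval only matters for physiological trace length and
    defaults to a desk-scale 3 s.
    """

    granularity: str = "levels3"
    n_trials_per_run: int = 26
    n_runs: int = 4
    iti: float = 3.0
    feedback: bool = False
    levels: tuple | None = None
    mu_s: float = 0.0
    sigma_s: float = 1.0

    def __post_init__(self) -> None:
        if self.granularity not in ("levels3", "levels5", "continuous"):
            raise ValueError(f"unknown granularity {self.granularity!r}")

    @property
    def level_values(self) -> tuple | None:
        if self.granularity == "continuous":
            return None
        return self.levels or _LEVELS[self.granularity]


@dataclass(frozen=True)
class LinkSpec:
    """How latent decision uncertainty drives the measured correlates.

    RT is linear in u with additive Gaussian noise and a hard floor;
    per-trial pupil responses are uncertainty-scaled dilation kernels on
    top of a gaze-coupled artifact and a blink process; BOLD-like channels
    are uncertainty-scaled HRF regressors plus noise, with a stated
    fraction of null channels.
    """

    rt_intercept: float = 0.5     # s
    rt_slope: float = 1.2         # s per unit u; > 0: uncertainty slows RT
    rt_sigma: float = 0.15        # s
    rt_floor: float = 0.15        # s
    pupil_fs: float = 500.0       # Hz
    pupil_baseline: float = 3000.0  # recorder units
    pupil_gain: float = 60.0      # dilation units per unit u
    artifact_gain: float = 3.0    # pupil units per squared degree of gaze
    blink_rate: float = 0.1       # blinks per second
    blink_duration: float = 0.15  # s
    bold_tr: float = 2.2          # s
    bold_gain: float = 0.5        # coefficient on the standardized u regressor
    bold_sigma: float = 1.0
    n_channels: int = 30
    null_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.rt_slope > 0:
            raise ValueError("rt_slope must be > 0 (uncertainty slows responses)")
        if min(self.rt_sigma, self.bold_sigma) <= 0:
            raise ValueError("noise SDs must be > 0")


def generate_stimulus_sequence(spec: ProtocolSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Pseudo-randomized stimulus sequence: balanced shuffled levels within
    each run (discrete protocols) or i.i.d. normal draws (continuous).
    Deterministic given ``seed``.  Returns columns run, trial, stimulus,
    onset (s)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for run in range(spec.n_runs):
        n = spec.n_trials_per_run
        if spec.granularity == "continuous":
            s = rng.normal(spec.mu_s, spec.sigma_s, size=n)
        else:
            levels = np.asarray(spec.level_values, dtype=float)
            per, extra = divmod(n, len(levels))
            if extra:
                warnings.warn(f"{n} trials not divisible by {len(levels)} levels; "
                              "using nearest balanced allocation", stacklevel=2)
            counts = np.full(len(levels), per)
            counts[rng.choice(len(levels), size=extra, replace=False)] += 1
            s = rng.permutation(np.repeat(levels, counts))
        frames.append(pd.DataFrame({"run": run, "trial": np.arange(n), "stimulus": s,
                                    "onset": np.arange(n) * spec.iti}))
    return pd.concat(frames, ignore_index=True)


def _pupil_kernel(fs: float, duration: float = 4.0) -> np.ndarray:
    """Pupil dilation impulse response (Erlang-style, peak ~0.93 s),
    peak-normalized."""
    t = np.arange(0, duration, 1.0 / fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / 0.93) ** 10.1 * np.exp(10.1 * (1 - t / 0.93))
    h[0] = 0.0
    return h


def _make_pupil(onsets: np.ndarray, u: np.ndarray, duration: float,
                link: LinkSpec, rng: np.random.Generator) -> PupilRecording:
    fs = link.pupil_fs
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # slow gaze wander around fixation, a couple of degrees in amplitude
    def wander(scale):
        from scipy.ndimage import gaussian_filter1d
        return gaussian_filter1d(np.cumsum(rng.normal(0, scale, n)), fs * 0.5, mode="nearest")
    gx, gy = wander(0.02), wander(0.02)
    d = np.hypot(gx, gy)
    dilation = np.zeros(n)
    idx = np.round(onsets * fs).astype(int)
    np.add.at(dilation, np.clip(idx, 0, n - 1), u * link.pupil_gain)
    dilation = np.convolve(dilation, _pupil_kernel(fs))[:n]
    base = link.pupil_baseline + dilation + link.artifact_gain * d ** 2
    pupil = np.column_stack([base + rng.normal(0, 2.0, n) for _ in range(2)])
    n_blinks = rng.poisson(link.blink_rate * duration)
    for start in rng.uniform(0, duration - link.blink_duration, size=n_blinks):
        k0 = int(start * fs)
        pupil[k0: k0 + int(link.blink_duration * fs), :] = np.nan
    return PupilRecording(time=t, pupil=pupil, gaze_x=gx, gaze_y=gy)


def _make_bold(onsets: np.ndarray, u: np.ndarray, duration: float,
               link: LinkSpec, rng: np.random.Generator):
    n_samp = int(np.ceil(duration / link.bold_tr))
    u_reg = hrf_regressor(u, onsets, n_samp, link.bold_tr)
    ev_reg = hrf_regressor(np.ones_like(u), onsets, n_samp, link.bold_tr)
    n_null = int(round(link.null_fraction * link.n_channels))
    gains = np.r_[np.zeros(n_null), np.full(link.n_channels - n_null, link.bold_gain)]
    signals = (gains[:, None] * u_reg[None, :] + 0.8 * ev_reg[None, :]
               + rng.normal(0, link.bold_sigma, (link.n_channels, n_samp)))
    return signals, gains


def generate_observer_dataset(spec: ProtocolSpec, params: ObserverParams,
                              link: LinkSpec | None = None,
                              seed: int | np.random.Generator = 0, subject: int = 0,
                              make_pupil: bool = False, make_bold: bool = False) -> dict:
    """One synthetic subject: trial table, latent truth, optional signals.

    Simulates the observer on a fresh stimulus sequence, then emits RT (and
    feedback where the protocol has it) per :class:`LinkSpec`.  The
    returned dict has ``trials`` (subject, run, trial, stimulus, choice,
    rt[, feedback]), ``truth`` (latent m, s_hat, b_hat, b_sd, v, u), and
    optionally ``pupil`` (:class:`PupilRecording`), ``bold`` (channels x
    time) with ``bold_gains``.  First-of-run rows and occasional fast
    (< 0.3 s) responses are present by construction so downstream trial
    filtering is exercised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    link = link or LinkSpec()
    table = generate_stimulus_sequence(spec, seed=rng)
    stimuli = table["stimulus"].to_numpy()
    runs = table["run"].to_numpy()
    sim = simulate_trials(stimuli, params, seed=rng, runs=runs)
    rt = link.rt_intercept + link.rt_slope * sim["u"] + rng.normal(0, link.rt_sigma, len(stimuli))
    trials = table.assign(subject=subject, choice=sim["choice"],
                          rt=np.maximum(rt, link.rt_floor))
    if spec.feedback:
        trials["feedback"] = np.where(trials["choice"] == np.sign(stimuli).astype(int), 1,
                                      np.where(stimuli == 0, rng.integers(0, 2, len(stimuli)) * 2 - 1, -1))
    truth = pd.DataFrame({k: sim[k] for k in ("m", "s_hat", "b_hat", "b_sd", "v", "u")})
    truth.insert(0, "subject", subject)
    out = {"trials": trials, "truth": truth}
    # absolute onsets across the concatenated session, one run after another
    run_len = spec.n_trials_per_run * spec.iti + 10.0
    onsets = trials["onset"].to_numpy() + trials["run"].to_numpy() * run_len + 2.0
    duration = spec.n_runs * run_len
    if make_pupil:
        out["pupil"] = _make_pupil(onsets, sim["u"], duration, link, rng)
        out["pupil_onsets"] = onsets
    if make_bold:
        out["bold"], out["bold_gains"] = _make_bold(onsets, sim["u"], duration, link, rng)
        out["bold_onsets"] = onsets
    return out


def generate_cohort(n_subjects: int, spec: ProtocolSpec | None = None,
                    params: ObserverParams | None = None, link: LinkSpec | None = None,
                    seed: int = 0, **kwargs) -> dict:
    """A cohort of synthetic subjects sharing protocol and parameters.

    Returns concatenated ``trials`` and ``truth`` tables (the per-trial
    latent uncertainty is merged into ``trials`` as column ``u`` for
    convenience in history regressions).
    """
    spec = spec or ProtocolSpec()
    params = params or ObserverParams()
    rng = np.random.default_rng(seed)
    trials, truths = [], []
    for subj in range(n_subjects):
        ds = generate_observer_dataset(spec, params, link=link, seed=rng,
                                       subject=subj, **kwargs)
        t = ds["trials"].copy()
        t["u"] = ds["truth"]["u"].to_numpy()
        trials.append(t)
        truths.append(ds["truth"])
    return {"trials": pd.concat(trials, ignore_index=True),
            "truth": pd.concat(truths, ignore_index=True)}


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)
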