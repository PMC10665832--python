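"""Pupil-trace preprocessing and the trial-wise uncertainty GLM.

The pupil pipeline follows the standard eye-tracking hygiene for
uncertainty-locked analyses: blink detection (missing samples, implausible
sample-to-sample jumps, off-screen gaze) with a +/-200 ms contamination
window, linear interpolation, detrending, 0.01-4 Hz band-pass, 10 Hz
resampling, orthogonalization against gaze position (x, y, eccentricity d,
each to the 4th power: 12 regressors), z-scoring, eye averaging, trial
epoching and 0-500 ms post-onset baseline correction.

The GLM localizes uncertainty correlates in generic channel x time signals
(BOLD-like or pupil): each channel is regressed on a canonical-HRF-convolved
trial regressor scaled by per-trial uncertainty u_t, an identically built
constant-event regressor, and an intercept; the u coefficient is the effect
of interest, with Benjamini-Hochberg FDR across channels and optional
minimum-cluster filtering when channel adjacency is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PupilRecording",
    "SignalEpochs",
    "detect_blinks",
    "preprocess_pupil",
    "canonical_hrf",
    "hrf_regressor",
    "glm_uncertainty",
]


@dataclass
class PupilRecording:
    """Raw binocular recording: times (s), pupil size per eye (recorder
    units), gaze position (degrees from screen center)."""

    time: np.ndarray
    pupil: np.ndarray   # (n_samples, 2)
    gaze_x: np.ndarray
    gaze_y: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def gaze_d(self) -> np.ndarray:
        return np.hypot(self.gaze_x, self.gaze_y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "pupilL": self.pupil[:, 0],
                             "pupilR": self.pupil[:, 1], "gazeX": self.gaze_x,
                             "gazeY": self.gaze_y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PupilRecording":
        return cls(time=df["time"].to_numpy(dtype=float),
                   pupil=df[["pupilL", "pupilR"]].to_numpy(dtype=float),
                   gaze_x=df["gazeX"].to_numpy(dtype=float),
                   gaze_y=df["gazeY"].to_numpy(dtype=float))


@dataclass
class SignalEpochs:
    """Trial x time matrix locked to an event, baseline-corrected."""

    data: np.ndarray
    times: np.ndarray            # seconds relative to the lock event
    flagged: np.ndarray          # trials with > 50% masked raw samples
    fs: float = 10.0
    trace: np.ndarray | None = field(default=None, repr=False)  # continuous, pre-epoch
    gaze_regressors: np.ndarray | None = field(default=None, repr=False)


def detect_blinks(rec: PupilRecording, jump_threshold: float = 50.0,
                  gaze_threshold: float = 20.0, pad: float = 0.2) -> np.ndarray:
    """Boolean mask of blink-contaminated samples.

    A sample is flagged when (i) pupil data are missing for either eye,
    (ii) the pupil size jumps by more than ``jump_threshold`` recorder
    units from the previous sample, or (iii) gaze deviates more than
    ``gaze_threshold`` degrees from the screen center; the mask is then
    dilated by ``pad`` seconds on both sides.
    """
    missing = np.isnan(rec.pupil).any(axis=1)
    jump = np.zeros(len(rec.time), dtype=bool)
    diffs = np.abs(np.diff(rec.pupil, axis=0))
    with np.errstate(invalid="ignore"):
        jump[1:] = np.nanmax(diffs, axis=1) > jump_threshold
    off_screen = rec.gaze_d > gaze_threshold
    mask = missing | jump | off_screen
    if mask.any() and pad > 0:
        width = int(round(pad * rec.fs))
        idx = np.flatnonzero(mask)
        dilated = np.zeros_like(mask)
        for k in idx:
            dilated[max(0, k - width): k + width + 1] = True
        mask = dilated
    return mask


def _interpolate(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if not bad.any():
        return x
    good = ~bad
    if not good.any():
        raise ValueError("no clean samples to interpolate from")
    out = x.copy()
    out[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])
    return out


def preprocess_pupil(rec: PupilRecording, trial_onsets, epoch_window=(-0.5, 3.5),
                     baseline=(0.0, 0.5), band=(0.01, 4.0), fs_out: float = 10.0,
                     blink_mask: np.ndarray | None = None) -> SignalEpochs:
    """Full pupil pipeline from raw recording to baseline-corrected epochs.

    Steps: blink interpolation (pupil and gaze x, y, d), linear detrend,
    2nd-order zero-phase Butterworth band-pass, resampling to ``fs_out``,
    orthogonalization of each eye's pupil trace against the 12 gaze
    regressors (x, y, d to powers 1-4), z-scoring, averaging the eyes,
    epoching around ``trial_onsets`` and subtracting the per-trial mean
    over the ``baseline`` window (seconds from onset).  Trials whose raw
    samples were more than half masked are flagged.
    """
    mask = detect_blinks(rec) if blink_mask is None else np.asarray(blink_mask, bool)
    fs_in = rec.fs
    pupil = np.column_stack([_interpolate(rec.pupil[:, k], mask) for k in range(2)])
    gx = _interpolate(rec.gaze_x, mask)
    gy = _interpolate(rec.gaze_y, mask)
    gd = _interpolate(rec.gaze_d, mask)

    def clean(x: np.ndarray) -> np.ndarray:
        x = signal.detrend(x, type="linear")
        sos = signal.butter(2, band, btype="bandpass", fs=fs_in, output="sos")
        x = signal.sosfiltfilt(sos, x)
        down = int(round(fs_in / fs_out))
        return signal.resample_poly(x, 1, down)

    pupil_rs = np.column_stack([clean(pupil[:, k]) for k in range(2)])
    gaze_rs = np.column_stack([clean(g) for g in (gx, gy, gd)])
    regressors = np.column_stack([gaze_rs ** p for p in (1, 2, 3, 4)])
    design = np.column_stack([np.ones(len(regressors)), regressors])
    coef, *_ = np.linalg.lstsq(design, pupil_rs, rcond=None)
    resid = pupil_rs - design @ coef
    sd = resid.std(axis=0)
    # floor relative to the raw recording scale: a residual this small is
    # numerical ripple of a constant input, not signal to be re-amplified
    sd_floor = 1e-9 * max(1.0, float(np.nanmax(np.abs(rec.pupil))))
    resid = np.where(sd > sd_floor, (resid - resid.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    trace = resid.mean(axis=1)

    onsets = np.asarray(trial_onsets, dtype=float)
    t0 = float(rec.time[0])
    rel = np.arange(round(epoch_window[0] * fs_out), round(epoch_window[1] * fs_out))
    times = rel / fs_out
    onset_idx = np.round((onsets - t0) * fs_out).astype(int)
    idx = onset_idx[:, None] + rel[None, :]
    if idx.min() < 0 or idx.max() >= len(trace):
        raise ValueError("epoch window extends beyond the recording")
    epochs = trace[idx]
    base = (times >= baseline[0]) & (times < baseline[1])
    epochs = epochs - epochs[:, base].mean(axis=1, keepdims=True)

    # fraction of raw samples masked within each epoch, for trial flagging
    raw_idx = (np.round((onsets - t0) * fs_in).astype(int)[:, None]
               + np.arange(round(epoch_window[0] * fs_in), round(epoch_window[1] * fs_in))[None, :])
    raw_idx = np.clip(raw_idx, 0, len(mask) - 1)
    flagged = mask[raw_idx].mean(axis=1) > 0.5
    return SignalEpochs(data=epochs, times=times, flagged=flagged, fs=fs_out,
                        trace=trace, gaze_regressors=regressors)


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (peak 6 s,
    undershoot 16 s, peak/undershoot ratio 6), peak-normalized."""
    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.max()


def hrf_regressor(u_series, onsets, n_samples: int, dt: float,
                  standardize: bool = True) -> np.ndarray:
    """Trial-impulse series scaled by per-trial uncertainty, convolved with
    the canonical HRF.

    Each onset contributes an impulse of height ``u_t`` at the nearest
    sample; the convolved series is truncated to ``n_samples`` and
    z-scored (unless constant).  Build the companion constant-event
    regressor by passing ``u_series`` of ones.
    """
    u = np.asarray(u_series, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if u.shape != onsets.shape:
        raise ValueError("u_series and onsets must have equal length")
    idx = np.round(onsets / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_samples):
        raise ValueError("onset outside the sampled window")
    if len(np.unique(idx)) < len(idx):
        import warnings
        warnings.warn("overlapping trial onsets at this sampling rate", stacklevel=2)
    impulses = np.zeros(n_samples)
    np.add.at(impulses, idx, u)
    reg = np.convolve(impulses, canonical_hrf(dt))[:n_samples]
    if standardize:
        sd = reg.std()
        if sd > 0:
            reg = (reg - reg.mean()) / sd
    return reg


def glm_uncertainty(signals, u_series, onsets, dt: float, alpha: float = 0.05,
                    min_cluster: int = 15, adjacency=None) -> pd.DataFrame:
    """Per-channel GLM of a signal on the uncertainty-scaled HRF regressor.

    ``signals`` is (n_channels, n_samples).  The design has three columns:
    the u-convolved regressor, the constant-event regressor and an
    intercept.  Returns a DataFrame with the u coefficient, its SE,
    t statistic, two-sided p, Benjamini-Hochberg q, and a ``significant``
    flag (q < ``alpha``; additionally restricted to connected clusters of
    at least ``min_cluster`` channels when ``adjacency`` — a boolean or
    sparse channel x channel matrix — is provided).
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = y.shape
    u_reg = hrf_regressor(u_series, onsets, n_samp, dt)
    const_reg = hrf_regressor(np.ones(len(np.atleast_1d(onsets))), onsets, n_samp, dt)
    x = np.column_stack([u_reg, const_reg, np.ones(n_samp)])
    if n_samp <= x.shape[1]:
        raise ValueError("fewer time points than regressors")
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ beta
    dof = n_samp - np.linalg.matrix_rank(x)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    tval = beta[0] / se
    p = 2.0 * t_dist.sf(np.abs(tval), dof)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    sig = q < alpha
    if adjacency is not None and sig.any():
        adj = sparse.csr_matrix(adjacency)
        sub = adj[np.ix_(sig.nonzero()[0], sig.nonzero()[0])]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        keep = np.zeros_like(sig)
        sig_idx = sig.nonzero()[0]
        for comp in range(n_comp):
            members = sig_idx[labels == comp]
            if members.size >= min_cluster:
                keep[members] = True
        sig = keep
    return pd.DataFrame({"coef": beta[0], "se": se, "t": tval, "p": p,
                         "q": q, "significant": sig})
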