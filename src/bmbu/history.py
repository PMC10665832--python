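"""Congruence coding and trial-history regressions.

The history effects of interest are (a) the repulsive bias — a negative
dependence of the current binary choice on previous stimuli — probed with a
multiple logistic regression of C_t on S_t, S_{t-i} and C_{t-i}; and (b)
congruence effects on continuous correlates of decision uncertainty (RT,
simulated u, pupil, BOLD amplitude) — probed with a multiple linear
regression on congruence factors, where the congruence of a history
variable is its product with the current signed choice:

* current congruence  S_t * C_t   (more congruent stimulus -> less uncertain)
* pre-congruence      S_{t-i} * C_t  (choice congruent with past stimuli ->
  more uncertain, the boundary having moved toward them)
* choice repetition   C_{t-i} * C_t

Choices are coded +1/-1; 3-level stimuli as -1/0/+1, 5-level as -2..+2,
continuous stimuli as per-subject z-scores.  Unique explained variance is
summarized with the signed R-squared: the sign of a factor's coefficient
times the R^2 drop when the factor is removed from the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .fitting import filter_trials

__all__ = [
    "HistoryDesign",
    "RegressionResult",
    "GroupTest",
    "build_history_design",
    "logistic_history_regression",
    "linear_history_regression",
    "signed_r_squared",
    "psychometric_summary",
    "group_ttest",
    "plot_psychometric",
    "plot_coefficients",
]

_COEF_CAP = 10.0  # logistic coefficient cap under separation


@dataclass
class HistoryDesign:
    frame: pd.DataFrame = field(repr=False)
    response: str
    lags: int
    extended: bool

    @property
    def stimulus_choice_terms(self) -> list[str]:
        """Regressors of the choice (logistic) model."""
        return (["S_t"] + [f"S_lag{i}" for i in range(1, self.lags + 1)]
                + [f"C_lag{i}" for i in range(1, self.lags + 1)])

    @property
    def congruence_terms(self) -> list[str]:
        """Regressors of the continuous-response (linear) model."""
        terms = (["SxC_0"] + [f"SxC_lag{i}" for i in range(1, self.lags + 1)]
                 + [f"CxC_lag{i}" for i in range(1, self.lags + 1)])
        if self.extended:
            terms += ["RT_lag1", "SxC_lag1_x_RT", "CxC_lag1_x_RT"]
        return terms


@dataclass
class GroupTest:
    mean: float
    ci95: tuple
    p: float
    degenerate: bool = False


@dataclass
class RegressionResult:
    coef: pd.DataFrame = field(repr=False)        # subjects x terms
    se: pd.DataFrame = field(repr=False)
    pvalues: pd.DataFrame = field(repr=False)
    group: pd.DataFrame = None                    # per-term mean/CI/p across subjects
    signed_r2: pd.DataFrame | None = field(default=None, repr=False)
    signed_r2_group: pd.Series | None = None
    ratios: pd.Series | None = None               # factor dR^2 / current-congruence dR^2, %
    flags: pd.Series | None = None                # per-subject separation/convergence flags


def _normalize_rt(rt: pd.Series, how: str) -> pd.Series:
    if how == "raw":
        return rt
    x = np.log(rt) if how == "logz" else rt
    return (x - x.mean()) / x.std(ddof=0)


def build_history_design(table: pd.DataFrame, response_name: str, lags: int = 5,
                         extended: bool = False, rt_normalization: str = "logz",
                         zscore_stimulus: str | bool = "auto") -> HistoryDesign:
    """Assemble the per-trial regressor matrix for history regressions.

    ``table`` needs ``stimulus``, ``choice``, ``run`` (and ``subject``,
    ``rt`` where relevant); target rows follow :func:`filter_trials`.  Lags
    never cross run boundaries; target rows lacking the full lag history
    are dropped (with a warning when more than 20% of targets are lost).
    Continuous stimuli and continuous responses are z-scored per subject;
    RT is normalized per subject as z of log RT by default
    (``rt_normalization``: ``raw`` / ``z`` / ``logz``).
    """
    df = table.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    if "is_target" not in df.columns:
        df = filter_trials(df)

    if zscore_stimulus == "auto":
        zscore_stimulus = df["stimulus"].nunique() > 9
    if zscore_stimulus:
        df["stimulus"] = df.groupby("subject")["stimulus"].transform(
            lambda s: (s - s.mean()) / s.std(ddof=0))

    parts = []
    for _, sub in df.groupby("subject", sort=False):
        sub = sub.copy()
        g = sub.groupby("run", sort=False)
        sub["S_t"] = sub["stimulus"]
        for i in range(1, lags + 1):
            sub[f"S_lag{i}"] = g["stimulus"].shift(i)
            sub[f"C_lag{i}"] = g["choice"].shift(i)
        c = sub["choice"]
        sub["SxC_0"] = sub["S_t"] * c
        for i in range(1, lags + 1):
            sub[f"SxC_lag{i}"] = sub[f"S_lag{i}"] * c
            sub[f"CxC_lag{i}"] = sub[f"C_lag{i}"] * c
        if extended:
            if "rt" not in sub.columns:
                raise ValueError("extended design requires an 'rt' column")
            rt_norm = _normalize_rt(sub["rt"], rt_normalization)
            sub["RT_lag1"] = rt_norm.groupby(sub["run"].values).shift(1)
            sub["SxC_lag1_x_RT"] = sub["SxC_lag1"] * sub["RT_lag1"]
            sub["CxC_lag1_x_RT"] = sub["CxC_lag1"] * sub["RT_lag1"]
        if response_name == "choice":
            sub["response"] = c
        elif response_name == "rt":
            sub["response"] = _normalize_rt(sub["rt"], rt_normalization)
        else:
            x = sub[response_name]
            sd = x.std(ddof=0)
            sub["response"] = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)

    design = HistoryDesign(frame=out, response=response_name, lags=lags, extended=extended)
    need = design.stimulus_choice_terms + (design.congruence_terms if response_name != "choice" else [])
    need = [t for t in need if t in out.columns] + ["response"]
    ok = out["is_target"] & out[need].notna().all(axis=1)
    n_target = int(out["is_target"].sum())
    if n_target and (n_target - int(ok.sum())) / n_target > 0.2:
        warnings.warn(f"{n_target - int(ok.sum())} of {n_target} target trials dropped "
                      "for incomplete lag history", stacklevel=2)
    design.frame = out[ok].reset_index(drop=True)
    return design


def _group_frame(coef: pd.DataFrame) -> pd.DataFrame | None:
    if coef.shape[0] < 3:  # group inference needs >= 3 subjects
        return None
    rows = {}
    for term in coef.columns:
        g = group_ttest(coef[term].to_numpy())
        rows[term] = {"mean": g.mean, "ci_lo": g.ci95[0], "ci_hi": g.ci95[1],
                      "p": g.p, "degenerate": g.degenerate}
    return pd.DataFrame(rows).T


def logistic_history_regression(design: HistoryDesign) -> RegressionResult:
    """Per-subject logistic regression of the current choice on the current
    stimulus and on lagged stimuli and choices, with a group-level t-test on
    each coefficient.  A negative group coefficient on lagged stimuli is the
    repulsive bias.  Perfect separation is flagged and the offending
    coefficients capped at +/-10.
    """
    terms = design.stimulus_choice_terms
    coefs, ses, ps, flags = {}, {}, {}, {}
    for subj, sub in design.frame.groupby("subject", sort=False):
        y = (sub["response"].to_numpy() > 0).astype(float)
        x = sm.add_constant(sub[terms], has_constant="add")
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, x).fit(method="lbfgs", maxiter=500, disp=0)
                params, bse, pv = fit.params, fit.bse, fit.pvalues
                flagged = not fit.mle_retvals.get("converged", True)
            except Exception:
                params = pd.Series(0.0, index=x.columns)
                bse = pd.Series(np.nan, index=x.columns)
                pv = pd.Series(np.nan, index=x.columns)
                flagged = True
        if params.abs().max() > _COEF_CAP:
            flagged = True
            params = params.clip(-_COEF_CAP, _COEF_CAP)
        coefs[subj], ses[subj], ps[subj], flags[subj] = params[terms], bse[terms], pv[terms], flagged
    coef = pd.DataFrame(coefs).T
    return RegressionResult(coef=coef, se=pd.DataFrame(ses).T, pvalues=pd.DataFrame(ps).T,
                            group=_group_frame(coef), flags=pd.Series(flags))


def _ols_r2(y: np.ndarray, x: pd.DataFrame) -> tuple:
    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return fit, float(fit.rsquared)


def linear_history_regression(design: HistoryDesign) -> RegressionResult:
    """Per-subject OLS of a standardized continuous response on the
    congruence factors (plus the previous-RT terms in the extended design),
    with group t-tests, per-factor signed R^2 and the percentage of the
    current-congruence unique variance explained by each other factor.
    Rank-deficient columns are dropped with a warning.
    """
    terms = design.congruence_terms
    coefs, ses, ps, sr2, ratios = {}, {}, {}, {}, {}
    for subj, sub in design.frame.groupby("subject", sort=False):
        y = sub["response"].to_numpy(dtype=float)
        x = sub[terms].astype(float)
        keep = [t for t in terms if x[t].std() > 0]
        if len(keep) < len(terms):
            warnings.warn(f"subject {subj}: dropped constant/aliased columns "
                          f"{sorted(set(terms) - set(keep))}", stacklevel=2)
        fit, r2_full = _ols_r2(y, x[keep])
        coefs[subj] = fit.params.reindex(terms)
        ses[subj] = fit.bse.reindex(terms)
        ps[subj] = fit.pvalues.reindex(terms)
        dr2 = {}
        for t in keep:
            _, r2_red = _ols_r2(y, x[[k for k in keep if k != t]])
            if r2_full < r2_red - 1e-10:
                raise RuntimeError("nested OLS produced R2_full < R2_reduced")
            dr2[t] = np.sign(fit.params[t]) * max(r2_full - r2_red, 0.0)
        sr2[subj] = pd.Series(dr2).reindex(terms)
        denom = abs(dr2.get("SxC_0", np.nan))
        ratios[subj] = pd.Series(
            {t: 100.0 * abs(dr2[t]) / denom if denom > 0 else np.nan for t in dr2}
        ).reindex(terms)
    coef = pd.DataFrame(coefs).T
    signed = pd.DataFrame(sr2).T
    return RegressionResult(
        coef=coef, se=pd.DataFrame(ses).T, pvalues=pd.DataFrame(ps).T,
        group=_group_frame(coef), signed_r2=signed, signed_r2_group=signed.mean(axis=0),
        ratios=pd.DataFrame(ratios).T.mean(axis=0))


def signed_r_squared(design: HistoryDesign, factor_name: str):
    """Signed unique explained variance of one factor, per subject and as a
    group mean: sign(beta_factor) * (R^2 of the full congruence model minus
    R^2 of the model without the factor)."""
    terms = design.congruence_terms
    if factor_name not in terms:
        raise ValueError(f"factor {factor_name!r} not in design terms {terms}")
    per_subject = {}
    for subj, sub in design.frame.groupby("subject", sort=False):
        y = sub["response"].to_numpy(dtype=float)
        fit, r2_full = _ols_r2(y, sub[terms].astype(float))
        _, r2_red = _ols_r2(y, sub[[t for t in terms if t != factor_name]].astype(float))
        if r2_full < r2_red - 1e-10:
            raise RuntimeError("nested OLS produced R2_full < R2_reduced")
        per_subject[subj] = float(np.sign(fit.params[factor_name]) * max(r2_full - r2_red, 0.0))
    series = pd.Series(per_subject)
    return series, float(series.mean())


def psychometric_summary(table: pd.DataFrame, n_bins: int = 9) -> pd.DataFrame:
    """Proportion of "large" choices in each (current stimulus, previous
    stimulus) cell, with binomial (Wilson) 95% CIs.  Continuous stimuli are
    discretized into ``n_bins`` equal-count bins (for display only).  Empty
    cells carry NaN with count 0.  A negative trend across the previous
    stimulus at fixed current stimulus is the repulsive bias.
    """
    df = table.copy()
    if "is_target" not in df.columns:
        df = filter_trials(df)
    if df["stimulus"].nunique() > n_bins:
        binned = pd.qcut(df["stimulus"], n_bins)
        df["S_bin"] = binned.map(lambda iv: iv.mid).astype(float)
    else:
        df["S_bin"] = df["stimulus"]
    df["S_prev"] = df.groupby(
        [c for c in ("subject", "run") if c in df.columns], sort=False)["S_bin"].shift(1)
    df = df[df["is_target"] & df["S_prev"].notna()]
    levels_t = np.sort(df["S_bin"].unique())
    levels_p = np.sort(df["S_prev"].unique())
    rows = []
    for s_t in levels_t:
        for s_p in levels_p:
            cell = df[(df["S_bin"] == s_t) & (df["S_prev"] == s_p)]
            n = len(cell)
            k = int((cell["choice"] > 0).sum())
            if n:
                lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
                rows.append({"S_t": s_t, "S_prev": s_p, "p_large": k / n,
                             "n": n, "ci_lo": lo, "ci_hi": hi})
            else:
                rows.append({"S_t": s_t, "S_prev": s_p, "p_large": np.nan,
                             "n": 0, "ci_lo": np.nan, "ci_hi": np.nan})
    return pd.DataFrame(rows)


def group_ttest(values) -> GroupTest:
    """Two-sided one-sample t-test of per-subject values against zero."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("group test needs at least 3 subjects")
    mean = float(x.mean())
    if np.std(x) == 0:
        return GroupTest(mean=mean, ci95=(mean, mean), p=0.0, degenerate=True)
    res = stats.ttest_1samp(x, 0.0)
    lo, hi = stats.t.interval(0.95, x.size - 1, loc=mean, scale=stats.sem(x))
    return GroupTest(mean=mean, ci95=(float(lo), float(hi)), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Plotting (display only)
# ---------------------------------------------------------------------------

def plot_psychometric(summary: pd.DataFrame, path: str) -> None:
    """Proportion-"large" curves against the previous stimulus, one line per
    current stimulus; negative slopes display the repulsive bias."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for s_t, grp in summary.groupby("S_t"):
        ax.errorbar(grp["S_prev"], grp["p_large"],
                    yerr=[grp["p_large"] - grp["ci_lo"], grp["ci_hi"] - grp["p_large"]],
                    marker="o", label=f"S_t = {s_t:g}")
    ax.set_xlabel("previous stimulus")
    ax.set_ylabel('p("large")')
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coefficients(result: RegressionResult, path: str) -> None:
    """Group-mean coefficient bars with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = result.group
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(g)), 3))
    xs = np.arange(len(g))
    ax.bar(xs, g["mean"], yerr=[g["mean"] - g["ci_lo"], g["ci_hi"] - g["mean"]], capsize=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(xs, g.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
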