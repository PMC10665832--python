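"""Congruence coding, history regressions, signed R-squared and group tests."""

import numpy as np
import pandas as pd
import pytest

from bmbu import (
    ObserverParams,
    ProtocolSpec,
    build_history_design,
    generate_cohort,
    group_ttest,
    linear_history_regression,
    logistic_history_regression,
    psychometric_summary,
    signed_r_squared,
)
from bmbu.history import HistoryDesign


@pytest.fixture(scope="module")
def cohort():
    """20 simulated boundary-updating observers, 6 runs of 26 trials each."""
    return generate_cohort(
        20, ProtocolSpec(n_runs=6),
        ObserverParams(mu0=0.1, sigma0=1.0, sigma_m=0.5, kappa=0.7), seed=42,
    )["trials"]


def orthogonal_design(y):
    """Three mutually orthogonal +/-1 columns and a hand-chosen response."""
    x = np.tile([1, 1, -1, -1], 4).astype(float)
    z1 = np.tile([1, -1], 8).astype(float)
    z2 = np.repeat([1, -1], 8).astype(float)
    frame = pd.DataFrame({"subject": 0, "response": y, "SxC_0": x,
                          "SxC_lag1": z1, "CxC_lag1": z2})
    return HistoryDesign(frame=frame, response="y", lags=1, extended=False)


class TestDesignConstruction:
    def test_congruence_encoding(self):
        table = pd.DataFrame({
            "run": [0, 0, 0, 0], "trial": range(4),
            "stimulus": [-1.0, 0.0, 1.0, -1.0],
            "choice": [1, 1, 1, 1], "rt": [1.0] * 4, "u": [0.2] * 4,
        })
        d = build_history_design(table, "u", lags=1)
        f = d.frame
        # current choice "large" after a small stimulus: pre-congruence -1
        assert f.loc[f["trial"] == 1, "SxC_lag1"].iloc[0] == -1.0
        # medium stimulus contributes zero to every congruence term
        assert f.loc[f["trial"] == 2, "SxC_lag1"].iloc[0] == 0.0
        assert f.loc[f["trial"] == 1, "SxC_0"].iloc[0] == 0.0
        # repeated "large" choice pair: choice-repetition +1
        assert (f["CxC_lag1"] == 1.0).all()

    def test_lags_do_not_cross_runs(self):
        table = pd.DataFrame({
            "run": [0, 0, 1, 1], "trial": [0, 1, 0, 1],
            "stimulus": [1.0, -1.0, 1.0, -1.0], "choice": [1, -1, 1, -1],
            "rt": [1.0] * 4, "u": [0.1] * 4,
        })
        d = build_history_design(table, "u", lags=1)
        # only the second trial of each run has lag-1 history; first-of-run
        # rows are not targets anyway
        assert set(zip(d.frame["run"], d.frame["trial"])) == {(0, 1), (1, 1)}

    def test_extended_terms_present(self, cohort):
        d = build_history_design(cohort, "rt", lags=2, extended=True)
        for col in ("RT_lag1", "SxC_lag1_x_RT", "CxC_lag1_x_RT"):
            assert col in d.frame.columns
            assert col in d.congruence_terms

    def test_continuous_stimuli_are_zscored(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "run": np.repeat([0, 1], 100), "trial": np.tile(range(100), 2),
            "stimulus": rng.normal(3.0, 2.0, 200),
            "choice": rng.choice([-1, 1], 200), "rt": np.ones(200), "u": np.ones(200) * 0.3,
        })
        d = build_history_design(table, "u", lags=1)
        assert abs(d.frame["S_t"].mean()) < 0.2
        assert d.frame["S_t"].std() == pytest.approx(1.0, abs=0.2)


class TestLogisticRegression:
    def test_stimulus_driven_chooser_has_no_history_coefficients(self, rng):
        stim = rng.choice([-1.0, 1.0], size=400)
        table = pd.DataFrame({
            "run": np.repeat(range(4), 100), "trial": np.tile(range(100), 4),
            "stimulus": stim, "choice": np.sign(stim).astype(int),
            "rt": np.ones(400), "subject": np.repeat([0, 1], 200),
        })
        d = build_history_design(table, "choice", lags=2)
        res = logistic_history_regression(d)
        assert res.flags.all()  # perfect separation flagged
        assert np.allclose(res.coef["S_t"], 10.0)  # capped
        assert res.coef[["S_lag1", "S_lag2"]].abs().to_numpy().max() < 1.0

    def test_simulated_observers_show_repulsive_bias(self, cohort):
        res = logistic_history_regression(build_history_design(cohort, "choice", lags=3))
        g = res.group
        assert g.loc["S_t", "mean"] > 0
        assert g.loc["S_lag1", "mean"] < 0 and g.loc["S_lag1", "p"] < 0.05
        mags = [-g.loc[f"S_lag{i}", "mean"] for i in (1, 2, 3)]
        assert mags[0] > mags[1] > mags[2] > 0


class TestLinearRegression:
    def test_exact_fit_on_own_regressor(self):
        d = orthogonal_design(y=np.tile([1, 1, -1, -1], 4).astype(float))
        res = linear_history_regression(d)
        assert res.coef.loc[0, "SxC_0"] == pytest.approx(1.0)
        assert abs(res.coef.loc[0, "SxC_lag1"]) < 1e-12
        assert res.signed_r2.loc[0, "SxC_0"] == pytest.approx(1.0)

    def test_uncertainty_response_shows_congruence_pattern(self, cohort):
        res = linear_history_regression(build_history_design(cohort, "u", lags=3))
        g = res.group
        assert g.loc["SxC_0", "mean"] < 0 and g.loc["SxC_0", "p"] < 0.05
        assert g.loc["SxC_lag1", "mean"] > 0 and g.loc["SxC_lag1", "p"] < 0.05
        mags = [g.loc[f"SxC_lag{i}", "mean"] for i in (1, 2, 3)]
        assert mags[0] > mags[1] > mags[2]

    def test_rt_response_shows_congruence_pattern(self, cohort):
        res = linear_history_regression(build_history_design(cohort, "rt", lags=3))
        g = res.group
        assert g.loc["SxC_0", "mean"] < 0
        assert g.loc["SxC_lag1", "mean"] > 0 and g.loc["SxC_lag1", "p"] < 0.05
        # uncertainty-coupled RT: pre-congruence unique variance within the
        # 10-46% of the current-congruence effect seen empirically
        assert 10 <= res.ratios["SxC_lag1"] <= 46


class TestSignedRSquared:
    def test_sign_carried_from_coefficient(self):
        x = np.tile([1, 1, -1, -1], 4).astype(float)
        for slope, expected in ((2.0, 1.0), (-2.0, -1.0)):
            d = orthogonal_design(y=slope * x)
            per_subject, group_mean = signed_r_squared(d, "SxC_0")
            assert group_mean == pytest.approx(expected, abs=1e-12)
            assert per_subject.loc[0] == pytest.approx(expected, abs=1e-12)

    def test_orthogonal_factors_partition_variance(self, rng):
        """In an orthogonal design each factor's unique R^2 equals its
        squared simple correlation, and the pieces add up to the total."""
        x = np.tile([1, 1, -1, -1], 4).astype(float)
        z1 = np.tile([1, -1], 8).astype(float)
        y = 1.0 * x + 0.5 * z1 + 0.25 * np.repeat([1, -1], 8)
        d = orthogonal_design(y=y)
        total = 0.0
        for term in ("SxC_0", "SxC_lag1", "CxC_lag1"):
            _, delta = signed_r_squared(d, term)
            r = np.corrcoef(y, d.frame[term])[0, 1]
            assert abs(delta) == pytest.approx(r ** 2, abs=1e-10)
            total += abs(delta)
        assert total == pytest.approx(1.0, abs=1e-10)  # noiseless orthogonal case

    def test_magnitude_invariant_to_regressor_scaling(self):
        x = np.tile([1, 1, -1, -1], 4).astype(float)
        y = 2.0 * x + np.tile([0.1, -0.1], 8)
        d1 = orthogonal_design(y=y)
        d2 = orthogonal_design(y=y)
        d2.frame["SxC_0"] *= 37.0
        _, a = signed_r_squared(d1, "SxC_0")
        _, b = signed_r_squared(d2, "SxC_0")
        assert a == pytest.approx(b, abs=1e-12)

    def test_unknown_factor_rejected(self):
        d = orthogonal_design(y=np.ones(16))
        with pytest.raises(ValueError):
            signed_r_squared(d, "nope")


class TestPsychometric:
    @staticmethod
    def _table(stim, choice):
        n = len(stim)
        return pd.DataFrame({"run": np.zeros(n, int), "trial": range(n),
                             "stimulus": stim, "choice": choice, "rt": np.ones(n)})

    def test_coin_flip_choices_near_half(self, rng):
        stim = rng.choice([-1.0, 0.0, 1.0], 3000)
        t = self._table(stim, rng.choice([-1, 1], 3000))
        s = psychometric_summary(t)
        assert np.nanmax(np.abs(s["p_large"] - 0.5)) < 0.1
        covers = (s["ci_lo"] < 0.5) & (s["ci_hi"] > 0.5)
        assert covers.sum() >= len(s) - 1  # ~5% per-cell miss rate allowed

    def test_deterministic_chooser_cells_are_zero_or_one(self, rng):
        stim = rng.choice([-1.0, 1.0], 500)
        t = self._table(stim, np.sign(stim).astype(int))
        s = psychometric_summary(t)
        assert set(s["p_large"].round(6)) <= {0.0, 1.0}
        assert (s.loc[s["S_t"] > 0, "p_large"] == 1.0).all()

    def test_simulated_observers_show_negative_previous_stimulus_slope(self, cohort):
        s = psychometric_summary(cohort)
        slopes = []
        for _, grp in s.groupby("S_t"):
            grp = grp.sort_values("S_prev")
            slopes.append(np.polyfit(grp["S_prev"], grp["p_large"], 1)[0])
        assert np.mean(slopes) < -0.01

    def test_empty_cells_are_nan_with_zero_count(self):
        t = self._table(np.array([1.0, 1.0, 1.0, 0.0, 0.0]), np.ones(5, int))
        s = psychometric_summary(t)
        empty = s[s["n"] == 0]
        assert len(empty) > 0 and empty["p_large"].isna().all()


class TestGroupTtest:
    def test_all_zero_values_flagged_degenerate(self):
        g = group_ttest(np.zeros(8))
        assert g.degenerate and g.p == 0.0

    def test_symmetric_values_give_large_p(self):
        g = group_ttest(np.tile([0.5, -0.5], 25))
        assert g.p > 0.95
        assert g.ci95[0] < 0 < g.ci95[1]

    def test_matches_textbook_formula(self):
        # values (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        g = group_ttest([1.0, 2.0, 3.0])
        assert g.mean == pytest.approx(2.0)
        assert g.p == pytest.approx(0.07417990022744847, rel=1e-9)

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            group_ttest([1.0, 2.0])
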