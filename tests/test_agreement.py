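import numpy as np
import pandas as pd
import pytest

from hrvalid.agreement import (
    AgreementModel,
    accuracy_per_subject,
    classify_thresholds,
    lin_ccc,
    lmm_bland_altman,
    reml_random_intercept,
    rm_ccc,
    rm_spearman,
    AccuracySummary,
    AgreementResult,
)
from hrvalid.pairing import PairedDataset

from .oracles import lin_ccc_by_hand


def make_paired(subjects, ref, dev, resolution="per_second"):
    """Assemble a PairedDataset from parallel arrays."""
    df = pd.DataFrame({"subject_id": subjects, "ref_bpm": np.asarray(ref, float),
                       "dev_bpm": np.asarray(dev, float)})
    df["t_s"] = df.groupby("subject_id").cumcount().astype(float)
    df["state"] = "steady"
    df["transition_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return PairedDataset(resolution, df, "dev", "ref")


def simulated_paired(rng, n_subj=8, n_obs=60, bias=0.0, sigma_u=1.0, sigma_e=3.0):
    subjects, ref, dev = [], [], []
    for i in range(n_subj):
        u = rng.normal(0, sigma_u)
        r = rng.normal(100, 15, n_obs)
        d = r + bias + u + rng.normal(0, sigma_e, n_obs)
        subjects += [f"S{i:02d}"] * n_obs
        ref.append(r)
        dev.append(d)
    return make_paired(subjects, np.concatenate(ref), np.concatenate(dev))


class TestAccuracy:
    def test_symmetric_errors(self):
        p = make_paired(["a", "a"], [100, 100], [90, 110])
        acc = accuracy_per_subject(p)
        assert acc.median_mae == 10.0 and acc.median_mape == 10.0

    def test_identity_is_zero_error(self):
        p = make_paired(["a"] * 5 + ["b"] * 5, np.arange(10) + 80.0, np.arange(10) + 80.0)
        acc = accuracy_per_subject(p)
        assert acc.median_mae == 0.0 and acc.median_mape == 0.0

    def test_median_iqr_follow_linear_interpolation_rule(self):
        # subjects with MAPE 2, 4, 9 %: hand-computed linear-interpolation
        # quantiles give Q1 = 3, median = 4, Q3 = 6.5, IQR = 3.5
        subjects = ["a"] * 2 + ["b"] * 2 + ["c"] * 2
        ref = np.full(6, 100.0)
        dev = np.array([102, 98, 104, 96, 109, 91], dtype=float)
        acc = accuracy_per_subject(make_paired(subjects, ref, dev))
        assert acc.per_subject["mape"].tolist() == [2.0, 4.0, 9.0]
        assert acc.median_mape == 4.0
        assert acc.iqr_mape == pytest.approx(3.5)

    def test_condition_filter_restricts_pairs(self):
        p = make_paired(["a"] * 4, [100] * 4, [110, 110, 100, 100])
        p.data.loc[:1, "state"] = "transition"
        p.data.loc[:1, "transition_id"] = 1
        assert accuracy_per_subject(p, "transition").median_mape == 10.0
        assert accuracy_per_subject(p, "steady").median_mape == 0.0

    def test_nonpositive_reference_rejected(self):
        p = make_paired(["a", "a"], [100, 100], [90, 110])
        p.data.loc[0, "ref_bpm"] = -1.0
        with pytest.raises(ValueError):
            accuracy_per_subject(p)


class TestLinCCC:
    def test_perfect_concordance(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_unit_shift(self):
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(2.0 / 3.0)

    def test_reversal_is_negative(self):
        assert lin_ccc([1, 2, 3], [-1 + 4, -2 + 4, -3 + 4]) < 0

    def test_degenerate_conventions(self):
        assert lin_ccc([5, 5, 5], [5, 5, 5]) == 1.0
        assert lin_ccc([5, 5, 5], [7, 7, 7]) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_computed_moment_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(100, 10, 30)
        y = 0.8 * x + rng.normal(0, 5, 30)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc_by_hand(x, y), abs=1e-12)


class TestRemlEngine:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_mixedlm(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        k, n = 12, 15
        groups = np.repeat(np.arange(k), n)
        x = rng.normal(0, 1, k * n)
        y = 2.0 + 0.5 * x + rng.normal(0, 1.5, k)[groups] + rng.normal(0, 2.0, k * n)
        X = np.column_stack([np.ones(k * n), x])
        fit = reml_random_intercept(y, X, groups)
        ml = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert fit.beta == pytest.approx(ml.fe_params, abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(ml.scale, rel=1e-3)
        assert fit.sigma_u2 == pytest.approx(float(np.asarray(ml.cov_re)[0, 0]), rel=1e-3, abs=1e-3)
        assert fit.se_beta == pytest.approx(ml.bse_fe, rel=5e-3)

    def test_boundary_collapses_to_ols(self, rng):
        y = rng.normal(0, 1, 100)  # no group structure at all
        groups = np.repeat(np.arange(10), 10)
        fit = reml_random_intercept(y, np.ones((100, 1)), groups)
        assert fit.sigma_u2 <= 1e-6


class TestRmCCC:
    def test_identity_is_one(self):
        rng = np.random.default_rng(0)
        r = rng.normal(100, 15, 120)
        p = make_paired(np.repeat([f"s{i}" for i in range(6)], 20), r, r.copy())
        est, _ = rm_ccc(p, n_boot=0)
        assert est == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_reduces_to_lin_ccc_on_single_pair_per_subject(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        x = rng.normal(100, 12, n)
        y = x + rng.normal(1, 4, n)
        p = make_paired([f"s{i}" for i in range(n)], x, y)
        est, _ = rm_ccc(p, n_boot=0)
        assert est == pytest.approx(lin_ccc(x, y), abs=1e-6)

    def test_large_location_shift_drives_concordance_to_zero(self):
        rng = np.random.default_rng(3)
        r = rng.normal(100, 10, 200)
        subj = np.repeat([f"s{i}" for i in range(10)], 20)
        prev = 1.0
        for c in (0.0, 20.0, 200.0):
            est, _ = rm_ccc(make_paired(subj, r, r + c), n_boot=0)
            assert est <= prev + 1e-12
            prev = est
        assert prev < 0.01

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(5)
        p = simulated_paired(rng)
        est, ci = rm_ccc(p, n_boot=100, seed=7)
        est2, ci2 = rm_ccc(p, n_boot=100, seed=7)
        assert ci == ci2 and est == est2
        assert ci[0] <= est <= ci[1]

    def test_single_subject_falls_back_to_lin(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 10, 30)
        p = make_paired(["only"] * 30, x, x + rng.normal(0, 3, 30))
        with pytest.warns(UserWarning, match="single subject"):
            est, ci = rm_ccc(p, n_boot=0)
        assert est == pytest.approx(lin_ccc(p.data.ref_bpm, p.data.dev_bpm))


class TestRmSpearman:
    def test_global_monotone_transform_gives_one(self):
        rng = np.random.default_rng(2)
        r = rng.normal(100, 15, 90)
        p = make_paired(np.repeat([f"s{i}" for i in range(6)], 15), r, np.exp(r / 30.0))
        est, _ = rm_spearman(p, n_boot=0)
        assert est == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        rng = np.random.default_rng(2)
        r = rng.normal(100, 15, 60)
        p = make_paired(np.repeat([f"s{i}" for i in range(4)], 15), r, 250.0 - r)
        est, _ = rm_spearman(p, n_boot=0)
        assert est == pytest.approx(-1.0)

    def test_independent_streams_near_zero(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            subj = np.repeat([f"s{i}" for i in range(10)], 50)
            p = make_paired(subj, rng.normal(100, 10, 500), rng.normal(100, 10, 500))
            ests.append(rm_spearman(p, n_boot=0)[0])
        assert np.max(np.abs(ests)) < 0.15
        assert abs(np.mean(ests)) < 0.05

    def test_constant_variable_rejected(self):
        p = make_paired(["a"] * 5 + ["b"] * 5, np.full(10, 100.0), np.arange(10) + 80.0)
        with pytest.raises(ValueError):
            rm_spearman(p, n_boot=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_rm_corr_on_ranks(self, seed):
        pingouin = pytest.importorskip("pingouin")
        from scipy.stats import rankdata

        rng = np.random.default_rng(seed)
        p = simulated_paired(rng, n_subj=6, n_obs=25)
        est, _ = rm_spearman(p, n_boot=0)
        df = p.data.copy()
        df["rx"] = rankdata(df.ref_bpm)
        df["ry"] = rankdata(df.dev_bpm)
        oracle = pingouin.rm_corr(data=df, x="rx", y="ry", subject="subject_id")
        assert est == pytest.approx(float(oracle.r.iloc[0]), abs=1e-6)


class TestMixedModelBlandAltman:
    def test_constant_difference_degenerates(self):
        p = make_paired(["a"] * 3 + ["b"] * 3, np.full(6, 100.0), np.full(6, 103.0))
        bias, bias_p, lo, hi = lmm_bland_altman(p)
        assert (bias, lo, hi) == (3.0, 3.0, 3.0)
        assert bias_p == pytest.approx(0.0)

    def test_identity_gives_zero_bias_zero_loa(self):
        rng = np.random.default_rng(0)
        r = rng.normal(100, 10, 60)
        p = make_paired(np.repeat(["a", "b", "c"], 20), r, r.copy())
        bias, bias_p, lo, hi = lmm_bland_altman(p)
        assert bias == 0.0 and lo == 0.0 and hi == 0.0 and bias_p == 1.0

    def test_recovers_generating_parameters(self):
        # d ~ mu + u_i + e_ij with mu = 2, sigma_u = 1, sigma_e = 3
        rng = np.random.default_rng(11)
        biases, halves = [], []
        for _ in range(10):
            p = simulated_paired(rng, n_subj=24, n_obs=100, bias=2.0, sigma_u=1.0, sigma_e=3.0)
            bias, _, lo, hi = lmm_bland_altman(p)
            biases.append(bias)
            halves.append((hi - lo) / 2)
        assert np.mean(biases) == pytest.approx(2.0, abs=0.3)
        assert np.mean(halves) == pytest.approx(1.96 * np.sqrt(10.0), rel=0.05)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_mixedlm_on_differences(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        p = simulated_paired(rng, n_subj=10, n_obs=30, bias=1.0)
        bias, _, lo, hi = lmm_bland_altman(p)
        d = (p.data.dev_bpm - p.data.ref_bpm).to_numpy()
        groups = p.data.subject_id.to_numpy()
        ml = sm.MixedLM(d, np.ones((d.size, 1)), groups=groups).fit(reml=True)
        sd = np.sqrt(ml.scale + float(np.asarray(ml.cov_re)[0, 0]))
        assert bias == pytest.approx(float(ml.fe_params[0]), abs=1e-4)
        assert (hi - lo) / 2 == pytest.approx(1.96 * sd, rel=1e-3)

    def test_boundary_zero_subject_variance_warns(self):
        rng = np.random.default_rng(4)
        r = rng.normal(100, 10, 300)
        subj = np.repeat([f"s{i}" for i in range(10)], 30)
        noise = rng.normal(0, 2, 300)
        # remove subject-mean differences so between-subject variance sits
        # below its expectation under independence -> boundary estimate
        noise -= np.repeat([noise[i * 30:(i + 1) * 30].mean() for i in range(10)], 30)
        p = make_paired(subj, r, r + noise)
        with pytest.warns(UserWarning, match="subject variance"):
            bias, _, lo, hi = lmm_bland_altman(p)
        d = p.data.dev_bpm - p.data.ref_bpm
        assert (hi - lo) / 2 == pytest.approx(1.96 * d.std(ddof=1), rel=0.05)


class TestThresholds:
    def _acc(self, mape, mae=20.0):
        per = pd.DataFrame({"mae": [mae], "mape": [mape]}, index=["s"])
        return AccuracySummary(per, mae, 0.0, mape, 0.0, 1)

    def _agr(self, cc):
        return AgreementResult(cc, (cc, cc), cc, (cc, cc), 0.0, 1.0, -1.0, 1.0, 10)

    def test_strong_band_but_not_acceptable(self):
        v = classify_thresholds(self._acc(12.0), self._agr(0.77))
        assert v.cc_band == "strong" and not v.cc_acceptable

    def test_boundary_mape_inclusive(self):
        assert classify_thresholds(self._acc(9.99), self._agr(0.9)).mape_acceptable
        assert not classify_thresholds(self._acc(10.01), self._agr(0.9)).mape_acceptable
        # MAE rule rescues a high-MAPE device
        assert classify_thresholds(self._acc(12.0, mae=4.0), self._agr(0.9)).mape_acceptable

    def test_cc_band_boundaries(self):
        assert classify_thresholds(self._acc(5.0), self._agr(0.5)).cc_band == "weak"
        assert classify_thresholds(self._acc(5.0), self._agr(0.6)).cc_band == "moderate"
        assert classify_thresholds(self._acc(5.0), self._agr(0.7)).cc_band == "strong"
        assert classify_thresholds(self._acc(5.0), self._agr(0.80)).cc_acceptable


class TestShiftInvariance:
    def test_constant_shift_leaves_scale_metrics_unchanged(self):
        rng = np.random.default_rng(8)
        p = simulated_paired(rng, n_subj=6, n_obs=40, bias=1.0)
        shifted = make_paired(p.data.subject_id, p.data.ref_bpm + 30.0, p.data.dev_bpm + 30.0)
        a0, a1 = accuracy_per_subject(p), accuracy_per_subject(shifted)
        assert a0.median_mae == pytest.approx(a1.median_mae)
        # MAPE shrinks with the larger denominator
        assert a1.median_mape < a0.median_mape
        b0, b1 = lmm_bland_altman(p), lmm_bland_altman(shifted)
        assert b0[0] == pytest.approx(b1[0], abs=1e-6)
        assert (b0[3] - b0[2]) == pytest.approx(b1[3] - b1[2], abs=1e-6)
        s0, _ = rm_spearman(p, n_boot=0)
        s1, _ = rm_spearman(shifted, n_boot=0)
        assert s0 == pytest.approx(s1, abs=1e-12)


class TestModelResults:
    def test_fit_summary_and_dict(self):
        rng = np.random.default_rng(9)
        p = simulated_paired(rng, n_subj=6, n_obs=40, bias=0.5)
        res = AgreementModel(p, n_boot=50, seed=0).fit()
        d = res.to_dict()
        assert d["n_pairs"] == len(p)
        assert d["loa_lower_bpm"] <= d["bias_bpm"] <= d["loa_upper_bpm"]
        assert -1 <= d["rmccc"] <= 1 and -1 <= d["rm_spearman"] <= 1
        text = res.summary()
        for token in ("median MAPE", "rmCCC", "95% LoA", "bias"):
            assert token in text

    def test_from_dataframe_constructor(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "subject_id": np.repeat(["a", "b", "c", "d"], 25),
            "t_s": np.tile(np.arange(25.0), 4),
            "ref_bpm": rng.normal(100, 10, 100),
        })
        df["dev_bpm"] = df.ref_bpm + rng.normal(0, 3, 100)
        res = AgreementModel.from_dataframe(df, n_boot=0).fit()
        assert res.agreement.n_pairs == 100
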