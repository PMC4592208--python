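"""Activity conversion, OLS fitting, selection and the frozen model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qsarscreen import qsar


class TestConversions:
    @pytest.mark.parametrize("ic50,expected", [(1.0, 9.0), (1000.0, 6.0), (5.0, 9 - math.log10(5))])
    def test_pic50(self, ic50, expected):
        assert qsar.pic50_from_ic50_nM(ic50) == pytest.approx(expected, abs=1e-9)

    def test_training_range_endpoints(self):
        # the 5-300 nM potency range maps to pIC50 [6.523, 8.301]
        assert qsar.pic50_from_ic50_nM(300) == pytest.approx(6.523, abs=5e-4)
        assert qsar.pic50_from_ic50_nM(5) == pytest.approx(8.301, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            qsar.pic50_from_ic50_nM(bad)

    @given(st.floats(min_value=-3, max_value=12))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, pic50):
        back = qsar.pic50_from_ic50_nM(qsar.ic50_nM_from_pic50(pic50))
        assert back == pytest.approx(pic50, rel=1e-9, abs=1e-9)


class TestMeanPic50:
    def records(self, ic50s, cid="cpd"):
        isos = ["HDAC1", "HDAC2", "HDAC3", "HDAC8"]
        return [qsar.ActivityRecord(cid, isos[i % 4], v) for i, v in enumerate(ic50s)]

    def test_single(self):
        assert qsar.mean_pic50(self.records([100.0])) == pytest.approx(7.0)

    def test_equal_isoforms(self):
        assert qsar.mean_pic50(self.records([10.0] * 4)) == pytest.approx(8.0)

    def test_convert_then_average(self):
        # (8 + 7 + 7 + 6)/4, not the pIC50 of the mean IC50
        assert qsar.mean_pic50(self.records([10, 100, 100, 1000])) == pytest.approx(7.0)

    def test_mixed_ids_rejected(self):
        recs = self.records([10.0]) + self.records([20.0], cid="other")
        with pytest.raises(ValueError, match="mix"):
            qsar.mean_pic50(recs)


class TestClassify:
    @pytest.mark.parametrize(
        "ic50,label", [(2400, "active"), (2600, "decoy"), (2500, "decoy"), (1, "active")]
    )
    def test_threshold(self, ic50, label):
        assert qsar.classify_activity(ic50) == label

    def test_study_design_split(self):
        # a 71-compound design with 41 below and 30 above the threshold
        ic50s = [100.0] * 41 + [10000.0] * 30
        labels = [qsar.classify_activity(v) for v in ic50s]
        assert labels.count("active") == 41 and labels.count("decoy") == 30


def pinv_ols(X, y):
    """Independent normal-equations oracle via the pseudo-inverse."""
    design = np.column_stack([np.ones(len(y)), X])
    return np.linalg.pinv(design) @ y


class TestFitMlr:
    def test_exact_line(self):
        x = np.arange(5.0)
        model = qsar.fit_mlr(pd.DataFrame({"x": x}), 2 + 3 * x)
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert model.coefficients["x"] == pytest.approx(3.0, abs=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_r2_matches_published_pair(self):
        assert qsar.adjusted_r2(0.93, n=10, p=5) == pytest.approx(0.8425)
        assert round(qsar.adjusted_r2(0.93, n=10, p=5), 2) == 0.84

    def test_matches_pinv_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, p = 8, 2
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = qsar.fit_mlr(pd.DataFrame(X, columns=["a", "b"]), y)
            beta = pinv_ols(X, y)
            assert model.intercept == pytest.approx(beta[0], abs=1e-8)
            assert list(model.coefficients.values()) == pytest.approx(beta[1:], abs=1e-8)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = qsar.fit_mlr(X, rng.normal(size=20))
        assert abs(model.residuals.sum()) < 1e-9
        assert model.adjusted_r2 <= model.r2
        assert model.see >= 0

    def test_rank_deficient_names_column(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            qsar.fit_mlr(X, x)

    def test_too_few_observations(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="n > p"):
            qsar.fit_mlr(X, np.ones(3))


class TestPublishedModel:
    def test_frozen_constants(self):
        m = qsar.published_model()
        assert m.intercept == 14.48
        assert len(m.coefficients) == 5
        assert m.coefficients["tpsa"] == 0.17
        assert m.coefficients["hba"] == -2.54
        assert (m.n, m.r2, m.adjusted_r2, m.see, m.p_value) == (10, 0.93, 0.84, 0.24, 0.02)

    def test_all_zero_vector_returns_intercept(self):
        zero = dict.fromkeys(qsar.published_model().coefficients, 0.0)
        assert qsar.predict_pic50(qsar.published_model(), zero) == 14.48

    def test_hand_vector(self):
        d = {"mol_polarizability": 30, "logp": 2, "tpsa": 60, "hba": 4, "balaban_j": 2}
        assert qsar.predict_pic50(qsar.published_model(), d) == pytest.approx(5.60, abs=1e-9)

    def test_missing_descriptor_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            qsar.predict_pic50(qsar.published_model(), {"tpsa": 1.0})


class TestExternalValidate:
    def test_self_validation_of_noiseless_fit(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = 1 + X["a"] - 2 * X["b"]
        model = qsar.fit_mlr(X, y)
        report = qsar.external_validate(model, X, y)
        assert report.external_r2 == pytest.approx(1.0, abs=1e-9)
        assert report.max_abs_residual < 1e-9 and report.flagged == []

    def test_constant_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = qsar.QSARModel(intercept=float(y.mean()), coefficients={"a": 0.0})
        report = qsar.external_validate(model, pd.DataFrame({"a": np.zeros(4)}), y)
        assert report.external_r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = 0.5 + X["a"].to_numpy() + rng.normal(scale=0.2, size=50)
        model = qsar.fit_mlr(X.iloc[:25], y[:25])
        report = qsar.external_validate(model, X.iloc[25:], y[25:])
        pred = report.predicted
        sse = float(np.sum((y[25:] - pred) ** 2))
        sst = float(np.sum((y[25:] - y[25:].mean()) ** 2))
        assert report.external_r2 == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_residual_flagging(self):
        model = qsar.QSARModel(intercept=0.0, coefficients={"a": 1.0})
        X = pd.DataFrame({"a": [0.0, 0.0]})
        report = qsar.external_validate(model, X, np.array([0.1, 0.9]))
        assert report.flagged == [1]

    def test_length_mismatch(self):
        model = qsar.QSARModel(intercept=0.0, coefficients={"a": 1.0})
        with pytest.raises(ValueError, match="mismatch"):
            qsar.external_validate(model, pd.DataFrame({"a": [1.0]}), np.ones(2))


class TestSelection:
    def make_signal_data(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["signal", "n1", "n2", "n3"])
        y = 10 * X["signal"].to_numpy() + rng.normal(size=n)  # effect 10 sigma
        return X, y

    @pytest.mark.parametrize("method", ["FS", "SS"])
    def test_forward_finds_planted_signal(self, method):
        X, y = self.make_signal_data()
        cols, model = qsar.select_descriptors(X, y, method=method)
        assert "signal" in cols
        assert model.r2 > 0.9

    def test_fs_exact_single_column(self):
        # strong effect, weak noise columns: FS must pick exactly the signal
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["signal", "n1", "n2"])
        y = 10 * X["signal"].to_numpy() + 0.1 * rng.normal(size=30)
        cols, _ = qsar.select_descriptors(X, y, method="FS")
        # exhaustive check: signal alone beats any noise column alone
        assert cols[0] == "signal"

    def test_be_keeps_true_model(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = 3 * X["a"].to_numpy() - 2 * X["b"].to_numpy()
        cols, _ = qsar.select_descriptors(X, y, method="BE")
        assert sorted(cols) == ["a", "b"]

    def test_null_selection_rate_is_loose_nominal(self):
        # pure-noise designs rarely admit any column at alpha_enter 0.05
        selected_any = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
            y = rng.normal(size=100)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols, _ = qsar.select_descriptors(X, y, method="FS")
            if cols:
                selected_any += 1
        assert selected_any <= 0.25 * n_seeds

    def test_intercept_only_fallback_warns(self):
        X = pd.DataFrame({"a": [0.1, -0.2, 0.05, 0.0, 0.1, -0.1]})
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="intercept-only"):
            cols, model = qsar.select_descriptors(X, y, method="FS")
        assert cols == [] and model.coefficients == {}


class TestAnova:
    def test_perfect_fit_reports_tiny_p(self):
        x = np.arange(8.0)
        model = qsar.fit_mlr(pd.DataFrame({"x": x}), 1 + 2 * x)
        _, p = qsar.anova_significance(model)
        assert p < 1e-12 or p == pytest.approx(1e-13)

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=30)
        model = qsar.fit_mlr(X, y)
        f, p = qsar.anova_significance(model)
        # brute force: MSR/MSE from explicit sums of squares
        pred = y - model.residuals
        ssr = np.sum((pred - y.mean()) ** 2)
        sse = np.sum(model.residuals**2)
        n, k = 30, 3
        f_oracle = (ssr / k) / (sse / (n - k - 1))
        assert f == pytest.approx(f_oracle, abs=1e-9)
        assert p == pytest.approx(float(stats.f.sf(f_oracle, k, n - k - 1)), abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(120):
            rng = np.random.default_rng(2000 + seed)
            X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
            model = qsar.fit_mlr(X, rng.normal(size=25))
            pvals.append(qsar.anova_significance(model)[1])
        pvals = np.array(pvals)
        # loose empirical-CDF bounds for a uniform sample of this size
        assert 0.3 < np.mean(pvals < 0.5) < 0.7
        assert np.mean(pvals < 0.1) < 0.25

    def test_degenerate_df_rejected(self):
        model = qsar.QSARModel(intercept=0.0, coefficients={"a": 1.0}, n=2)
        with pytest.raises(ValueError, match="degrees of freedom|residuals"):
            qsar.anova_significance(model)


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = qsar.fit_mlr(X, rng.normal(size=20))
        path = tmp_path / "model.txt"
        qsar.save_model(model, path)
        loaded = qsar.load_model(path)
        assert loaded.intercept == model.intercept  # exact, via float hex
        assert loaded.coefficients == model.coefficients
        assert loaded.coefficient_se == model.coefficient_se
        assert (loaded.r2, loaded.see, loaded.n) == (model.r2, model.see, model.n)


def test_read_activities_round_trip(tmp_path):
    path = tmp_path / "act.csv"
    pd.DataFrame(
        {"compound_id": ["c1", "c1"], "isoform": ["HDAC1", "HDAC2"], "ic50_nM": [10.0, 1000.0]}
    ).to_csv(path, index=False)
    recs = qsar.read_activities(path)
    assert len(recs) == 2
    assert qsar.mean_pic50(recs) == pytest.approx(7.0)
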