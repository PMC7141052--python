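"""Scaling, filtering, crossed-effects fitting, correlations."""

import numpy as np
import pandas as pd
import pytest

from gazeparse.analysis import (
    ModelSpec,
    fit_lmm,
    fit_lmm_many,
    predictor_correlations,
    prepare,
    scale_predictors,
)
from gazeparse.synthetic_data import RTConfig, gen_reading_times


def small_predictors(n_items=12, words_per_item=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_items):
        for w in range(1, words_per_item + 1):
            rows.append({
                "sentence": f"it{i}",
                "word": w,
                "x": rng.normal(),
                "z": rng.normal(),
            })
    return pd.DataFrame(rows)


def simulated_table(spec, beta_x=0.0, n_subjects=8, seed=0, zero_fraction=0.2):
    pred = small_predictors(seed=seed)
    cfg = RTConfig(
        betas={"fprt": {"x": beta_x, "z": 0.0}},
        intercepts={"fprt": 5.5},
        n_subjects=n_subjects,
        subject_slope_sd=0.0,
        item_slope_sd=0.0,
        zero_fraction=zero_fraction,
    )
    measures, truth = gen_reading_times(pred, cfg, seed=seed)
    return prepare(measures, pred, spec), truth


class TestScaling:
    def test_three_point_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = scale_predictors(df, ["x"])
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_constant_column_errors_with_name(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="'x'"):
            scale_predictors(df, ["x"])

    def test_idempotent_up_to_float_tolerance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(3, 2, 50)})
        once = scale_predictors(df, ["x"])
        twice = scale_predictors(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_scaled_moments(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.exponential(4, 200)})
        out = scale_predictors(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestPrepare:
    def test_zero_rows_dropped_and_counted(self):
        measures = pd.DataFrame({
            "subject": ["a"] * 4,
            "sentence": ["s"] * 4,
            "word": [1, 2, 3, 4],
            "fprt": [100.0, 0.0, 150.0, 220.0],
        })
        predictors = pd.DataFrame({
            "sentence": ["s"] * 4, "word": [1, 2, 3, 4],
            "x": [0.1, 0.5, -0.3, 0.2],
        })
        spec = ModelSpec(dependent="fprt", predictors=("x",))
        out = prepare(measures, predictors, spec)
        assert len(out) == 3
        assert out.attrs["filters"]["zero_measure"] == 1
        assert np.allclose(out["log_rt"], np.log([100.0, 150.0, 220.0]))

    def test_all_zero_measure_errors(self):
        measures = pd.DataFrame({
            "subject": ["a", "a"], "sentence": ["s", "s"], "word": [1, 2],
            "fprt": [0.0, 0.0],
        })
        predictors = pd.DataFrame({"sentence": ["s", "s"], "word": [1, 2],
                                   "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="no data left"):
            prepare(measures, predictors, ModelSpec(dependent="fprt",
                                                    predictors=("x",)))

    def test_filter_bookkeeping_balances(self):
        spec = ModelSpec(dependent="fprt", predictors=("x", "z"))
        table, _ = simulated_table(spec, seed=5)
        filters = table.attrs["filters"]
        total_in = 8 * 12 * 5
        assert total_in - filters["zero_measure"] - filters["join_loss"] == len(table)

    def test_retrieval_mode_drops_zero_retrieval_rows(self):
        measures = pd.DataFrame({
            "subject": ["a"] * 3, "sentence": ["s"] * 3, "word": [1, 2, 3],
            "fprt": [100.0, 120.0, 130.0],
        })
        predictors = pd.DataFrame({
            "sentence": ["s"] * 3, "word": [1, 2, 3],
            "x": [0.1, 0.2, 0.9],
            "retrieval_latency_ms": [0.0, 40.0, 60.0],
        })
        spec = ModelSpec(dependent="fprt", predictors=("x",),
                         retrieval_mode=True)
        out = prepare(measures, predictors, spec)
        assert len(out) == 2
        assert out.attrs["filters"]["zero_retrieval"] == 1


class TestFitLmm:
    def test_t_equals_estimate_over_se(self):
        spec = ModelSpec(dependent="fprt", predictors=("x", "z"))
        table, _ = simulated_table(spec, beta_x=0.1, seed=1)
        result = fit_lmm(table, spec)
        for _, row in result.coefficients.iterrows():
            assert row["t"] == pytest.approx(row["estimate"] / row["se"], rel=1e-6)

    def test_intercept_only_recovers_grand_mean(self):
        spec = ModelSpec(dependent="fprt", predictors=())
        table, _ = simulated_table(spec, seed=2)
        result = fit_lmm(table, spec)
        grand = table["log_rt"].mean()
        assert result.coefficients.loc["intercept", "estimate"] == pytest.approx(
            grand, abs=0.05
        )

    def test_known_effect_recovered_within_two_se(self):
        spec = ModelSpec(dependent="fprt", predictors=("x", "z"))
        table, truth = simulated_table(spec, beta_x=0.1, n_subjects=12, seed=3)
        result = fit_lmm(table, spec)
        row = result.coefficients.loc["x"]
        assert abs(row["estimate"] - 0.1) <= 2 * row["se"]
        assert row["significant"]

    def test_backends_agree_on_crossed_intercept_model(self):
        """lme4 and statsmodels are independent implementations of the same
        REML problem; their fixed effects must agree."""
        spec = ModelSpec(dependent="fprt", predictors=("x", "z"))
        table, _ = simulated_table(spec, beta_x=0.08, seed=4)
        a = fit_lmm(table, spec, backend="lme4")
        b = fit_lmm(table, spec, backend="statsmodels")
        for term in ("intercept", "x", "z"):
            assert a.coefficients.loc[term, "estimate"] == pytest.approx(
                b.coefficients.loc[term, "estimate"], abs=1e-3
            )
            assert a.coefficients.loc[term, "se"] == pytest.approx(
                b.coefficients.loc[term, "se"], rel=0.05
            )

    def test_too_few_groups_rejected(self):
        table = pd.DataFrame({
            "log_rt": [5.0, 5.1, 5.2],
            "subject": ["a", "a", "a"],
            "sentence": ["s1", "s2", "s3"],
            "x": [0.0, 1.0, -1.0],
        })
        with pytest.raises(ValueError, match="at least 2"):
            fit_lmm(table, ModelSpec(dependent="fprt", predictors=("x",)))

    def test_batched_fits_match_single_fits(self):
        spec = ModelSpec(dependent="fprt", predictors=("x",))
        tables = [simulated_table(ModelSpec(dependent="fprt",
                                            predictors=("x", "z")),
                                  beta_x=0.05, seed=s)[0] for s in (6, 7)]
        many = fit_lmm_many(tables, spec)
        singles = [fit_lmm(t, spec) for t in tables]
        for m, s in zip(many, singles):
            assert np.allclose(m.coefficients["estimate"],
                               s.coefficients["estimate"], atol=1e-4)


class TestCorrelations:
    def test_self_correlation_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "neg": -x})
        corr = predictor_correlations(df, ["x", "neg"])
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_manual_covariance_computation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        corr = predictor_correlations(df, ["a", "b", "c"])
        for i in ("a", "b", "c"):
            for j in ("a", "b", "c"):
                x, y = df[i].to_numpy(), df[j].to_numpy()
                manual = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum())
                )
                assert corr.loc[i, j] == pytest.approx(manual, abs=1e-12)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = predictor_correlations(df, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"])
        assert corr.attrs["constant_columns"] == ["b"]
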