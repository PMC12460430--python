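import numpy as np
import pytest
from scipy import integrate, optimize, stats

from traceddm import _wfpt
from traceddm.ddm import (
    DDMParams,
    WienerDDM,
    assess_fit_quality,
    ez_init,
    filter_outliers,
    fit_ml,
    fit_participants,
    simulate,
    wiener_logpdf,
)
from traceddm.trajectories import Trajectory, TrialRecord, TrialSet


def _trialset_from_rts(rts, upper=None):
    traj = Trajectory(t=np.array([0.0, 0.5]), x=np.array([0.0, -5.0]),
                      y=np.array([0.0, 5.0]))
    recs = []
    for i, rt in enumerate(rts):
        ok = True if upper is None else bool(upper[i])
        recs.append(
            TrialRecord("p1", i + 1, "left", "left" if ok else "right",
                        int(ok), float(rt), traj)
        )
    return TrialSet({"p1": recs})


class TestClosedForms:
    def test_absorption_probability(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.0)
        assert p.p_upper() == pytest.approx(0.8808, abs=1e-4)

    def test_mean_decision_time(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.0)
        assert p.mean_decision_time() == pytest.approx(0.7616, abs=1e-4)

    def test_driftless_symmetric(self):
        p = DDMParams(v=0.0, a=2.0, t0=0.3)
        assert p.p_upper() == pytest.approx(0.5)
        assert p.mean_decision_time() == pytest.approx(1.0)


class TestWienerDensity:
    @pytest.mark.parametrize("v,a", [(1.0, 2.0), (-0.5, 1.2), (2.0, 0.8)])
    def test_normalization(self, v, a):
        p = DDMParams(v=v, a=a, t0=0.0)
        total = 0.0
        for upper in (True, False):
            val, _ = integrate.quad(
                lambda t: float(np.exp(wiener_logpdf(float(t), upper, p))),
                1e-6, 40.0, limit=300,
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_upper_integral_equals_absorption_probability(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.0)
        val, _ = integrate.quad(
            lambda t: float(np.exp(wiener_logpdf(float(t), True, p))),
            1e-6, 40.0, limit=300,
        )
        assert val == pytest.approx(0.8808, abs=1e-4)

    def test_density_zero_before_t0(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.4)
        assert wiener_logpdf(0.3, True, p) == -np.inf

    def test_simulator_matches_density(self):
        # KS distance between simulated upper-boundary RTs and the density
        p = DDMParams(v=1.2, a=1.6, t0=0.2)
        sam = simulate(p, 20_000, seed=5)
        rts = sam.rt[sam.choice]
        grid = np.linspace(1e-4, 12, 4000) + p.t0
        pdf = np.exp(wiener_logpdf(grid, True, p))
        cdf = np.cumsum(pdf) * (grid[1] - grid[0])
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(rts), grid, side="right") / rts.size
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestSimulator:
    def test_deterministic_under_seed(self):
        p = DDMParams(v=0.8, a=1.8, t0=0.3)
        a = simulate(p, 500, seed=9)
        b = simulate(p, 500, seed=9)
        assert np.array_equal(a.rt, b.rt)
        assert np.array_equal(a.choice, b.choice)

    def test_moments_against_closed_form(self):
        p = DDMParams(v=1.0, a=2.0, t0=0.0)
        n = 30_000
        sam = simulate(p, n, seed=3)
        p_up = sam.choice.mean()
        se_p = np.sqrt(p_up * (1 - p_up) / n)
        assert abs(p_up - p.p_upper()) < 3 * se_p
        mdt = sam.rt.mean()
        se_m = sam.rt.std() / np.sqrt(n)
        assert abs(mdt - p.mean_decision_time()) < 3 * se_m

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate(DDMParams(1, 2, 0.1), 10, dt=0.0)


class TestOutlierFilter:
    def test_hand_counted_removals(self):
        rts = [0.2, 0.21, 0.22, 0.23] + [1.0] * 96
        ts = _trialset_from_rts(rts)
        kept, report = filter_outliers(ts)
        row = report.iloc[0]
        assert row.n_early_removed == 4  # ceil(0.035 * 100)
        assert row.n_late_removed == 0   # SD = 0 among the rest, strict >
        assert row.n_kept == 96

    def test_identical_rts_only_early_removed(self):
        ts = _trialset_from_rts([1.0] * 50)
        kept, report = filter_outliers(ts)
        assert report.iloc[0].n_late_removed == 0
        assert report.iloc[0].n_early_removed == 2

    def test_not_idempotent(self, rng):
        rts = rng.lognormal(-0.2, 0.4, 200).clip(0.05, 2.0)
        ts = _trialset_from_rts(rts)
        once, _ = filter_outliers(ts)
        twice, rep2 = filter_outliers(once)
        assert len(twice) < len(once)

    def test_small_participant_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            filter_outliers(_trialset_from_rts([1.0] * 5))


class TestMLFit:
    def test_refuses_below_trial_floor(self):
        with pytest.raises(ValueError, match="at least 10"):
            WienerDDM([0.5] * 9, [True] * 9)

    def test_loglik_at_truth_not_above_optimum(self):
        true = DDMParams(v=1.2, a=1.7, t0=0.3)
        sam = simulate(true, 300, seed=21)
        model = WienerDDM(sam.rt, sam.choice)
        res = model.fit(seed=0)
        assert res.loglik >= model.loglik(true) - 1e-6
        assert res.fit_index == pytest.approx(res.loglik / 300)

    def test_single_seed_recovery(self):
        true = DDMParams(v=1.5, a=1.8, t0=0.35)
        sam = simulate(true, 500, seed=2)
        res = fit_ml(sam.rt, sam.choice, seed=3)
        assert abs(res.params.v - true.v) < 0.4
        assert abs(res.params.a - true.a) < 0.25
        assert abs(res.params.t0 - true.t0) < 0.05
        assert np.all(np.isfinite(res.bse))

    def test_all_one_choice_flagged(self):
        true = DDMParams(v=4.0, a=1.5, t0=0.3)
        sam = simulate(true, 60, seed=8)
        res = fit_ml(sam.rt, np.ones(60, dtype=bool), seed=0)
        assert res.all_one_choice

    def test_matches_scipy_optimizer(self):
        """Compiled Nelder-Mead reaches the same optimum as scipy's."""
        true = DDMParams(v=1.0, a=2.0, t0=0.3)
        sam = simulate(true, 200, seed=4)
        res = fit_ml(sam.rt, sam.choice, seed=1)
        t0_max = float(sam.rt.min()) - 1e-3
        x0 = ez_init(sam.rt, sam.choice)
        x0[2] = min(x0[2], t0_max)
        sp = optimize.minimize(
            _wfpt.negloglik, x0, args=(sam.rt, sam.choice, 0.5, t0_max),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        assert -res.loglik <= sp.fun + 1e-3
        assert np.allclose(res.params.as_array(), sp.x, atol=0.05)


class TestFitQuality:
    def test_degenerate_inputs_rejected(self, rng):
        import pandas as pd
        fits = pd.DataFrame({
            "participant": ["a", "b", "c"],
            "v": [1.0, 1.2, 0.9], "a": [2.0, 1.9, 2.1],
            "t0": [0.3, 0.35, 0.4], "fit_index": [-0.5, -0.4, -0.6],
        })
        with pytest.raises(ValueError, match="n_sets"):
            assess_fit_quality(fits, n_sets=1, seed=0)
        with pytest.raises(ValueError, match="participants"):
            assess_fit_quality(fits.iloc[:2], n_sets=10, seed=0)

    def test_uniform_rt_participant_flagged(self, rng):
        """A participant whose RTs are uniform noise is a clear misfit."""
        import pandas as pd
        rows = []
        for i in range(12):
            true = DDMParams(v=float(rng.uniform(0.4, 1.2)),
                             a=float(rng.uniform(1.6, 2.4)),
                             t0=float(rng.uniform(0.3, 0.6)))
            sam = simulate(true, 90, seed=int(rng.integers(2**31)))
            res = fit_ml(sam.rt, sam.choice, seed=i)
            rows.append({"participant": f"p{i}", "v": res.params.v,
                         "a": res.params.a, "t0": res.params.t0,
                         "fit_index": res.fit_index})
        junk_rt = rng.uniform(0.05, 2.0, 90)
        junk_up = rng.random(90) < 0.5
        junk = fit_ml(junk_rt, junk_up, seed=99)
        rows.append({"participant": "junk", "v": junk.params.v,
                     "a": junk.params.a, "t0": junk.params.t0,
                     "fit_index": junk.fit_index})
        fits = pd.DataFrame(rows)
        flags = assess_fit_quality(fits, n_sets=120, n_trials=90, seed=7)
        assert bool(flags.loc[flags.participant == "junk", "bad_fit"].iloc[0])


def test_fit_participants_frame(small_cohort):
    trials, truth = small_cohort
    sub = TrialSet({pid: trials.trials[pid] for pid in trials.participants[:3]})
    fits = fit_participants(sub, seed=0)
    assert list(fits.columns) == [
        "participant", "v", "a", "t0", "loglik", "fit_index", "n_trials",
        "converged",
    ]
    assert fits.converged.all()
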