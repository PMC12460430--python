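"""Drift-diffusion model: simulation, ML fitting, outlier and fit-quality rules.

The model has three free parameters per participant — drift rate ``v``,
threshold separation ``a`` and non-decision time ``t0`` — with the relative
start point fixed at ``zr = 0.5`` (neutral bias) and diffusion coefficient
``s = 1``.  The upper boundary codes the correct response.

Fitting follows the statsmodels convention: :class:`WienerDDM` is built from
one participant's response data and :meth:`WienerDDM.fit` returns a
:class:`WienerDDMResults` with estimates, standard errors (numerical Hessian)
and a ``summary()`` table.  :func:`fit_ml` is the functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _wfpt
from .trajectories import TrialSet

__all__ = [
    "DDMParams",
    "ChoiceRTSample",
    "WienerDDM",
    "WienerDDMResults",
    "simulate",
    "wiener_logpdf",
    "filter_outliers",
    "sample_censored",
    "fit_ml",
    "fit_participants",
    "assess_fit_quality",
    "ez_init",
]


@dataclass(frozen=True)
class DDMParams:
    """Drift rate (1/s), threshold separation, non-decision time (s)."""

    v: float
    a: float
    t0: float
    zr: float = 0.5
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"threshold separation must be > 0, got {self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        if not (0 < self.zr < 1):
            raise ValueError(f"relative start point must lie in (0, 1), got {self.zr}")
        if self.s != 1.0:
            raise ValueError("diffusion coefficient is fixed at 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.a, self.t0])

    # closed forms for the unbiased case, used as oracles and EZ-style inits
    def p_upper(self) -> float:
        """Probability of absorption at the upper (correct) boundary."""
        v, a, z = self.v, self.a, self.zr * self.a
        if abs(v) < 1e-12:
            return z / a
        return float((1.0 - math.exp(-2.0 * v * z)) / (1.0 - math.exp(-2.0 * v * a)))

    def mean_decision_time(self) -> float:
        """Unconditional mean first-passage time (zr = 0.5 closed form)."""
        v, a = self.v, self.a
        if self.zr != 0.5:
            raise NotImplementedError("closed form implemented for zr = 0.5 only")
        if abs(v) < 1e-12:
            z = self.zr * a
            return float(z * (a - z))
        return float(a / (2.0 * v) * math.tanh(a * v / 2.0))


@dataclass(frozen=True)
class ChoiceRTSample:
    """Simulated choices (True = upper/correct) and response times in seconds."""

    choice: np.ndarray
    rt: np.ndarray

    def __len__(self) -> int:
        return int(self.rt.size)


def simulate(
    params: DDMParams,
    n: int,
    dt: float = 1e-3,
    seed: int | np.random.Generator | None = None,
    max_time: float = 20.0,
    return_paths: bool = False,
) -> ChoiceRTSample | Tuple[ChoiceRTSample, np.ndarray, np.ndarray]:
    """Euler-Maruyama first-passage sampler with Brownian-bridge crossings.

    Each step adds ``v*dt + sqrt(dt)*N(0,1)`` to the accumulator started at
    ``zr*a``.  Within-step boundary crossings are detected with the exact
    bridge crossing probability ``exp(-2*d*d'/dt)`` for current/next distances
    ``d, d'`` to a boundary, which removes the O(sqrt(dt)) bias of naive
    end-of-step monitoring.  RT = crossing time + t0.  Walks not absorbed by
    ``max_time`` get ``rt = inf``.

    With ``return_paths=True`` also returns the evidence paths as a
    ``(n, n_steps+1)`` array (NaN after absorption) plus the step grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v, a, t0 = params.v, params.a, params.t0
    n_steps = int(np.ceil(max_time / dt))
    y = np.full(n, params.zr * a)
    active = np.arange(n)
    choice = np.zeros(n, dtype=bool)
    dtime = np.full(n, np.inf)
    sqdt = math.sqrt(dt)
    if return_paths:
        paths = np.full((n, n_steps + 1), np.nan)
        paths[:, 0] = y
        tgrid = np.arange(n_steps + 1) * dt

    for step in range(n_steps):
        if active.size == 0:
            break
        ya = y[active]
        yn = ya + v * dt + sqdt * rng.standard_normal(active.size)
        t_cross = (step + 1) * dt
        up = yn >= a
        lo = (~up) & (yn <= 0.0)
        interior = ~(up | lo)
        if np.any(interior):
            yi, yni = ya[interior], yn[interior]
            p_up = np.exp(-2.0 * (a - yi) * (a - yni) / dt)
            p_lo = np.exp(-2.0 * yi * yni / dt)
            u1 = rng.random(yi.size)
            u2 = rng.random(yi.size)
            hit_up = u1 < p_up
            hit_lo = u2 < p_lo
            both = hit_up & hit_lo
            if np.any(both):
                # rare: resolve to the more probable boundary
                pick_up = rng.random(int(both.sum())) < (
                    p_up[both] / (p_up[both] + p_lo[both])
                )
                hit_lo[np.flatnonzero(both)[pick_up]] = False
                hit_up[np.flatnonzero(both)[~pick_up]] = False
            up[interior] = hit_up
            lo[interior] = hit_lo
        absorbed = up | lo
        idx = active[absorbed]
        choice[idx] = up[absorbed]
        dtime[idx] = t_cross
        if return_paths:
            yn_rec = np.clip(yn, 0.0, a)
            paths[active, step + 1] = yn_rec
            # freeze path at boundary value for absorbed walks
            paths[idx, step + 1] = np.where(up[absorbed], a, 0.0)
        y[active] = yn
        active = active[~absorbed]

    rt = dtime + t0
    sample = ChoiceRTSample(choice=choice, rt=rt)
    if return_paths:
        return sample, paths, tgrid
    return sample


def wiener_logpdf(
    rt: np.ndarray | float,
    choice: np.ndarray | bool,
    params: DDMParams,
) -> np.ndarray | float:
    """Log Wiener first-passage density of (rt, boundary) under ``params``.

    ``choice`` is True (or 1) for the upper boundary.  The lower-boundary
    density is obtained by reflection (v -> -v, zr -> 1 - zr).  Returns -inf
    where rt <= t0.
    """
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    ch_arr = np.atleast_1d(np.asarray(choice, dtype=bool))
    if ch_arr.size == 1 and rt_arr.size > 1:
        ch_arr = np.full(rt_arr.size, bool(ch_arr[0]))
    out = _wfpt.logpdf_many(rt_arr, ch_arr, params.v, params.a, params.t0, params.zr)
    if np.isscalar(rt) or (isinstance(rt, float)):
        return float(out[0])
    return out


def filter_outliers(
    trials: TrialSet,
    early_frac: float = 0.035,
    sd_mult: float = 2.0,
) -> Tuple[TrialSet, pd.DataFrame]:
    """Per-participant RT outlier removal: fastest fraction, then mean + k*SD.

    First the ``ceil(early_frac * n)`` fastest-RT trials are dropped, then —
    on the remaining trials — every trial with RT strictly above
    ``mean + sd_mult * SD`` (sample SD).  Not idempotent: reapplication trims
    further, which the report makes visible.
    """
    kept: Dict[str, list] = {}
    rows = []
    for pid, recs in trials.trials.items():
        n = len(recs)
        if n < 10:
            raise ValueError(
                f"participant {pid!r} has {n} trials; outlier filtering needs >= 10"
            )
        rts = np.array([r.rt for r in recs])
        n_early = int(np.ceil(early_frac * n))
        order = np.argsort(rts, kind="stable")
        early_idx = set(order[:n_early].tolist())
        remaining = [i for i in range(n) if i not in early_idx]
        rem_rts = rts[remaining]
        mean = float(rem_rts.mean())
        sd = float(rem_rts.std(ddof=1)) if rem_rts.size > 1 else 0.0
        cutoff = mean + sd_mult * sd
        late_removed = [i for i in remaining if rts[i] > cutoff]
        keep_idx = [i for i in remaining if rts[i] <= cutoff]
        if len(keep_idx) < 2:
            raise ValueError(
                f"participant {pid!r} left with {len(keep_idx)} trials after filtering"
            )
        kept[pid] = [recs[i] for i in keep_idx]
        rows.append(
            {
                "participant": pid,
                "n_total": n,
                "n_early_removed": n_early,
                "n_late_removed": len(late_removed),
                "n_kept": len(keep_idx),
                "pct_removed": 100.0 * (n - len(keep_idx)) / n,
                "late_cutoff": cutoff,
            }
        )
    return TrialSet(kept), pd.DataFrame(rows)


def sample_censored(
    params: DDMParams,
    n_keep: int,
    rt_cap: float = 2.0,
    rng: np.random.Generator | None = None,
    dt: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n_keep`` choice/RT pairs with RT below ``rt_cap``.

    Mirrors the task's stimulus-phase time limit: over-cap trials are
    discarded and redrawn.  Returns (rt, upper); fewer than ``n_keep`` only
    when the cap leaves almost no probability mass (caller must check).
    """
    rng = rng or np.random.default_rng()
    n_steps = int(math.ceil((rt_cap + 0.5) / dt))
    rts: List[np.ndarray] = []
    ups: List[np.ndarray] = []
    got = 0
    for _ in range(50):
        ch, dtm = _wfpt.simulate_rts(
            params.v, params.a, params.zr, max(2 * n_keep, 60), dt, n_steps,
            int(rng.integers(2**31)),
        )
        rt = dtm + params.t0
        ok = rt < rt_cap
        rts.append(rt[ok])
        ups.append(ch[ok])
        got += int(ok.sum())
        if got >= n_keep:
            break
    rt_all = np.concatenate(rts)
    up_all = np.concatenate(ups)
    return rt_all[:n_keep], up_all[:n_keep]


def ez_init(rt: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Closed-form EZ-style starting values (v, a, t0) from summary statistics.

    Uses accuracy, and mean/variance of correct RTs (all RTs as fallback),
    with edge corrections for accuracy 0, 0.5 and 1.
    """
    n = rt.size
    pc = float(np.mean(upper))
    pc = min(max(pc, 0.5 + 1.0 / (2.0 * n)), 1.0 - 1.0 / (2.0 * n))
    rts_c = rt[upper] if np.any(upper) else rt
    mrt = float(np.mean(rts_c))
    vrt = float(np.var(rts_c, ddof=1)) if rts_c.size > 1 else 0.01
    vrt = max(vrt, 1e-4)
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    v = float(np.clip(v, 0.05, 8.0))
    a = float(np.clip(L / v, 0.3, 4.0))
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    t0 = float(np.clip(mrt - mdt, 0.0, float(rt.min()) - 1e-3))
    return np.array([v, a, t0])


class WienerDDM:
    """Maximum-likelihood Wiener diffusion model for one participant.

    Parameters
    ----------
    rt : response times in seconds (one per trial).
    upper : boolean/0-1 array; True where the upper (correct) boundary was hit.
    zr : relative start point, fixed at 0.5 (neutral bias).
    """

    MIN_TRIALS = 10  # ML fitting floor

    def __init__(self, rt: Sequence[float], upper: Sequence[bool], zr: float = 0.5):
        self.rt = np.asarray(rt, dtype=float)
        self.upper = np.asarray(upper, dtype=bool)
        if self.rt.size != self.upper.size:
            raise ValueError("rt and upper must have equal length")
        if self.rt.size < self.MIN_TRIALS:
            raise ValueError(
                f"refusing to fit {self.rt.size} trials; "
                f"the ML fit requires at least {self.MIN_TRIALS}"
            )
        if np.any(self.rt <= 0):
            raise ValueError("all RTs must be positive")
        self.zr = zr

    @classmethod
    def from_records(cls, records) -> "WienerDDM":
        """Build from TrialRecord list; upper boundary codes a correct response."""
        rt = [r.rt for r in records]
        upper = [bool(r.accuracy) for r in records]
        return cls(rt, upper)

    def loglik(self, params: DDMParams) -> float:
        return float(np.sum(wiener_logpdf(self.rt, self.upper, params)))

    def fit(self, n_starts: int = 5, seed: int | None = 0,
            maxiter: int = 400) -> "WienerDDMResults":
        """Multi-start Nelder-Mead ML estimation of (v, a, t0)."""
        rng = np.random.default_rng(seed)
        t0_max = float(self.rt.min()) - 1e-3
        base = ez_init(self.rt, self.upper)
        base[2] = min(base[2], t0_max)
        starts = [base]
        for _ in range(max(0, n_starts - 2)):
            pert = base + rng.normal(0, [0.4, 0.25, 0.05])
            pert[1] = max(pert[1], 0.2)
            pert[2] = float(np.clip(pert[2], 0.0, t0_max))
            starts.append(pert)
        if n_starts >= 2:  # one dispersed start far from the EZ guess
            starts.append(np.array([0.5, 1.0, max(0.0, t0_max * 0.5)]))
        starts_arr = np.asarray(starts)
        x, f, conv = _wfpt.multistart_fit(
            starts_arr, self.rt, self.upper, self.zr, t0_max, maxiter
        )
        params = DDMParams(v=float(x[0]), a=float(max(x[1], 1e-2)),
                           t0=float(np.clip(x[2], 0.0, t0_max)), zr=self.zr)
        loglik = -float(f)
        one_choice = bool(np.all(self.upper) or not np.any(self.upper))
        bse = self._bse(x, t0_max)
        return WienerDDMResults(
            model=self, params=params, loglik=loglik,
            n_trials=int(self.rt.size), converged=bool(conv),
            fit_index=loglik / self.rt.size, bse=bse,
            all_one_choice=one_choice,
        )

    def _bse(self, x: np.ndarray, t0_max: float) -> np.ndarray:
        """Standard errors from a central-difference Hessian; NaN if singular."""
        def nll(theta):
            return _wfpt.negloglik(theta, self.rt, self.upper, self.zr, t0_max)

        h = np.array([1e-4, 1e-4, 1e-5])
        hess = np.zeros((3, 3))
        f0 = nll(x)
        for i in range(3):
            for j in range(i, 3):
                ei = np.zeros(3); ei[i] = h[i]
                ej = np.zeros(3); ej[j] = h[j]
                if i == j:
                    val = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h[i] ** 2
                else:
                    val = (
                        nll(x + ei + ej) - nll(x + ei - ej)
                        - nll(x - ei + ej) + nll(x - ei - ej)
                    ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.inv(hess)
            d = np.diag(cov)
            with np.errstate(invalid="ignore"):
                return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)


@dataclass
class WienerDDMResults:
    """ML estimates for one participant with uncertainties and diagnostics."""

    model: WienerDDM
    params: DDMParams
    loglik: float
    n_trials: int
    converged: bool
    fit_index: float  # mean log-likelihood per trial
    bse: np.ndarray
    all_one_choice: bool

    @property
    def names(self) -> List[str]:
        return ["v", "a", "t0"]

    def summary(self) -> str:
        lines = [
            "Wiener diffusion ML fit (zr = 0.5, s = 1)",
            f"  n_trials: {self.n_trials}   loglik: {self.loglik:.3f}   "
            f"fit index (loglik/trial): {self.fit_index:.4f}",
            f"  converged: {self.converged}"
            + ("   WARNING: all responses on one boundary" if self.all_one_choice else ""),
            f"  {'param':<6}{'estimate':>10}{'std err':>10}",
        ]
        for name, est, se in zip(self.names, self.params.as_array(), self.bse):
            lines.append(f"  {name:<6}{est:>10.4f}{se:>10.4f}")
        return "\n".join(lines)


def fit_ml(rt: Sequence[float], upper: Sequence[bool], n_starts: int = 5,
           seed: int | None = 0) -> WienerDDMResults:
    """Functional wrapper: fit one participant's (rt, boundary) data by ML."""
    return WienerDDM(rt, upper).fit(n_starts=n_starts, seed=seed)


def fit_participants(trials: TrialSet, n_starts: int = 5,
                     seed: int | None = 0) -> pd.DataFrame:
    """Fit every participant; columns participant, v, a, t0, loglik, fit_index,
    n_trials, converged."""
    rows = []
    for pid, recs in trials.trials.items():
        res = WienerDDM.from_records(recs).fit(n_starts=n_starts, seed=seed)
        rows.append(
            {
                "participant": pid,
                "v": res.params.v,
                "a": res.params.a,
                "t0": res.params.t0,
                "loglik": res.loglik,
                "fit_index": res.fit_index,
                "n_trials": res.n_trials,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def assess_fit_quality(
    fits: pd.DataFrame,
    n_sets: int = 1000,
    n_trials: int = 90,
    rt_cap: float = 2.0,
    seed: int | None = None,
    n_starts: int = 5,
) -> pd.DataFrame:
    """Flag bad empirical fits against a synthetic fit-index distribution.

    Parameter triples are drawn from a trivariate normal with the mean and
    covariance of the empirical (v, a, t0) fits (invalid draws with a <= 0 or
    t0 < 0 rejected).  For each set, choices/RTs are simulated, censored at
    ``rt_cap``, subsampled to ``n_trials`` and refit with the same ML
    procedure.  Empirical fit indices below the 5% quantile of the synthetic
    fit-index distribution are flagged as bad fits.

    ``fits`` needs columns participant, v, a, t0, fit_index.
    """
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2 for the 5% quantile to exist")
    if len(fits) < 3:
        raise ValueError("need >= 3 participants to estimate the covariance")
    rng = np.random.default_rng(seed)
    mat = fits[["v", "a", "t0"]].to_numpy(dtype=float)
    mean = mat.mean(axis=0)
    cov = np.cov(mat, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 3:
        raise ValueError("degenerate covariance of empirical parameters")

    synth_index = np.empty(n_sets)
    filled = 0
    while filled < n_sets:
        draw = rng.multivariate_normal(mean, cov, size=n_sets)
        valid = (draw[:, 1] > 0.05) & (draw[:, 2] >= 0)
        for row in draw[valid]:
            if filled >= n_sets:
                break
            params = DDMParams(v=row[0], a=row[1], t0=row[2])
            rt_all, up_all = sample_censored(params, n_trials, rt_cap, rng)
            if rt_all.size < WienerDDM.MIN_TRIALS:
                continue  # degenerate draw, almost no sub-cap mass
            res = fit_ml(rt_all, up_all, n_starts=n_starts,
                         seed=int(rng.integers(2**31)))
            synth_index[filled] = res.fit_index
            filled += 1

    q5 = float(np.quantile(synth_index, 0.05))
    out = fits[["participant", "fit_index"]].copy()
    out["threshold_5pct"] = q5
    out["bad_fit"] = out["fit_index"] < q5
    return out
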