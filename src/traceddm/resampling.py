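"""Trial-reduction bootstrap and trial-order control analyses.

How many trials do cursor measures need?  Two resampling pipelines answer
this:

* pipeline a — per participant, draw ``size`` trials with replacement,
  average the per-trial cursor measures (and RT/accuracy) over the draw, and
  refit the PLSR against the participant's FIXED full-data DDM parameter;
  repeat B times per size and summarize the LOO cv R² distribution;
* pipeline b — draw trials the same way but refit the diffusion model on the
  subsample and square the correlation between subsample and full-data
  parameters across participants (the DDM "self-correlation").

Model families: ``cursor`` uses the minimal-model cursor measures for the
target; ``rt_ac`` uses mean RT and accuracy only; ``hybrid`` uses both.

The order-effect control replaces random draws with presentation-order
prefixes (trials 1..k) and with single trials (trial k alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ddm import WienerDDM, fit_ml
from .measures import MEASURE_NAMES, MeasureConfig, trial_measures_frame
from .plsr import fit_plsr
from .trajectories import TrialSet

__all__ = [
    "ResamplingCurve",
    "resample_plsr",
    "resample_ddm_selfcorr",
    "order_effect_models",
    "family_predictors",
]

TARGETS = ["v", "a", "t0"]
FAMILIES = ["cursor", "rt_ac", "hybrid"]


@dataclass
class ResamplingCurve:
    """Mean and percentile CI of cv R² per trial-sample size."""

    family: str
    target: str
    sizes: np.ndarray
    mean_r2: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_ok: np.ndarray  # usable iterations per size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "target": self.target,
                "size": self.sizes,
                "mean_r2": self.mean_r2,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_ok": self.n_ok,
            }
        )


def family_predictors(
    family: str,
    target: str,
    minimal_predictors: Mapping[str, Sequence[str]],
) -> List[str]:
    """Predictor columns for a model family and DDM-parameter target."""
    cursor = list(minimal_predictors[target])
    if family == "cursor":
        return cursor
    if family == "rt_ac":
        return ["rt", "accuracy"]
    if family == "hybrid":
        return ["rt", "accuracy"] + cursor
    raise ValueError(f"unknown model family {family!r}")


def _per_trial_tables(trials: TrialSet, config: MeasureConfig
                      ) -> Dict[str, pd.DataFrame]:
    per_trial = trial_measures_frame(trials, config)
    return {pid: g.reset_index(drop=True)
            for pid, g in per_trial.groupby("participant", sort=False)}


def _summarize(values: np.ndarray) -> tuple[float, float, float, int]:
    ok = values[np.isfinite(values)]
    if ok.size == 0:
        return float("nan"), float("nan"), float("nan"), 0
    return (
        float(np.mean(ok)),
        float(np.quantile(ok, 0.025)),
        float(np.quantile(ok, 0.975)),
        int(ok.size),
    )


def max_common_size(trials: TrialSet) -> int:
    """Largest sample size drawable for every participant (minimum count)."""
    return min(len(v) for v in trials.trials.values())


def resample_plsr(
    trials: TrialSet,
    params: pd.DataFrame,
    minimal_predictors: Mapping[str, Sequence[str]],
    sizes: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    families: Iterable[str] = FAMILIES,
    targets: Iterable[str] = TARGETS,
    measure_config: MeasureConfig = MeasureConfig(),
    identity_draw: bool = False,
) -> List[ResamplingCurve]:
    """Pipeline a: bootstrap cursor measures, keep DDM parameters fixed.

    ``params`` holds the full-data fits (columns participant, v, a, t0).
    One RNG stream per (size, iteration) is derived from the master seed so
    the draws are reproducible and shared across families/targets within an
    iteration.  ``identity_draw`` replaces the bootstrap by the first
    ``size`` trials (test hook: with size == full count this reproduces the
    full-data model).
    """
    families = list(families)
    targets = list(targets)
    cap = max_common_size(trials)
    sizes = list(sizes)
    for s in sizes:
        if not (1 <= s <= cap):
            raise ValueError(
                f"size {s} outside 1..{cap} (minimum retained-trial count)"
            )
    tables = _per_trial_tables(trials, measure_config)
    pids = [p for p in trials.participants]
    params = params.set_index("participant")
    pred_cols = ["rt", "accuracy"] + MEASURE_NAMES

    r2 = {
        (f, tgt): np.full((len(sizes), B), np.nan)
        for f in families for tgt in targets
    }
    for si, size in enumerate(sizes):
        for b in range(B):
            ss = np.random.SeedSequence(seed, spawn_key=(si, b))
            rng = np.random.default_rng(ss)
            rows = []
            for pid in pids:
                tab = tables[pid]
                if identity_draw:
                    idx = np.arange(size)
                else:
                    idx = rng.integers(0, len(tab), size=size)
                rows.append(tab.iloc[idx][pred_cols].mean())
            X_full = pd.DataFrame(rows, index=pids)
            for f in families:
                for tgt in targets:
                    cols = family_predictors(f, tgt, minimal_predictors)
                    y = params.loc[pids, tgt]
                    try:
                        res = fit_plsr(X_full[cols], y, target_name=tgt)
                        r2[(f, tgt)][si, b] = res.cv_r2
                    except ValueError:
                        pass  # e.g. constant column at size 1; logged as NaN
    curves = []
    for f in families:
        for tgt in targets:
            stats = [_summarize(r2[(f, tgt)][si]) for si in range(len(sizes))]
            curves.append(
                ResamplingCurve(
                    family=f, target=tgt, sizes=np.asarray(sizes),
                    mean_r2=np.array([s[0] for s in stats]),
                    ci_lo=np.array([s[1] for s in stats]),
                    ci_hi=np.array([s[2] for s in stats]),
                    n_ok=np.array([s[3] for s in stats]),
                )
            )
    return curves


def resample_ddm_selfcorr(
    trials: TrialSet,
    params: pd.DataFrame,
    sizes: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 5,
    identity_draw: bool = False,
) -> List[ResamplingCurve]:
    """Pipeline b: refit the DDM on trial subsamples and self-correlate.

    For each size (>= the 10-trial ML floor) and iteration, every
    participant's RT/choice data is resampled with replacement and refit;
    the subsample parameters are Pearson-correlated with the full-data
    parameters across participants and squared.  Non-convergent fits are
    excluded from that iteration's correlation.
    """
    cap = max_common_size(trials)
    sizes = list(sizes)
    for s in sizes:
        if s < WienerDDM.MIN_TRIALS:
            raise ValueError(
                f"size {s} below the {WienerDDM.MIN_TRIALS}-trial ML fitting floor"
            )
        if s > cap:
            raise ValueError(f"size {s} exceeds the common trial count {cap}")
    pids = list(trials.participants)
    data = {
        pid: (
            np.array([r.rt for r in recs]),
            np.array([bool(r.accuracy) for r in recs]),
        )
        for pid, recs in trials.trials.items()
    }
    params = params.set_index("participant")
    full = params.loc[pids, TARGETS].to_numpy()

    out = {tgt: np.full((len(sizes), B), np.nan) for tgt in TARGETS}
    for si, size in enumerate(sizes):
        for b in range(B):
            ss = np.random.SeedSequence(seed, spawn_key=(si, b))
            rng = np.random.default_rng(ss)
            sub = np.full((len(pids), 3), np.nan)
            for k, pid in enumerate(pids):
                rt, up = data[pid]
                if identity_draw:
                    idx = np.arange(size)
                else:
                    idx = rng.integers(0, rt.size, size=size)
                res = fit_ml(rt[idx], up[idx], n_starts=n_starts,
                             seed=int(rng.integers(2**31)))
                if res.converged:
                    sub[k] = res.params.as_array()
            ok = np.all(np.isfinite(sub), axis=1)
            if ok.sum() >= 3:
                for j, tgt in enumerate(TARGETS):
                    sd_sub = sub[ok, j].std()
                    sd_full = full[ok, j].std()
                    if sd_sub > 0 and sd_full > 0:
                        r = np.corrcoef(sub[ok, j], full[ok, j])[0, 1]
                        out[tgt][si, b] = r * r
    curves = []
    for tgt in TARGETS:
        stats = [_summarize(out[tgt][si]) for si in range(len(sizes))]
        curves.append(
            ResamplingCurve(
                family="ddm_selfcorr", target=tgt, sizes=np.asarray(sizes),
                mean_r2=np.array([s[0] for s in stats]),
                ci_lo=np.array([s[1] for s in stats]),
                ci_hi=np.array([s[2] for s in stats]),
                n_ok=np.array([s[3] for s in stats]),
            )
        )
    return curves


def order_effect_models(
    trials: TrialSet,
    params: pd.DataFrame,
    minimal_predictors: Mapping[str, Sequence[str]],
    families: Iterable[str] = FAMILIES,
    targets: Iterable[str] = TARGETS,
    measure_config: MeasureConfig = MeasureConfig(),
) -> pd.DataFrame:
    """Deterministic trial-order control: accumulated prefixes and single trials.

    Returns a long frame with columns mode (accumulated | single), family,
    target, k (trial index), cv_r2.  Presentation order is the retained
    trials' ``trial_index`` order per participant.
    """
    families = list(families)
    targets = list(targets)
    cap = max_common_size(trials)
    if cap < 2:
        raise ValueError("need a common trial count of at least 2")
    tables = _per_trial_tables(trials, measure_config)
    tables = {pid: tab.sort_values("trial").reset_index(drop=True)
              for pid, tab in tables.items()}
    pids = list(trials.participants)
    params = params.set_index("participant")
    pred_cols = ["rt", "accuracy"] + MEASURE_NAMES

    rows = []
    for mode in ("accumulated", "single"):
        for k in range(1, cap + 1):
            feats = []
            for pid in pids:
                tab = tables[pid]
                sel = tab.iloc[:k] if mode == "accumulated" else tab.iloc[[k - 1]]
                feats.append(sel[pred_cols].mean())
            X_full = pd.DataFrame(feats, index=pids)
            for f in families:
                for tgt in targets:
                    cols = family_predictors(f, tgt, minimal_predictors)
                    y = params.loc[pids, tgt]
                    try:
                        res = fit_plsr(X_full[cols], y, target_name=tgt)
                        r2 = res.cv_r2
                    except ValueError:
                        r2 = float("nan")
                    rows.append(
                        {"mode": mode, "family": f, "target": tgt,
                         "k": k, "cv_r2": r2}
                    )
    return pd.DataFrame(rows)
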