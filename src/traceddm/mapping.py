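"""Mapping cursor measures onto DDM parameters.

Pipeline per DDM parameter (v, a, t0), operating on a participant-level
table of mean cursor measures joined to fitted parameters, RT and accuracy:

1. correlational reduction — among near-duplicate measure pairs
   (|r| >= 0.9) keep the one that is cheaper to compute (RT and accuracy may
   absorb a measure but are never discarded themselves, and they stay out of
   the cursor-only predictor set);
2. initial model — PLS regression, iteratively discarding predictors whose
   regression coefficient contradicts the sign of their simple correlation
   with the criterion (removing the weakest-correlating offender first);
3. VIP reduction — drop all predictors with VIP < 0.8, then keep dropping
   the lowest-VIP predictor while the LOO RMSEP does not deteriorate;
4. minimal model — greedily probe removals that cost at most a configured
   loss in cross-validated R^2 and rise in RMSEP.

Every removal is logged in a replayable :class:`ReductionTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURE_NAMES
from .plsr import CursorPLS, CursorPLSResults, fit_plsr

__all__ = [
    "DEFAULT_COST_RANKING",
    "MappingConfig",
    "CorrelationReport",
    "ReductionStep",
    "ReductionTrace",
    "MappingResult",
    "correlation_reduce",
    "sign_consistency_prune",
    "vip_reduce",
    "minimal_reduce",
    "run_mapping",
]

TARGETS = ["v", "a", "t0"]

#: Computation-cost precedence, cheapest first.  Ties in the reduction steps
#: are broken toward keeping the earlier (cheaper) entry.  RT and accuracy
#: are by-products of the trial table and rank cheapest.
DEFAULT_COST_RANKING: List[str] = [
    "rt",
    "accuracy",
    "minX",
    "MAD",
    "MADabove",
    "AUC",
    "AD",
    "curvature",
    "maxVel",
    "minVel",
    "maxAcc",
    "meanVel",
    "motionTime",
    "motorPauses",
    "timeToPeakVel",
    "timeToPeakAcc",
    "xFlips",
    "reversals",
    "accChanges",
    "sampleEnX",
]


@dataclass(frozen=True)
class MappingConfig:
    corr_threshold: float = 0.9
    vip_threshold: float = 0.8
    max_r2_loss: float = 0.01      # tolerated drop in cv R^2 (fraction)
    max_rmsep_rise: float = 0.002  # tolerated rise in LOO RMSEP (y units)
    cost_ranking: Tuple[str, ...] = tuple(DEFAULT_COST_RANKING)

    def cost(self, name: str) -> int:
        try:
            return self.cost_ranking.index(name)
        except ValueError:
            raise KeyError(
                f"measure {name!r} missing from the computation-cost ranking"
            ) from None

    def cost_or_default(self, name: str) -> int:
        """Tie-break cost; names outside the ranking count as costliest."""
        try:
            return self.cost_ranking.index(name)
        except ValueError:
            return len(self.cost_ranking)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with p-values and the discard log."""

    corr: pd.DataFrame
    pvalues: pd.DataFrame
    discarded: List[Tuple[str, str, float]]  # (discarded, retained partner, r)

    def summary(self) -> str:
        lines = ["Correlational reduction (|r| >= threshold keeps the cheaper measure)"]
        if not self.discarded:
            lines.append("  nothing discarded")
        for name, partner, r in self.discarded:
            lines.append(f"  {name:<16} discarded (r = {r:+.3f} with {partner})")
        return "\n".join(lines)


@dataclass(frozen=True)
class ReductionStep:
    step_type: str  # sign-prune | vip-prune | minimal-prune
    removed: str
    cv_r2_before: float
    cv_r2_after: float
    rmsep_before: float
    rmsep_after: float


@dataclass
class ReductionTrace:
    steps: List[ReductionStep] = field(default_factory=list)

    def removed(self) -> List[str]:
        return [s.removed for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    def replay(self, X: pd.DataFrame, y: pd.Series) -> CursorPLSResults:
        """Re-apply the logged removals to reproduce the final model."""
        keep = [c for c in X.columns if c not in set(self.removed())]
        return fit_plsr(X[keep], y, target_name=str(y.name))


@dataclass
class MappingResult:
    """All model stages for one DDM parameter."""

    target: str
    initial: CursorPLSResults
    vip_reduced: CursorPLSResults
    minimal: CursorPLSResults
    trace: ReductionTrace
    correlation_report: CorrelationReport


def _pearson_matrix(df: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    cols = list(df.columns)
    corr = df.corr(method="pearson")
    n = len(df)
    r = corr.to_numpy(copy=True)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-15, None))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return corr, pd.DataFrame(p, index=cols, columns=cols)


def correlation_reduce(
    data: pd.DataFrame,
    threshold: float = 0.9,
    config: Optional[MappingConfig] = None,
) -> Tuple[CorrelationReport, List[str]]:
    """Discard near-duplicate measures, keeping the cheaper of each pair.

    ``data`` holds participant-level columns: cursor measures, the DDM
    parameters (v, a, t0), rt and accuracy.  Only measures are discardable;
    rt and accuracy can be the retained partner but never leave, and they are
    not part of the returned cursor predictor set.  The pair with the highest
    |r| at or above ``threshold`` is resolved first, then correlations are
    re-examined.
    """
    config = config or MappingConfig(corr_threshold=threshold)
    measures = [c for c in data.columns if c in MEASURE_NAMES]
    protected = [c for c in ("rt", "accuracy") if c in data.columns]
    if data[measures + protected].isna().any().any():
        raise ValueError("missing cells in the participant table")
    if len(data) < 4:
        raise ValueError("need >= 4 participants for the correlation structure")
    for m in measures:
        config.cost(m)  # raises KeyError if the ranking is incomplete

    report_cols = measures + [c for c in TARGETS if c in data.columns] + protected
    corr_full, pvals = _pearson_matrix(data[report_cols])

    candidates = measures + protected
    discarded: List[Tuple[str, str, float]] = []
    active = list(candidates)
    while True:
        sub = data[active].corr().to_numpy()
        np.fill_diagonal(sub, 0.0)
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a_, b_ = active[i], active[j]
                if a_ in protected and b_ in protected:
                    continue
                r = sub[i, j]
                if abs(r) >= threshold:
                    if best is None or abs(r) > abs(best[2]):
                        best = (a_, b_, r)
        if best is None:
            break
        a_, b_, r = best
        if a_ in protected:
            drop, keep = b_, a_
        elif b_ in protected:
            drop, keep = a_, b_
        else:
            drop, keep = (a_, b_) if config.cost(a_) > config.cost(b_) else (b_, a_)
        discarded.append((drop, keep, float(r)))
        active.remove(drop)

    retained = [m for m in active if m in measures]
    return CorrelationReport(corr=corr_full, pvalues=pvals, discarded=discarded), retained


class EmptyModelError(ValueError):
    """Every predictor was pruned away; no model remains."""


def _fit(X: pd.DataFrame, y: pd.Series, cols: Sequence[str]) -> CursorPLSResults:
    return fit_plsr(X[list(cols)], y, target_name=str(y.name))


def sign_consistency_prune(
    X: pd.DataFrame,
    y: pd.Series,
    config: Optional[MappingConfig] = None,
) -> Tuple[CursorPLSResults, ReductionTrace]:
    """Remove predictors whose PLSR coefficient contradicts their correlation.

    While any predictor's coefficient and Pearson correlation with the
    criterion have opposite signs, the offender with the smallest |r| is
    removed (ties broken toward removing the costlier measure) and the model
    is refit.  Terminates because the predictor count strictly decreases.
    """
    config = config or MappingConfig()
    cols = list(X.columns)
    if not cols:
        raise EmptyModelError("no predictors to fit")
    trace = ReductionTrace()
    res = _fit(X, y, cols)
    while True:
        r = np.array([stats.pearsonr(X[c], y)[0] for c in res.predictor_names])
        mismatch = np.flatnonzero(res.coef * r < 0)
        if mismatch.size == 0:
            return res, trace
        if len(res.predictor_names) == 1:
            raise EmptyModelError("all predictors sign-inconsistent")
        # weakest absolute correlation goes; ties -> costlier measure
        order = sorted(
            mismatch,
            key=lambda i: (abs(r[i]),
                           -config.cost_or_default(res.predictor_names[i])),
        )
        victim = res.predictor_names[order[0]]
        cols = [c for c in res.predictor_names if c != victim]
        new = _fit(X, y, cols)
        trace.steps.append(
            ReductionStep("sign-prune", victim, res.cv_r2, new.cv_r2,
                          res.rmsep, new.rmsep)
        )
        res = new


def vip_reduce(
    X: pd.DataFrame,
    y: pd.Series,
    model: CursorPLSResults,
    config: Optional[MappingConfig] = None,
) -> Tuple[CursorPLSResults, ReductionTrace]:
    """Drop low-VIP predictors: one bulk pass, then guarded single removals.

    The first pass removes every predictor with VIP below the threshold at
    once.  Afterwards, while any predictor still falls below the threshold,
    the lowest-VIP one is tentatively removed and the removal is kept only if
    the LOO RMSEP does not increase.
    """
    config = config or MappingConfig()
    trace = ReductionTrace()
    res = model
    cols = list(res.predictor_names)

    low = [c for c, v in zip(cols, res.vip) if v < config.vip_threshold]
    if low and len(low) < len(cols):
        new_cols = [c for c in cols if c not in low]
        new = _fit(X, y, new_cols)
        for c in low:
            trace.steps.append(
                ReductionStep("vip-prune", c, res.cv_r2, new.cv_r2,
                              res.rmsep, new.rmsep)
            )
        res, cols = new, new_cols

    while len(cols) > 1:
        vips = res.vip
        i_low = int(np.argmin(vips))
        if vips[i_low] >= config.vip_threshold:
            break
        candidate_cols = [c for k, c in enumerate(cols) if k != i_low]
        new = _fit(X, y, candidate_cols)
        if new.rmsep > res.rmsep:
            break  # removal would hurt prediction; keep the predictor
        trace.steps.append(
            ReductionStep("vip-prune", cols[i_low], res.cv_r2, new.cv_r2,
                          res.rmsep, new.rmsep)
        )
        res, cols = new, candidate_cols
    return res, trace


def minimal_reduce(
    X: pd.DataFrame,
    y: pd.Series,
    model: CursorPLSResults,
    config: Optional[MappingConfig] = None,
) -> Tuple[CursorPLSResults, ReductionTrace]:
    """Greedy removal of predictors whose loss stays within the tolerances.

    A removal is admissible if cv R^2 drops by at most ``max_r2_loss`` and
    RMSEP rises by at most ``max_rmsep_rise`` relative to the current model;
    among admissible removals the one with the smallest RMSEP change is
    taken, and the probing repeats until none qualifies.
    """
    config = config or MappingConfig()
    trace = ReductionTrace()
    res = model
    while len(res.predictor_names) > 1:
        best = None
        for c in res.predictor_names:
            cand_cols = [k for k in res.predictor_names if k != c]
            cand = _fit(X, y, cand_cols)
            d_r2 = cand.cv_r2 - res.cv_r2
            d_rmsep = cand.rmsep - res.rmsep
            if d_r2 >= -config.max_r2_loss and d_rmsep <= config.max_rmsep_rise:
                if best is None or d_rmsep < best[1]:
                    best = (c, d_rmsep, cand)
        if best is None:
            break
        c, _, cand = best
        trace.steps.append(
            ReductionStep("minimal-prune", c, res.cv_r2, cand.cv_r2,
                          res.rmsep, cand.rmsep)
        )
        res = cand
    return res, trace


def run_mapping(
    participants: pd.DataFrame,
    config: Optional[MappingConfig] = None,
) -> Dict[str, MappingResult]:
    """Full reduction chain for each DDM parameter.

    ``participants`` must contain the cursor-measure columns, v, a, t0, rt
    and accuracy (one row per participant).  Deterministic: no randomness in
    the mapping stage.
    """
    config = config or MappingConfig()
    missing = [t for t in TARGETS if t not in participants.columns]
    if missing:
        raise ValueError(f"participant table lacks DDM parameter(s): {missing}")
    report, retained = correlation_reduce(
        participants, threshold=config.corr_threshold, config=config
    )
    out: Dict[str, MappingResult] = {}
    for target in TARGETS:
        y = participants[target]
        X = participants[retained]
        initial, trace = sign_consistency_prune(X, y, config)
        vip_model, vip_trace = vip_reduce(X, y, initial, config)
        minimal, min_trace = minimal_reduce(X, y, vip_model, config)
        trace.steps.extend(vip_trace.steps)
        trace.steps.extend(min_trace.steps)
        out[target] = MappingResult(
            target=target,
            initial=initial,
            vip_reduced=vip_model,
            minimal=minimal,
            trace=trace,
            correlation_report=report,
        )
    return out
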