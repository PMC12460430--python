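"""Partial least squares regression (PLS1) with LOO cross-validation and VIP.

The single-response NIPALS algorithm extracts components that maximize the
covariance between the (z-standardized) predictors and criterion; the
components then act as an ordinary regression basis.  Model performance is
always reported from leave-one-out cross-validation: ``cv_r2 = 1 -
PRESS/TSS`` and ``rmsep = sqrt(PRESS/n)``, with standardization refit inside
every fold so no information leaks from the held-out observation.

Variable importance in projection (VIP) scores summarize each predictor's
contribution across components; their squares average to 1, and predictors
with VIP below 0.8 are conventional candidates for removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

__all__ = ["CursorPLS", "CursorPLSResults", "fit_plsr"]


@njit(cache=True)
def _loo_press_nb(X: np.ndarray, y: np.ndarray, kmax: int) -> np.ndarray:
    """PRESS per component count from a literal leave-one-out loop."""
    n, p = X.shape
    press = np.zeros(kmax)
    for i in range(n):
        m = n - 1
        Xt = np.empty((m, p))
        yt = np.empty(m)
        row = 0
        for r_ in range(n):
            if r_ == i:
                continue
            Xt[row] = X[r_]
            yt[row] = y[r_]
            row += 1
        xm = np.empty(p)
        xs = np.empty(p)
        for j in range(p):
            xm[j] = Xt[:, j].mean()
            sd = Xt[:, j].std() * math_sqrt_corr(m)
            xs[j] = sd if sd > 0 else 1.0
        ym = yt.mean()
        ysd = yt.std() * math_sqrt_corr(m)
        if ysd <= 0:
            ysd = 1.0
        Xs = (Xt - xm) / xs
        ys = (yt - ym) / ysd
        # NIPALS with per-component prediction of the held-out row
        xi = (X[i] - xm) / xs
        Xr = Xs.copy()
        yr = ys.copy()
        W = np.zeros((p, kmax))
        P = np.zeros((p, kmax))
        q = np.zeros(kmax)
        used = 0
        for k in range(kmax):
            w = Xr.T @ yr
            nw = np.sqrt((w * w).sum())
            if nw < 1e-12:
                break
            w /= nw
            tvec = Xr @ w
            tt = (tvec * tvec).sum()
            if tt < 1e-12:
                break
            pj = (Xr.T @ tvec) / tt
            qj = (yr * tvec).sum() / tt
            Xr -= np.outer(tvec, pj)
            yr = yr - qj * tvec
            W[:, k] = w
            P[:, k] = pj
            q[k] = qj
            used += 1
        for k in range(kmax):
            kk = min(k + 1, used)
            if kk == 0:
                pred = ym
            else:
                Wk = np.ascontiguousarray(W[:, :kk])
                Pk = np.ascontiguousarray(P[:, :kk])
                qk = np.ascontiguousarray(q[:kk])
                Bk = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
                pred = ym + ysd * (xi @ Bk)
            press[k] += (y[i] - pred) ** 2
    return press


@njit(cache=True)
def math_sqrt_corr(m: int) -> float:
    """ddof-1 correction factor for numba's population std."""
    return (m / (m - 1.0)) ** 0.5


def _nipals(Xs: np.ndarray, ys: np.ndarray, k: int):
    """PLS1 NIPALS on standardized data; returns (W, P, q, T, actual_k)."""
    n, p = Xs.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    Xr = Xs.copy()
    yr = ys.copy()
    used = 0
    for j in range(k):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pj = (Xr.T @ t) / tt
        qj = float(yr @ t) / tt
        Xr -= np.outer(t, pj)
        yr = yr - qj * t
        W[:, j], P[:, j], q[j], T[:, j] = w, pj, qj, t
        used += 1
    return W[:, :used], P[:, :used], q[:used], T[:, :used], used


def _coefs_per_k(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> List[np.ndarray]:
    """Standardized regression coefficient vectors for every component count."""
    out = []
    for k in range(1, q.size + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        Bk = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
        out.append(Bk)
    return out


@dataclass
class CursorPLSResults:
    """Fitted PLS1 model: weights, coefficients, VIP, LOO diagnostics."""

    predictor_names: List[str]
    target_name: str
    n_components: int
    coef: np.ndarray          # standardized-scale regression coefficients
    x_weights: np.ndarray     # (p, k)
    x_loadings: np.ndarray    # (p, k)
    y_loadings: np.ndarray    # (k,)
    vip: np.ndarray
    cv_r2: float
    rmsep: float
    rmsep_by_k: np.ndarray    # LOO RMSEP for 1..kmax components
    n_obs: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    fittedvalues: np.ndarray  # in-sample fits on the original y scale

    def predict(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        Xs = (X - self.x_mean) / self.x_std
        return self.y_mean + self.y_std * (Xs @ self.coef)

    def summary(self) -> str:
        lines = [
            f"PLS regression: {self.target_name} ~ {len(self.predictor_names)} "
            f"predictors, {self.n_components} component(s), n = {self.n_obs}",
            f"  LOO cv R^2 = {self.cv_r2:.4f}   RMSEP = {self.rmsep:.4f}",
            f"  {'predictor':<16}{'coef(std)':>10}{'VIP':>8}",
        ]
        for name, c, v in zip(self.predictor_names, self.coef, self.vip):
            lines.append(f"  {name:<16}{c:>10.4f}{v:>8.3f}")
        return "\n".join(lines)


class CursorPLS:
    """PLS1 model of one criterion on a block of standardized predictors.

    ``n_components="auto"`` picks the component count minimizing the LOO
    RMSEP over 1..min(p, n-2).
    """

    def __init__(
        self,
        X: Union[pd.DataFrame, np.ndarray],
        y: Union[pd.Series, np.ndarray],
        predictor_names: Optional[Sequence[str]] = None,
        target_name: str = "y",
    ):
        if isinstance(X, pd.DataFrame):
            predictor_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        if isinstance(y, pd.Series):
            target_name = y.name if y.name is not None else target_name
            y = y.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, p) and y length n")
        n, p = self.X.shape
        if n < 5:
            raise ValueError(f"need n >= 5 observations, got {n}")
        if p < 1:
            raise ValueError("need at least one predictor")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite values in X or y")
        self.predictor_names = (
            list(predictor_names) if predictor_names is not None
            else [f"x{i}" for i in range(p)]
        )
        self.target_name = str(target_name)
        stds = self.X.std(axis=0, ddof=1)
        bad = np.flatnonzero(stds == 0)
        if bad.size:
            raise ValueError(
                f"constant predictor column: {self.predictor_names[bad[0]]!r}"
            )
        if self.y.std(ddof=1) == 0:
            raise ValueError("constant criterion")

    def _loo_rmsep(self, kmax: int) -> np.ndarray:
        """LOO RMSEP for each component count 1..kmax (fold-wise refits)."""
        press = _loo_press_nb(np.ascontiguousarray(self.X),
                              np.ascontiguousarray(self.y), kmax)
        return np.sqrt(press / self.X.shape[0])

    def fit(self, n_components: Union[str, int] = "auto") -> CursorPLSResults:
        n, p = self.X.shape
        kmax = max(1, min(p, n - 2))
        rmsep_by_k = self._loo_rmsep(kmax)
        if n_components == "auto":
            k = int(np.argmin(rmsep_by_k)) + 1
        else:
            k = int(n_components)
            if not (1 <= k <= kmax):
                raise ValueError(f"n_components must lie in 1..{kmax}, got {k}")
        xm, xs = self.X.mean(axis=0), self.X.std(axis=0, ddof=1)
        ym, ysd = self.y.mean(), self.y.std(ddof=1)
        Xs = (self.X - xm) / xs
        ys = (self.y - ym) / ysd
        W, P, q, T, used = _nipals(Xs, ys, k)
        k = max(used, 1)
        coef = _coefs_per_k(W, P, q)[-1] if used else np.zeros(p)

        # VIP: weight each predictor by the y-variance its components explain
        ss = q ** 2 * np.einsum("ij,ij->j", T, T)
        denom = ss.sum()
        if denom > 0:
            vip = np.sqrt(p * (W ** 2 @ ss) / denom)
        else:
            vip = np.zeros(p)

        rmsep = float(rmsep_by_k[k - 1])
        press = n * rmsep ** 2
        tss = float(np.sum((self.y - ym) ** 2))
        fitted = ym + ysd * (Xs @ coef)
        return CursorPLSResults(
            predictor_names=self.predictor_names,
            target_name=self.target_name,
            n_components=k,
            coef=coef,
            x_weights=W,
            x_loadings=P,
            y_loadings=q,
            vip=vip,
            cv_r2=1.0 - press / tss,
            rmsep=rmsep,
            rmsep_by_k=rmsep_by_k,
            n_obs=n,
            x_mean=xm,
            x_std=xs,
            y_mean=float(ym),
            y_std=float(ysd),
            fittedvalues=fitted,
        )


def fit_plsr(
    X: Union[pd.DataFrame, np.ndarray],
    y: Union[pd.Series, np.ndarray],
    n_components: Union[str, int] = "auto",
    target_name: str = "y",
) -> CursorPLSResults:
    """Fit a PLS1 model (standardized, LOO-validated); see :class:`CursorPLS`."""
    return CursorPLS(X, y, target_name=target_name).fit(n_components=n_components)
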