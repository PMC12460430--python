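"""Numba-compiled Wiener first-passage-time density and ML optimizer core.

The density uses the classical dual series expansion for the first-passage
time of a drifted Brownian motion between two absorbing boundaries: a
small-time representation (image-method sum over reflected Gaussians) and a
large-time representation (eigenfunction/sine series), switching to whichever
needs fewer terms for a truncation error below ``EPS``.  Everything here is
scale-standardized to diffusion coefficient s = 1.

The lower-boundary density at decision time ``td`` for drift v, separation a
and relative start w is

    f_lower(td) = exp(-v*a*w - v^2*td/2) / a^2  *  f1(td/a^2, w)

and the upper-boundary density follows by reflection (v -> -v, w -> 1-w).

A compact bounded Nelder-Mead minimizer over (v, a, t0) is compiled alongside
so that a single maximum-likelihood fit costs milliseconds; bootstrap and
calibration procedures in this package perform thousands of such fits.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

EPS = 1e-7  # series truncation error tolerance


@njit(cache=True)
def _f1(u: float, w: float) -> float:
    """Standardized density f(u | v=0, a=1, w) via series switching."""
    if u <= 0.0:
        return 0.0
    # number of terms needed by each representation
    if 2.0 * math.sqrt(2.0 * math.pi * u) * EPS < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * EPS * math.sqrt(2.0 * math.pi * u)))
        sq = math.sqrt(u) + 1.0
        if sq > ks:
            ks = sq
    else:
        ks = 2.0
    if math.pi * u * EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * EPS) / (math.pi * math.pi * u))
        inv = 1.0 / (math.pi * math.sqrt(u))
        if inv > kl:
            kl = inv
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        half = (K - 1) // 2 + 1
        acc = 0.0
        for k in range(-half, half + 1):
            wk = w + 2.0 * k
            acc += wk * math.exp(-wk * wk / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u * u * u)
    # large-time expansion
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(
            k * math.pi * w
        )
    return math.pi * acc


@njit(cache=True)
def logpdf_one(td: float, upper: bool, v: float, a: float, w: float) -> float:
    """Log first-passage density at decision time td for one boundary."""
    if td <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return -np.inf
    if upper:
        v = -v
        w = 1.0 - w
    u = td / (a * a)
    f = _f1(u, w)
    if f <= 0.0:
        return -np.inf
    return math.log(f) - math.log(a * a) - v * a * w - v * v * td / 2.0


@njit(cache=True)
def logpdf_many(rt: np.ndarray, upper: np.ndarray, v: float, a: float,
                t0: float, w: float) -> np.ndarray:
    out = np.empty(rt.size)
    for i in range(rt.size):
        out[i] = logpdf_one(rt[i] - t0, upper[i], v, a, w)
    return out


@njit(cache=True)
def negloglik(theta: np.ndarray, rt: np.ndarray, upper: np.ndarray,
              w: float, t0_max: float) -> float:
    """Penalized negative log-likelihood over (v, a, t0); s = 1, zr = w."""
    v = theta[0]
    a = theta[1]
    t0 = theta[2]
    penalty = 0.0
    if a < 1e-2:
        penalty += 1e4 * (1e-2 - a) ** 2
        a = 1e-2
    if t0 < 0.0:
        penalty += 1e4 * t0 * t0
        t0 = 0.0
    if t0 > t0_max:
        penalty += 1e4 * (t0 - t0_max) ** 2
        t0 = t0_max
    if v > 10.0:
        penalty += 1e4 * (v - 10.0) ** 2
        v = 10.0
    if v < -10.0:
        penalty += 1e4 * (v + 10.0) ** 2
        v = -10.0
    total = 0.0
    for i in range(rt.size):
        lp = logpdf_one(rt[i] - t0, upper[i], v, a, w)
        if not np.isfinite(lp):
            lp = -1e4  # soft floor keeps the surface finite for the simplex
        total -= lp
    return total + penalty


@njit(cache=True)
def nelder_mead(x0: np.ndarray, step: np.ndarray, rt: np.ndarray,
                upper: np.ndarray, w: float, t0_max: float,
                maxiter: int, fatol: float, xatol: float):
    """Minimize negloglik from x0; returns (xbest, fbest, converged)."""
    ndim = 3
    npts = ndim + 1
    sim = np.empty((npts, ndim))
    fvals = np.empty(npts)
    sim[0] = x0
    fvals[0] = negloglik(x0, rt, upper, w, t0_max)
    for i in range(ndim):
        xi = x0.copy()
        xi[i] += step[i]
        sim[i + 1] = xi
        fvals[i + 1] = negloglik(xi, rt, upper, w, t0_max)

    converged = False
    for _ in range(maxiter):
        order = np.argsort(fvals)
        sim = sim[order]
        fvals = fvals[order]
        # convergence: spread of values and vertices
        fspread = fvals[-1] - fvals[0]
        xspread = 0.0
        for i in range(1, npts):
            for j in range(ndim):
                d = abs(sim[i, j] - sim[0, j])
                if d > xspread:
                    xspread = d
        if fspread < fatol and xspread < xatol:
            converged = True
            break

        centroid = np.zeros(ndim)
        for i in range(npts - 1):
            centroid += sim[i]
        centroid /= (npts - 1)

        xr = centroid + (centroid - sim[-1])  # reflection
        fr = negloglik(xr, rt, upper, w, t0_max)
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - sim[-1])  # expansion
            fe = negloglik(xe, rt, upper, w, t0_max)
            if fe < fr:
                sim[-1] = xe
                fvals[-1] = fe
            else:
                sim[-1] = xr
                fvals[-1] = fr
        elif fr < fvals[-2]:
            sim[-1] = xr
            fvals[-1] = fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = centroid + 0.5 * (xr - centroid)
            else:  # inside contraction
                xc = centroid + 0.5 * (sim[-1] - centroid)
            fc = negloglik(xc, rt, upper, w, t0_max)
            if fc < min(fr, fvals[-1]):
                sim[-1] = xc
                fvals[-1] = fc
            else:  # shrink toward the best vertex
                for i in range(1, npts):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fvals[i] = negloglik(sim[i], rt, upper, w, t0_max)

    order = np.argsort(fvals)
    return sim[order[0]].copy(), fvals[order[0]], converged


@njit(cache=True)
def multistart_fit(starts: np.ndarray, rt: np.ndarray, upper: np.ndarray,
                   w: float, t0_max: float, maxiter: int):
    """Run Nelder-Mead from each start row; return the best (x, f, converged)."""
    best_x = np.zeros(3)
    best_f = np.inf
    best_conv = False
    for s in range(starts.shape[0]):
        step = np.empty(3)
        step[0] = 0.25
        step[1] = 0.15
        step[2] = 0.02
        x, f, conv = nelder_mead(starts[s], step, rt, upper, w, t0_max,
                                 maxiter, 1e-7, 1e-6)
        if f < best_f:
            best_f = f
            best_x = x
            best_conv = conv
    return best_x, best_f, best_conv


@njit(cache=True)
def simulate_paths(v: float, a: float, zr: float, n: int, dt: float,
                   n_steps: int, seed: int):
    """Euler-Maruyama walks with bridge-corrected crossings, paths recorded.

    Returns (choice upper?, decision time, paths) with paths frozen at the
    boundary value after absorption and NaN beyond the recorded step.
    """
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    choice = np.zeros(n, dtype=np.bool_)
    dtime = np.full(n, np.inf)
    paths = np.full((n, n_steps + 1), np.nan)
    for i in range(n):
        y = zr * a
        paths[i, 0] = y
        for k in range(n_steps):
            yn = y + v * dt + sqdt * np.random.standard_normal()
            t_cross = (k + 1) * dt
            if yn >= a:
                choice[i] = True
                dtime[i] = t_cross
                paths[i, k + 1] = a
                break
            if yn <= 0.0:
                choice[i] = False
                dtime[i] = t_cross
                paths[i, k + 1] = 0.0
                break
            p_up = math.exp(-2.0 * (a - y) * (a - yn) / dt)
            p_lo = math.exp(-2.0 * y * yn / dt)
            u1 = np.random.random()
            u2 = np.random.random()
            hit_up = u1 < p_up
            hit_lo = u2 < p_lo
            if hit_up and hit_lo:
                if np.random.random() < p_up / (p_up + p_lo):
                    hit_lo = False
                else:
                    hit_up = False
            if hit_up:
                choice[i] = True
                dtime[i] = t_cross
                paths[i, k + 1] = a
                break
            if hit_lo:
                choice[i] = False
                dtime[i] = t_cross
                paths[i, k + 1] = 0.0
                break
            paths[i, k + 1] = yn
            y = yn
    return choice, dtime, paths


@njit(cache=True)
def sampen_counts(z: np.ndarray, m: int, r: float):
    """Template-match pair counts (B at length m, A at length m+1)."""
    n = z.size
    nt = n - m
    b = 0
    a_ = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(z[i + k] - z[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(z[i + m] - z[j + m]) <= r:
                    a_ += 1
    return b, a_


@njit(cache=True)
def simulate_rts(v: float, a: float, zr: float, n: int, dt: float,
                 n_steps: int, seed: int):
    """Bridge-corrected first-passage sampler without path recording."""
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    choice = np.zeros(n, dtype=np.bool_)
    dtime = np.full(n, np.inf)
    for i in range(n):
        y = zr * a
        for k in range(n_steps):
            yn = y + v * dt + sqdt * np.random.standard_normal()
            t_cross = (k + 1) * dt
            if yn >= a:
                choice[i] = True
                dtime[i] = t_cross
                break
            if yn <= 0.0:
                choice[i] = False
                dtime[i] = t_cross
                break
            p_up = math.exp(-2.0 * (a - y) * (a - yn) / dt)
            p_lo = math.exp(-2.0 * y * yn / dt)
            u1 = np.random.random()
            u2 = np.random.random()
            hit_up = u1 < p_up
            hit_lo = u2 < p_lo
            if hit_up and hit_lo:
                if np.random.random() < p_up / (p_up + p_lo):
                    hit_lo = False
                else:
                    hit_up = False
            if hit_up:
                choice[i] = True
                dtime[i] = t_cross
                break
            if hit_lo:
                choice[i] = False
                dtime[i] = t_cross
                break
            y = yn
    return choice, dtime
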