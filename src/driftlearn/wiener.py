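"""Two-boundary Wiener first-passage-time distribution.

The drift-diffusion model (DDM) describes a two-alternative decision as a
Wiener process with drift ``v`` (drift rate, DR), diffusion coefficient fixed
at 1, absorbing boundaries at 0 and ``a`` (response boundary, RB), start point
``z * a`` (``z`` the relative bias), and an additive non-decision time ``t0``
(NDT).  The response is determined by which boundary absorbs the process and
the response time by the first-passage time plus ``t0``.

The defective first-passage density at the *lower* boundary is evaluated with
the standard pair of series expansions — a small-time expansion in image
terms and a large-time Fourier sine expansion — switching to whichever needs
fewer terms at a truncation error of 1e-7.  The upper-boundary density follows
from the reflection identity ``f_upper(t; v, z) = f_lower(t; -v, 1 - z)``.

All functions broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "WienerParams",
    "fpt_logdensity",
    "fpt_density",
    "fpt_cdf",
    "choice_probability",
    "mean_decision_time",
    "sample_fpt",
    "simulate_euler",
]

_TRUNC_EPS = 1e-7
_SMALL_KMAX = 64
_LARGE_KMAX = 512


@dataclass(frozen=True)
class WienerParams:
    """Instantaneous DDM parameter set for one trial.

    Parameters
    ----------
    v : float
        Drift rate (evidence units / s, signed).
    a : float
        Boundary separation (> 0).
    z : float
        Start point as a proportion of ``a``; 0 < z < 1.
    t0 : float
        Non-decision time in seconds (>= 0).
    """

    v: float
    a: float
    z: float
    t0: float

    def __post_init__(self) -> None:
        v, a, z, t0 = (np.asarray(x, dtype=float) for x in (self.v, self.a, self.z, self.t0))
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(a))
                and np.all(np.isfinite(z)) and np.all(np.isfinite(t0))):
            raise ValueError("WienerParams must be finite")
        if np.any(a <= 0):
            raise ValueError("boundary separation a must be > 0")
        if np.any((z <= 0) | (z >= 1)):
            raise ValueError("relative bias z must lie strictly in (0, 1)")
        if np.any(t0 < 0):
            raise ValueError("non-decision time t0 must be >= 0")


def _validate(v, a, z, t0):
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(a)) or np.any(~np.isfinite(z)) \
            or np.any(~np.isfinite(t0)) or np.any(a <= 0) or np.any((z <= 0) | (z >= 1)) \
            or np.any(t0 < 0):
        raise ValueError("invalid Wiener parameters (need a>0, 0<z<1, t0>=0, all finite)")
    return v, a, z, t0


def _unpack(p, bound):
    if isinstance(p, WienerParams):
        v, a, z, t0 = p.v, p.a, p.z, p.t0
    else:
        v, a, z, t0 = p
    v, a, z, t0 = _validate(v, a, z, t0)
    if bound == "lower":
        return v, a, z, t0
    if bound == "upper":
        return -v, a, 1.0 - z, t0
    raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")


def _log_f1_small(tau, w, kmax):
    """log of the standardized small-time series (tau = t/a^2, w = relative start)."""
    k = np.arange(-kmax, kmax + 1, dtype=float)
    terms_arg = w[..., None] + 2.0 * k
    # signed terms; sum is positive for valid inputs
    expo = -(terms_arg ** 2) / (2.0 * tau[..., None])
    # factor out the dominant exponent for stability
    m = np.max(expo, axis=-1, keepdims=True)
    s = np.sum(terms_arg * np.exp(expo - m), axis=-1)
    s = np.maximum(s, 1e-300)
    return np.log(s) + m[..., 0] - 0.5 * np.log(2.0 * np.pi) - 1.5 * np.log(tau)


def _log_f1_large(tau, w, kmax):
    """log of the standardized large-time (Fourier) series."""
    k = np.arange(1, kmax + 1, dtype=float)
    expo = -(k ** 2) * (np.pi ** 2) * tau[..., None] / 2.0
    s = np.sum(k * np.exp(expo) * np.sin(k * np.pi * w[..., None]), axis=-1)
    s = np.maximum(s, 1e-300)
    return np.log(np.pi) + np.log(s)


def _n_terms_small(tau):
    # Navarro & Fuss (2009)-style term counts at truncation error _TRUNC_EPS
    eps = _TRUNC_EPS
    arg = 2.0 * eps * np.sqrt(2.0 * np.pi * tau)
    ks = np.where(arg < 1.0, 2.0 + np.sqrt(-2.0 * tau * np.log(np.maximum(arg, 1e-300))),
                  np.sqrt(tau) + 1.0)
    return np.maximum(ks, np.sqrt(tau) + 1.0)


def _n_terms_large(tau):
    eps = _TRUNC_EPS
    arg = np.pi * tau * eps
    kl = np.where(arg < 1.0,
                  np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg, 1e-300)), 0.0)
                          / (np.pi ** 2 * tau)),
                  1.0 / (np.pi * np.sqrt(tau)))
    return np.maximum(kl, 1.0 / (np.pi * np.sqrt(tau)))


def fpt_logdensity(rt, bound, p, *, on_invalid_rt: str = "neginf"):
    """Log of the defective first-passage density at ``rt`` for one boundary.

    ``rt`` is the observed response time (seconds, including non-decision
    time).  Returns ``-inf`` where ``rt <= t0`` (the likelihood of an
    impossible decision time), or raises if ``on_invalid_rt='raise'``.
    """
    v, a, z, t0 = _unpack(p, bound)
    rt = np.asarray(rt, dtype=float)
    if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt must be finite and positive")
    t = rt - t0
    bad = t <= 0
    if np.any(bad) and on_invalid_rt == "raise":
        raise ValueError("rt <= t0 has zero likelihood")

    scalar = np.ndim(t) == 0 and np.ndim(v) == 0 and np.ndim(a) == 0 and np.ndim(z) == 0
    t_, v_, a_, z_ = np.broadcast_arrays(np.atleast_1d(t), v, a, z)
    t_ = np.where(t_ <= 0, 1.0, t_)  # placeholder; masked to -inf below
    tau = t_ / a_ ** 2

    ks = _n_terms_small(tau)
    kl = _n_terms_large(tau)
    use_small = ks < kl
    out = np.empty_like(tau)
    if np.any(use_small):
        kmax = int(min(np.ceil(np.max(ks[use_small])), _SMALL_KMAX))
        out[use_small] = _log_f1_small(tau[use_small], z_[use_small], kmax)
    if np.any(~use_small):
        kmax = int(min(np.ceil(np.max(kl[~use_small])), _LARGE_KMAX))
        out[~use_small] = _log_f1_large(tau[~use_small], z_[~use_small], kmax)

    out = out - v_ * a_ * z_ - (v_ ** 2) * t_ / 2.0 - 2.0 * np.log(a_)
    out = np.where(np.broadcast_to(np.atleast_1d(bad), out.shape), -np.inf, out)
    return float(out[0]) if scalar and out.size == 1 else np.reshape(out, np.broadcast(t, v, a, z).shape)


def fpt_density(rt, bound, p):
    """Defective first-passage density (natural scale)."""
    return np.exp(fpt_logdensity(rt, bound, p))


def choice_probability(p) -> float:
    """Probability that the process is absorbed at the *upper* boundary.

    Closed form ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))`` with the
    zero-drift limit ``z`` handled by expansion; continuous in ``v``.
    """
    if isinstance(p, WienerParams):
        v, a, z, t0 = p.v, p.a, p.z, p.t0
    else:
        v, a, z, t0 = p
    v, a, z, _ = _validate(v, a, z, t0)
    va = v * a
    small = np.abs(va) < 1e-8
    va_safe = np.where(small, 1.0, va)
    exact = np.expm1(-2.0 * va_safe * z) / np.expm1(-2.0 * va_safe)
    limit = z * (1.0 + va * (1.0 - z))
    out = np.where(small, limit, exact)
    return out if out.ndim else float(out)


def mean_decision_time(p) -> float:
    """Expected first-passage time (seconds), excluding non-decision time.

    Unconditional over the two boundaries.  Zero-drift limit is the exact
    ``a^2 z (1 - z)``.
    """
    if isinstance(p, WienerParams):
        v, a, z, t0 = p.v, p.a, p.z, p.t0
    else:
        v, a, z, t0 = p
    v, a, z, _ = _validate(v, a, z, t0)
    x0 = z * a
    small = np.abs(v) < 1e-6
    v_safe = np.where(small, 1.0, v)
    pu = choice_probability((v_safe, a, z, 0.0))
    exact = (a * pu - x0) / v_safe
    limit = x0 * (a - x0)
    out = np.where(small, limit, exact)
    return out if np.ndim(out) else float(out)


def fpt_cdf(rt, bound, p):
    """Defective first-passage CDF: P(T <= rt and absorbed at ``bound``).

    Evaluated by term-wise integration of the large-time Fourier series; the
    number of terms adapts to the smallest decision time requested.  Regions
    where the boundary is unreachable within ``rt`` at ~1e-12 mass return 0.
    """
    v, a, z, t0 = _unpack(p, bound)
    rt = np.asarray(rt, dtype=float)
    t = rt - t0
    scalar = np.ndim(t) == 0 and np.ndim(v) == 0
    t_, v_, a_, z_ = np.broadcast_arrays(np.atleast_1d(t).astype(float), v, a, z)
    out = np.zeros_like(t_, dtype=float)
    pos = t_ > 0
    if np.any(pos):
        tt, vv, aa, zz = t_[pos], v_[pos], a_[pos], z_[pos]
        # unreachable guard: first passage to the lower bound needs travel z*a
        reachable = (zz * aa) ** 2 / (2.0 * tt) < 40.0
        val = np.zeros_like(tt)
        if np.any(reachable):
            val[reachable] = _cdf_series(tt[reachable], vv[reachable],
                                         aa[reachable], zz[reachable])
        out[pos] = val
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar and out.size == 1 else np.reshape(out, np.broadcast(t, v).shape)


def _cdf_series(t, v, a, z):
    """Lower-boundary defective CDF via integrated Fourier series (t > 0)."""
    p_lower = 1.0 - np.asarray(choice_probability((v, a, z, 0.0)))
    tau = t / a ** 2
    # choose kmax so the tail k*exp(-k^2 pi^2 tau_min / 2)/lambda_k < eps
    tau_min = float(np.min(tau))
    kmax = int(np.ceil(np.sqrt(max(4.0, -2.0 * np.log(1e-12) / (np.pi ** 2 * tau_min)))))
    kmax = min(kmax, 4000)
    k = np.arange(1, kmax + 1, dtype=float)
    lam = (v[..., None] ** 2 + (k * np.pi / a[..., None]) ** 2) / 2.0
    terms = (k * np.sin(k * np.pi * z[..., None]) / lam
             * np.exp(-lam * t[..., None]))
    tail = (np.pi / a ** 2) * np.exp(-v * a * z) * np.sum(terms, axis=-1)
    return p_lower - tail


def sample_fpt(n, p, rng, *, grid_size: int = 2048):
    """Draw ``n`` (rt, upper) pairs by numerical inversion of the exact CDF.

    Builds a dense time grid, inverts each defective CDF by interpolation and
    polishes with two Newton steps using the analytic density.  Returns
    ``(rt, upper)`` with ``rt`` including ``t0`` and ``upper`` boolean.
    """
    if isinstance(p, WienerParams):
        v, a, z, t0 = p.v, p.a, p.z, p.t0
    else:
        v, a, z, t0 = p
    v, a, z, t0 = (float(x) for x in (v, a, z, t0))
    _validate(v, a, z, t0)
    pu = choice_probability((v, a, z, t0))
    lam1 = (v ** 2 + (np.pi / a) ** 2) / 2.0
    t_max = mean_decision_time((v, a, z, t0)) + max(40.0 / lam1, 1.0)
    # quadratic spacing: dense near zero where the density is steep
    grid = t_max * np.linspace(0.0, 1.0, grid_size) ** 2
    grid[0] = 1e-9
    rt = np.empty(n)
    u = rng.uniform(size=n)
    upper = u < pu
    for is_up, mass in ((True, pu), (False, 1.0 - pu)):
        sel = upper == is_up
        m = int(np.sum(sel))
        if m == 0:
            continue
        bound = "upper" if is_up else "lower"
        cdf_grid = fpt_cdf(grid + t0, bound, (v, a, z, t0))
        cdf_grid = np.maximum.accumulate(cdf_grid)
        targets = rng.uniform(size=m) * mass
        tt = np.interp(targets, cdf_grid, grid)
        for _ in range(2):
            f = np.maximum(fpt_density(tt + t0, bound, (v, a, z, t0)), 1e-12)
            F = fpt_cdf(tt + t0, bound, (v, a, z, t0))
            tt = np.clip(tt - (F - targets) / f, 1e-9, t_max)
        rt[sel] = tt + t0
    return rt, upper


def simulate_euler(n, p, rng, *, dt: float = 1e-3, t_max: float = 30.0,
                   bridge_correction: bool = True):
    """Euler–Maruyama simulation of the bounded diffusion (independent oracle).

    Deliberately kept separate from the series evaluation and the inverse-CDF
    sampler so it can serve as a cross-check of both.  With
    ``bridge_correction`` (default) the probability that the Brownian bridge
    between consecutive points crossed a boundary mid-step,
    ``exp(-2 d_old d_new / dt)``, is accounted for, removing the O(sqrt(dt))
    under-detection bias of naive thresholding.  Returns ``(rt, upper)``.
    """
    if isinstance(p, WienerParams):
        v, a, z, t0 = p.v, p.a, p.z, p.t0
    else:
        v, a, z, t0 = p
    v, a, z, t0 = (float(x) for x in (v, a, z, t0))
    _validate(v, a, z, t0)
    x = np.full(n, z * a)
    rt = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    alive = np.arange(n)
    sqdt = np.sqrt(dt)
    n_steps = int(t_max / dt)
    for step in range(1, n_steps + 1):
        x_old = x
        x = x + v * dt + sqdt * rng.standard_normal(alive.size)
        hit_up = x >= a
        hit_lo = x <= 0.0
        if bridge_correction:
            interior = ~(hit_up | hit_lo)
            if np.any(interior):
                d_up = (a - x_old[interior]) * (a - x[interior])
                d_lo = x_old[interior] * x[interior]
                p_up = np.exp(-2.0 * d_up / dt)
                p_lo = np.exp(-2.0 * d_lo / dt)
                u = rng.uniform(size=int(interior.sum()))
                cross_up = u < p_up
                cross_lo = (~cross_up) & (u < p_up + p_lo)
                ii = np.flatnonzero(interior)
                hit_up[ii[cross_up]] = True
                hit_lo[ii[cross_lo]] = True
        done = hit_up | hit_lo
        if np.any(done):
            idx = alive[done]
            rt[idx] = step * dt + t0
            upper[idx] = hit_up[done]
            alive = alive[~done]
            x = x[~done]
            if alive.size == 0:
                break
    if alive.size:  # censor stragglers at t_max (negligible mass for sane params)
        rt[alive] = t_max + t0
    return rt, upper
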