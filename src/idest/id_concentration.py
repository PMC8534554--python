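"""Concentration-of-measure estimators: Fisher separability (FisherS),
expected simplex skewness (ESS), and angle/norm concentration (DANCo).

These methods compare a measured property of the point cloud — linear
separability by Fisher discriminants, the expected sine of the angle between
random directions, or the joint concentration of neighbor norms and angles —
against its closed-form behavior in a model n-dimensional distribution, and
report the n that matches best (the "effective dimension" reading of
intrinsic dimension).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import betainc, gammaln, i0e, i1e

from .base import (
    STATUS_DEGENERATE,
    STATUS_INFINITE,
    STATUS_OK,
    BaseIDEstimator,
    classify_value,
)
from .core import build_neighbor_table
from .id_geometric import mind_loglik

__all__ = [
    "FisherS",
    "ESS",
    "DANCo",
    "fishers",
    "ess",
    "danco",
    "separability_profile",
    "ball_inseparability",
    "ess_curve",
    "ess_invert",
]


# ---------------------------------------------------------------------------
# Fisher separability


def ball_inseparability(alpha: float, n: float) -> float:
    """Probability p(α, n) that two points of the uniform n-ball model are
    Fisher-inseparable at threshold α after projection onto the unit sphere.

    Projecting the uniform n-ball radially gives the uniform sphere S^{n−1},
    for which P(⟨x, y⟩ > α) is the spherical-cap mass
    ½·I_{1−α²}((n−1)/2, ½) (regularized incomplete beta), which decays
    geometrically in n as (1−α²)^{(n−1)/2} for fixed α.
    """
    if n <= 1:
        return 0.5
    return 0.5 * float(betainc((n - 1.0) / 2.0, 0.5, 1.0 - alpha**2))


def separability_profile(X: np.ndarray, alphas: np.ndarray, cond_ratio: float = 10.0):
    """Mean inseparability fraction p̄(α) over a grid of thresholds.

    The cloud is centered, projected on the principal components whose
    eigenvalue satisfies λ1/λi < cond_ratio, whitened, and projected onto
    the unit sphere; a point y is inseparable from x at threshold α when
    ⟨x, y⟩ > α.  Returns ``(p_bar, n_dropped)`` where ``n_dropped`` counts
    zero-norm points removed after centering.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    m = Xc.shape[0]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (m - 1)
    retained = (lam > 0) & (lam[0] / np.where(lam > 0, lam, np.inf) < cond_ratio)
    if not np.any(retained):
        retained = lam > 0
    Y = Xc @ vt[retained].T / np.sqrt(lam[retained])
    norms = np.linalg.norm(Y, axis=1)
    keep = norms > 0
    n_dropped = int(np.count_nonzero(~keep))
    Y = Y[keep] / norms[keep, None]
    m = Y.shape[0]
    gram = Y @ Y.T
    np.fill_diagonal(gram, -np.inf)  # never compare a point with itself
    p_bar = np.array(
        [np.count_nonzero(gram > a) / (m * (m - 1)) for a in alphas], dtype=float
    )
    return p_bar, n_dropped


def _invert_inseparability(p_obs: float, alpha: float) -> float:
    """Continuous n with p(α, n) = p_obs, by bracketed root finding."""
    if p_obs >= 0.5:  # at or above the n→1 limit of the cap mass
        return 1.0
    f = lambda n: math.log(ball_inseparability(alpha, n)) - math.log(p_obs)
    lo, hi = 1.0 + 1e-9, 2.0
    while f(hi) > 0 and hi < 1e7:
        hi *= 2.0
    if f(lo) < 0:
        return 1.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def fishers(
    X,
    alphas: np.ndarray | None = None,
    cond_ratio: float = 10.0,
    alpha_select: str = "fixed",
    alpha_fixed: float = 0.8,
) -> tuple[float, str, dict]:
    """Fisher-separability dimension.

    Inverts the uniform-ball inseparability law p(α, n) at the measured
    fraction of Fisher-inseparable point pairs.  With ``alpha_select="auto"``
    the threshold is the one whose p̄(α) sits closest to the middle of the
    usable range (p̄ strictly inside (0, 1)); otherwise ``alpha_fixed``.
    """
    if alphas is None:
        alphas = np.arange(0.60, 0.981, 0.02)
    alphas = np.asarray(alphas, dtype=float)
    if np.any((alphas <= 0) | (alphas >= 1)) or np.any(np.diff(alphas) <= 0):
        raise ValueError("alphas must be strictly increasing within (0, 1)")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("FisherS needs at least 10 points")
    p_bar, n_dropped = separability_profile(X, alphas, cond_ratio=cond_ratio)
    with np.errstate(invalid="ignore"):
        n_alpha = np.array(
            [
                _invert_inseparability(p, a) if p > 0 else np.inf
                for p, a in zip(p_bar, alphas)
            ]
        )
    info = {
        "alphas": alphas,
        "p_bar": p_bar,
        "n_alpha": n_alpha,
        "n_dropped": n_dropped,
    }
    if alpha_select == "auto":
        usable = np.flatnonzero((p_bar > 0) & (p_bar < 1))
        if len(usable) == 0:
            return float("nan"), STATUS_INFINITE, info
        idx = usable[len(usable) // 2]
    elif alpha_select == "fixed":
        idx = int(np.argmin(np.abs(alphas - alpha_fixed)))
    else:
        raise ValueError(f"unknown alpha_select {alpha_select!r}")
    info["alpha_used"] = float(alphas[idx])
    if p_bar[idx] == 0:
        return float("nan"), STATUS_INFINITE, info
    d = float(n_alpha[idx])
    return d, classify_value(d), info


class FisherS(BaseIDEstimator):
    """Effective dimension from linear separability by Fisher discriminants."""

    _method_tag = "FisherS"

    def __init__(
        self,
        alphas=None,
        cond_ratio: float = 10.0,
        alpha_select: str = "fixed",
        alpha_fixed: float = 0.8,
    ):
        self.alphas = alphas
        self.cond_ratio = cond_ratio
        self.alpha_select = alpha_select
        self.alpha_fixed = alpha_fixed

    def _fit(self, X):
        d, status, self.details_ = fishers(
            X,
            alphas=self.alphas,
            cond_ratio=self.cond_ratio,
            alpha_select=self.alpha_select,
            alpha_fixed=self.alpha_fixed,
        )
        return d, status


# ---------------------------------------------------------------------------
# expected simplex skewness (pair/angle version)


def ess_curve(n_grid: np.ndarray) -> np.ndarray:
    """Theoretical E|sin θ| between two independent uniform directions in n
    dimensions: the Wallis-integral ratio ∫sin^{n−1} / ∫sin^{n−2} =
    Γ(n/2)² / (Γ((n+1)/2) Γ((n−1)/2)).  Strictly increasing in n; 0 at n=1."""
    n = np.asarray(n_grid, dtype=float)
    with np.errstate(divide="ignore"):
        log_t = 2 * gammaln(n / 2) - gammaln((n + 1) / 2) - gammaln((n - 1) / 2)
    return np.where(n <= 1, 0.0, np.exp(log_t))


def ess_invert(s: float, d_max: int) -> float:
    """Piecewise-linear inverse of the E|sin θ| curve on the integer grid
    1..d_max, clamped to [1, d_max]; exact at the grid nodes."""
    grid = np.arange(1, max(int(d_max), 2) + 1, dtype=float)
    return float(np.interp(s, ess_curve(grid), grid))


def ess(
    X,
    d_simplex: int = 1,
    n_pairs: int = 100_000,
    seed: int = 0,
    max_rows: int = 2000,
    max_cols: int = 20,
    force: bool = False,
) -> tuple[float, str, dict]:
    """Expected-simplex-skewness dimension (version 'a', simplex order 1).

    The observed statistic is the mean |sin θ| over sampled pairs of
    mean-centered vectors; the dimension is the piecewise-linear inverse of
    the theoretical curve at that value, clamped to [1, p].
    """
    if d_simplex != 1:
        raise NotImplementedError("only d_simplex=1 (pair/angle version) is provided")
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    if not force and (m > max_rows or p > max_cols):
        raise ValueError(
            f"ESS input {m}x{p} exceeds the {max_rows}x{max_cols} cost cap; "
            "reduce the matrix (see bench caps) or pass force=True"
        )
    if m < 3:
        raise ValueError("ESS needs at least 3 points")
    V = X - X.mean(axis=0)
    norms = np.linalg.norm(V, axis=1)
    V = V[norms > 0]
    norms = norms[norms > 0]
    if V.shape[0] < 2:
        return float("nan"), STATUS_DEGENERATE, {}
    U = V / norms[:, None]
    n_vec = U.shape[0]
    total_pairs = n_vec * (n_vec - 1) // 2
    if total_pairs <= n_pairs:
        idx_i, idx_j = np.triu_indices(n_vec, k=1)
    else:
        rng = np.random.default_rng(seed)
        idx_i = rng.integers(0, n_vec, size=n_pairs)
        idx_j = rng.integers(0, n_vec - 1, size=n_pairs)
        idx_j[idx_j >= idx_i] += 1  # distinct pair members
    cos = np.einsum("ij,ij->i", U[idx_i], U[idx_j])
    s = float(np.mean(np.sqrt(np.maximum(1.0 - cos**2, 0.0))))
    d = ess_invert(s, p)
    info = {"statistic": s, "n_pairs_used": len(idx_i)}
    return d, classify_value(d), info


class ESS(BaseIDEstimator):
    """Expected simplex skewness: dimension from the mean sine of pair angles."""

    _method_tag = "ESS"

    def __init__(
        self,
        d_simplex: int = 1,
        n_pairs: int = 100_000,
        seed: int = 0,
        force: bool = False,
    ):
        self.d_simplex = d_simplex
        self.n_pairs = n_pairs
        self.seed = seed
        self.force = force

    def _fit(self, X):
        d, status, self.details_ = ess(
            X,
            d_simplex=self.d_simplex,
            n_pairs=self.n_pairs,
            seed=self.seed,
            force=self.force,
        )
        return d, status


# ---------------------------------------------------------------------------
# DANCo


def _vonmises_fit(theta: np.ndarray) -> tuple[float, float]:
    """ML von Mises location/concentration from a sample of angles."""
    c, s_ = np.cos(theta).mean(), np.sin(theta).mean()
    nu = math.atan2(s_, c)
    r_bar = min(math.hypot(c, s_), 1.0 - 1e-12)
    # invert A(τ) = I1(τ)/I0(τ) = r_bar
    a = lambda tau: i1e(tau) / i0e(tau) - r_bar
    hi = 1.0
    while a(hi) < 0 and hi < 1e8:
        hi *= 2.0
    tau = brentq(a, 0.0, hi, xtol=1e-10) if r_bar > 0 else 0.0
    return nu, tau


def _vonmises_kl(nu1: float, tau1: float, nu2: float, tau2: float) -> float:
    """KL divergence between von Mises distributions (closed form)."""
    log_i0_ratio = (math.log(i0e(tau2)) + tau2) - (math.log(i0e(tau1)) + tau1)
    a1 = i1e(tau1) / i0e(tau1)
    return log_i0_ratio + a1 * (tau1 - tau2 * math.cos(nu2 - nu1))


def _mind_kl(d1: float, d2: float, k: int) -> float:
    """KL divergence between the normalized-distance densities
    g(ρ; d, k) = k d ρ^{d−1} (1−ρ^d)^{k−1}, by numerical quadrature."""

    def log_g(rho, d):
        return (
            math.log(k * d)
            + (d - 1.0) * math.log(rho)
            + (k - 1.0) * math.log1p(-(rho**d))
        )

    def integrand(rho):
        return math.exp(log_g(rho, d1)) * (log_g(rho, d1) - log_g(rho, d2))

    val, _ = quad(integrand, 1e-9, 1.0 - 1e-9, limit=200)
    return val


def _danco_stats(X: np.ndarray, k: int) -> tuple[float, float, float]:
    """(d_hat, nu, tau): continuous MiND-ML dimension of ρ = r1/rk, plus the
    mean von Mises fit of pairwise angles between neighbor directions."""
    m, p = X.shape
    nt = build_neighbor_table(X, k=k)
    rk, r1 = nt.distances[:, -1], nt.distances[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(rk > 0, r1 / rk, np.nan)
    rho = rho[np.isfinite(rho) & (rho > 0) & (rho < 1)]
    if len(rho) == 0:
        raise FloatingPointError("degenerate normalized distances")
    if p == 1:
        d_hat = 1.0
    else:
        res = minimize_scalar(
            lambda d: -mind_loglik(d, rho, k),
            bounds=(1.0, float(max(p, 2))),
            method="bounded",
        )
        d_hat = float(res.x)
    nus, taus = [], []
    iu, ju = np.triu_indices(k, k=1)
    for i in range(m):
        vec = X[nt.indices[i]] - X[i]
        nrm = np.linalg.norm(vec, axis=1)
        good = nrm > 0
        if np.count_nonzero(good) < 2:
            continue
        u = vec[good] / nrm[good, None]
        g = np.clip(u @ u.T, -1.0, 1.0)
        kk = u.shape[0]
        ii, jj = (iu, ju) if kk == k else np.triu_indices(kk, k=1)
        theta = np.arccos(g[ii, jj])
        nu_i, tau_i = _vonmises_fit(theta)
        nus.append(nu_i)
        taus.append(tau_i)
    if not nus:
        raise FloatingPointError("no valid angle statistics")
    return d_hat, float(np.mean(nus)), float(np.mean(taus))


_CALIBRATION_CACHE: dict[tuple, tuple[float, float, float]] = {}


def _calibration_stats(d: int, k: int, n_calib: int, seed: int):
    """Statistics of a seeded uniform sample of the unit d-ball (cached)."""
    key = (d, k, n_calib, seed)
    if key not in _CALIBRATION_CACHE:
        rng = np.random.default_rng(seed + 1_000_003 * d)
        g = rng.standard_normal((n_calib, d))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        radii = rng.random(n_calib) ** (1.0 / d)
        _CALIBRATION_CACHE[key] = _danco_stats(g * radii[:, None], k)
    return _CALIBRATION_CACHE[key]


def danco(
    X,
    k: int = 10,
    D_max: int | None = None,
    n_calib: int = 100,
    seed: int = 0,
    max_rows: int = 10_000,
    max_cols: int = 100,
    force: bool = False,
) -> tuple[float, str, dict]:
    """Dimension by joint norm/angle concentration calibration.

    Measures a MiND-style likelihood statistic on ρ = r1/rk and a von Mises
    fit of pairwise neighbor angles, then compares both against seeded
    uniform d-ball calibration samples for each candidate d, minimizing the
    summed KL divergences.
    """
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    if not force and (m > max_rows or p > max_cols):
        raise ValueError(
            f"DANCo input {m}x{p} exceeds the {max_rows}x{max_cols} cost cap; "
            "reduce the matrix (see bench caps) or pass force=True"
        )
    if m < k + 2:
        raise ValueError(f"DANCo needs at least k+2={k + 2} points")
    d_max = int(D_max) if D_max else p
    try:
        d_data, nu_data, tau_data = _danco_stats(X, k)
    except FloatingPointError:
        return float("nan"), STATUS_DEGENERATE, {}
    kls = {}
    for d in range(1, d_max + 1):
        try:
            d_cal, nu_cal, tau_cal = _calibration_stats(d, k, n_calib, seed)
            kl = _mind_kl(d_data, d_cal, k) + _vonmises_kl(
                nu_data, tau_data, nu_cal, tau_cal
            )
        except (FloatingPointError, ValueError):
            continue
        kls[d] = kl
    info = {"kl": kls, "d_hat": d_data, "nu": nu_data, "tau": tau_data}
    if not kls:
        return float("nan"), STATUS_DEGENERATE, info
    d_star = min(kls, key=lambda d: (kls[d], d))
    return float(d_star), STATUS_OK, info


class DANCo(BaseIDEstimator):
    """Angle- and norm-concentration estimator with seeded calibration."""

    _method_tag = "DANCo"

    def __init__(
        self,
        k: int = 10,
        D_max: int | None = None,
        n_calib: int = 100,
        seed: int = 0,
        force: bool = False,
    ):
        self.k = k
        self.D_max = D_max
        self.n_calib = n_calib
        self.seed = seed
        self.force = force

    def _fit(self, X):
        d, status, self.details_ = danco(
            X,
            k=min(self.k, X.shape[0] - 2),
            D_max=self.D_max,
            n_calib=self.n_calib,
            seed=self.seed,
            force=self.force,
        )
        return d, status
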