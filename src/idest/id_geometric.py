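"""Fractal and nearest-neighbor-distance estimators.

These methods read the intrinsic dimension off how distances between close
points scale: the correlation integral (CorrInt), the Levina–Bickel maximum
likelihood estimator with the MacKay–Ghahramani correction (MLE), the
two-nearest-neighbor ratio estimator (TwoNN), the manifold-adaptive fractal
dimension (MADA), the method of moments (MOM), the tight-locality estimator
(TLE), minimum-neighbor-distance maximum likelihood (MiND_ML), and the
scaling of k-nearest-neighbor graph length with sample size (KNN).

All of them are invariant under rigid motions, and the ratio-based ones are
additionally invariant to uniform scaling of the data.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .base import (
    STATUS_DEGENERATE,
    STATUS_INFINITE,
    STATUS_OK,
    BaseIDEstimator,
    classify_value,
)
from .core import NeighborTable, build_neighbor_table

__all__ = [
    "CorrInt",
    "MLE",
    "TwoNN",
    "MADA",
    "MOM",
    "TLE",
    "MiND_ML",
    "KNN",
    "corrint",
    "mle_id",
    "twonn",
    "mada",
    "mom",
    "tle",
    "mind_ml",
    "knn_graph_id",
    "count_pairs_within",
]


# ---------------------------------------------------------------------------
# correlation (fractal) dimension


def count_pairs_within(X: np.ndarray, r: float, chunk: int = 1024) -> int:
    """Number of unordered pairs (i < j) with Euclidean distance <= r."""
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)
    r2 = r * r
    total = 0
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        within = d2 <= r2
        # count only j > i to get unordered pairs once
        cols = np.arange(m)[None, :]
        rows = np.arange(start, stop)[:, None]
        total += int(np.count_nonzero(within & (cols > rows)))
    return total


def corrint(X, k1: int = 10, k2: int = 20) -> tuple[float, str, dict]:
    """Two-scale correlation-integral slope.

    C(r) = 2/(M(M-1)) * #{pairs within r}; the two radii are the mean
    distances to the k1-th and k2-th neighbors, and
    d = [ln C(r2) - ln C(r1)] / [ln r2 - ln r1].
    """
    if k1 >= k2:
        raise ValueError("k1 must be smaller than k2")
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < k2 + 1:
        raise ValueError(f"need at least k2+1={k2 + 1} points, got {m}")
    nt = build_neighbor_table(X, k=k2)
    r1 = float(nt.distances[:, k1 - 1].mean())
    r2 = float(nt.distances[:, k2 - 1].mean())
    n_pairs = m * (m - 1) / 2
    c1 = count_pairs_within(X, r1) / n_pairs
    c2 = count_pairs_within(X, r2) / n_pairs
    info = {"r1": r1, "r2": r2, "C_r1": c1, "C_r2": c2}
    if r1 <= 0 or r2 <= 0 or r1 == r2 or c1 == 0:
        return float("nan"), STATUS_DEGENERATE, info
    d = (np.log(c2) - np.log(c1)) / (np.log(r2) - np.log(r1))
    return float(d), classify_value(d), info


class CorrInt(BaseIDEstimator):
    """Correlation (fractal) dimension from a two-scale integral slope."""

    _method_tag = "CorrInt"

    def __init__(self, k1: int = 10, k2: int = 20):
        self.k1 = k1
        self.k2 = k2

    def _fit(self, X):
        d, status, self.details_ = corrint(X, k1=self.k1, k2=self.k2)
        return d, status


# ---------------------------------------------------------------------------
# Levina–Bickel MLE


def mle_id(nt: NeighborTable, aggregate: str = "global_mackay") -> tuple[float, str]:
    """Maximum-likelihood dimension from neighbor-distance log-ratios.

    Per point the inverse estimate is m(x) = mean_{j<k} ln(r_k/r_j).
    ``global_mackay`` averages the inverses over all points and log-ratio
    terms before inverting (the MacKay–Ghahramani correction);
    ``mean_of_locals`` averages the per-point estimates 1/m(x).
    """
    if aggregate not in ("global_mackay", "mean_of_locals"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if nt.k < 2:
        raise ValueError("MLE needs k >= 2 neighbors")
    r = nt.distances
    if np.any(r[:, : nt.k] <= 0):
        return float("nan"), STATUS_DEGENERATE
    logs = np.log(r[:, -1][:, None] / r[:, :-1])  # (M, k-1)
    if aggregate == "global_mackay":
        mean_log = logs.mean()
        if mean_log == 0:
            return float("nan"), STATUS_DEGENERATE
        d = 1.0 / mean_log
    else:
        m_x = logs.mean(axis=1)
        valid = m_x > 0
        if not np.any(valid):
            return float("nan"), STATUS_DEGENERATE
        d = float(np.mean(1.0 / m_x[valid]))
    return float(d), classify_value(d)


class MLE(BaseIDEstimator):
    """Levina–Bickel maximum-likelihood estimator (MacKay-corrected)."""

    _method_tag = "MLE"

    def __init__(self, k: int = 20, aggregate: str = "global_mackay"):
        self.k = k
        self.aggregate = aggregate

    def _fit(self, X):
        nt = build_neighbor_table(X, k=min(self.k, X.shape[0] - 1))
        return mle_id(nt, aggregate=self.aggregate)


# ---------------------------------------------------------------------------
# TwoNN


def twonn(
    nt: NeighborTable, discard_fraction: float = 0.1, fit: str = "linear"
) -> tuple[float, str]:
    """Dimension from the ratio of the two smallest neighbor distances.

    μ_i = r2/r1 follows a Pareto law with shape equal to the intrinsic
    dimension; the largest ``discard_fraction`` of the μ are dropped before
    fitting.  ``fit="mle"`` uses d = M'/Σ ln μ; ``fit="linear"`` regresses
    −ln(1 − i/M) on ln μ_(i) through the origin.
    """
    if fit not in ("linear", "mle"):
        raise ValueError(f"unknown fit {fit!r}")
    if not (0 <= discard_fraction < 1):
        raise ValueError("discard_fraction must lie in [0, 1)")
    if nt.k < 2:
        raise ValueError("TwoNN needs k >= 2 neighbors")
    r1, r2 = nt.distances[:, 0], nt.distances[:, 1]
    if np.any(r1 <= 0):
        return float("nan"), STATUS_DEGENERATE
    mu = np.sort(r2 / r1)
    m = len(mu)
    n_drop = int(np.ceil(discard_fraction * m))
    kept = mu[: m - n_drop] if n_drop else mu
    if np.all(kept == 1.0):
        return float("nan"), STATUS_DEGENERATE
    log_mu = np.log(kept)
    if fit == "mle":
        d = len(kept) / log_mu.sum()
    else:
        # empirical CDF with plotting position i/M over the full sample
        f_hat = np.arange(1, len(kept) + 1) / m
        y = -np.log(1.0 - f_hat)
        denom = np.dot(log_mu, log_mu)
        if denom == 0:
            return float("nan"), STATUS_DEGENERATE
        d = float(np.dot(log_mu, y) / denom)
    return float(d), classify_value(d)


class TwoNN(BaseIDEstimator):
    """Two-nearest-neighbor ratio estimator."""

    _method_tag = "TwoNN"

    def __init__(self, discard_fraction: float = 0.1, fit_method: str = "linear"):
        self.discard_fraction = discard_fraction
        self.fit_method = fit_method

    def _fit(self, X):
        nt = build_neighbor_table(X, k=2)
        return twonn(nt, discard_fraction=self.discard_fraction, fit=self.fit_method)


# ---------------------------------------------------------------------------
# MADA


def mada(nt: NeighborTable, aggregate: str = "mean") -> tuple[float, str, dict]:
    """Manifold-adaptive fractal dimension: per point
    d(x) = ln 2 / ln(r_k / r_ceil(k/2)), aggregated over valid points."""
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    k = nt.k
    if k < 2:
        raise ValueError("MADA needs k >= 2 neighbors")
    rk = nt.distances[:, k - 1]
    rh = nt.distances[:, int(np.ceil(k / 2)) - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((rh > 0), rk / rh, np.nan)
        log_ratio = np.log(ratio)
        d_x = np.where(log_ratio > 0, np.log(2.0) / log_ratio, np.nan)
    valid = np.isfinite(d_x)
    info = {"invalid_fraction": float(1.0 - valid.mean()), "per_point": d_x}
    if not np.any(valid):
        return float("nan"), STATUS_DEGENERATE, info
    d = float(np.mean(d_x[valid]) if aggregate == "mean" else np.median(d_x[valid]))
    return d, classify_value(d), info


class MADA(BaseIDEstimator):
    """Manifold-adaptive fractal dimension from a two-radius ratio."""

    _method_tag = "MADA"

    def __init__(self, k: int = 20, aggregate: str = "mean"):
        self.k = k
        self.aggregate = aggregate

    def _fit(self, X):
        nt = build_neighbor_table(X, k=min(self.k, X.shape[0] - 1))
        d, status, self.details_ = mada(nt, aggregate=self.aggregate)
        return d, status


# ---------------------------------------------------------------------------
# method of moments


def mom(nt: NeighborTable) -> tuple[float, str, dict]:
    """Method of moments: per point d = m1/(w − m1) with w the distance to
    the k-th neighbor and m1 the mean of the first k distances."""
    if nt.k < 2:
        raise ValueError("MOM needs k >= 2 neighbors")
    w = nt.distances[:, -1]
    m1 = nt.distances.mean(axis=1)
    denom = w - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        d_x = np.where(denom > 0, m1 / denom, np.nan)
    valid = np.isfinite(d_x)
    info = {"invalid_fraction": float(1.0 - valid.mean()), "per_point": d_x}
    if not np.any(valid):
        return float("nan"), STATUS_DEGENERATE, info
    d = float(np.mean(d_x[valid]))
    return d, classify_value(d), info


class MOM(BaseIDEstimator):
    """Method-of-moments estimator from mean neighbor distances."""

    _method_tag = "MOM"

    def __init__(self, k: int = 20):
        self.k = k

    def _fit(self, X):
        nt = build_neighbor_table(X, k=min(self.k, X.shape[0] - 1))
        d, status, self.details_ = mom(nt)
        return d, status


# ---------------------------------------------------------------------------
# tight-locality estimator (TLE)


def _tle_point(a_dists: np.ndarray, pair_d2: np.ndarray, r: float) -> float:
    """Per-point tight-locality estimate.

    Neighbors live inside the ball B(x, r).  For every ordered pair (v, w)
    of distinct neighbors two distance samples in (0, 1] are formed: the
    distance d(v, w) divided by the chord length from v through w to the
    boundary of the ball, and the same with w reflected through the center
    x.  Both chord lengths follow from the distance triple alone.  The
    estimate is −1 / mean(ln s) over all valid samples.
    """
    k = len(a_dists)
    Di = a_dists[:, None]  # ||v - x||
    Dj = a_dists[None, :]  # ||w - x||
    V2 = pair_d2  # ||v - w||^2
    logs = []
    for reflected in (False, True):
        if reflected:
            # w' = 2x − w: ||v − w'||^2 = 2||v−x||^2 + 2||w−x||^2 − ||v−w||^2
            W2 = 2 * Di**2 + 2 * Dj**2 - V2
            dot = -(3 * Di**2 + Dj**2 - V2) / 2  # <v−x, (w'−x)−(v−x)>
        else:
            W2 = V2
            dot = (Dj**2 - Di**2 - V2) / 2
        W = np.sqrt(np.maximum(W2, 0.0))
        mask = ~np.eye(k, dtype=bool) & (W > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            proj = dot / W  # <v−x, u> with u the unit direction v→w
            disc = np.maximum(proj**2 + r**2 - Di**2, 0.0)
            t = -proj + np.sqrt(disc)  # chord length to the boundary
            s = W / t
        mask &= np.isfinite(s) & (s > 0)
        if np.any(mask):
            logs.append(np.log(np.minimum(s[mask], 1.0)))
    if not logs:
        return float("nan")
    mean_log = np.concatenate(logs).mean()
    if mean_log >= -1e-12:  # all samples at the boundary: ties, not structure
        return float("nan")
    return -1.0 / mean_log


def tle(nt: NeighborTable, X) -> tuple[float, str, dict]:
    """Tight-locality estimator: mean of valid per-point estimates."""
    if nt.k < 3:
        raise ValueError("TLE needs k >= 3 neighbors")
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    values = np.full(m, np.nan)
    for i in range(m):
        r = nt.distances[i, -1]
        if r <= 0:
            continue
        nbrs = X[nt.indices[i]]
        diff = nbrs[:, None, :] - nbrs[None, :, :]
        pair_d2 = np.einsum("ijk,ijk->ij", diff, diff)
        values[i] = _tle_point(nt.distances[i], pair_d2, r)
    valid = np.isfinite(values) & (values > 0)
    info = {"invalid_fraction": float(1.0 - valid.mean()), "per_point": values}
    if not np.any(valid):
        return float("nan"), STATUS_DEGENERATE, info
    d = float(values[valid].mean())
    return d, classify_value(d), info


class TLE(BaseIDEstimator):
    """Tight-locality estimator from chord-normalized pairwise distances."""

    _method_tag = "TLE"

    def __init__(self, k: int = 20):
        self.k = k

    def _fit(self, X):
        nt = build_neighbor_table(X, k=min(self.k, X.shape[0] - 1))
        d, status, self.details_ = tle(nt, X)
        return d, status


# ---------------------------------------------------------------------------
# MiND maximum likelihood


def mind_loglik(d: float, rho: np.ndarray, k: int) -> float:
    """Log-likelihood of the normalized smallest-neighbor distances ρ = r1/rk
    under the minimum-neighbor-distance model in dimension d."""
    with np.errstate(divide="ignore"):
        return float(
            np.sum(
                np.log(k * d)
                + (d - 1.0) * np.log(rho)
                + (k - 1.0) * np.log1p(-(rho**d))
            )
        )


def mind_ml(
    nt: NeighborTable, variant: str = "MLi", D_max: int | None = None
) -> tuple[float, str]:
    """Minimum-neighbor-distance ML estimator.

    ``MLi`` maximizes the likelihood over integer candidate dimensions
    1..D_max; ``MLk`` maximizes it continuously on [1, D_max].
    """
    if variant not in ("MLi", "MLk"):
        raise ValueError(f"unknown variant {variant!r}")
    if nt.k < 2:
        raise ValueError("MiND_ML needs k >= 2 neighbors")
    rk = nt.distances[:, -1]
    r1 = nt.distances[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(rk > 0, r1 / rk, np.nan)
    rho = rho[np.isfinite(rho) & (rho > 0) & (rho < 1)]
    if len(rho) == 0:
        return float("nan"), STATUS_DEGENERATE
    if D_max is None:
        raise ValueError("D_max (candidate-dimension cap) is required")
    d_max = max(int(D_max), 1)
    if variant == "MLi":
        ll = [mind_loglik(d, rho, nt.k) for d in range(1, d_max + 1)]
        d = float(int(np.argmax(ll)) + 1)
    else:
        if d_max == 1:
            return 1.0, STATUS_OK
        res = minimize_scalar(
            lambda d: -mind_loglik(d, rho, nt.k),
            bounds=(1.0, float(d_max)),
            method="bounded",
        )
        d = float(res.x)
    return d, classify_value(d)


class MiND_ML(BaseIDEstimator):
    """Minimum-neighbor-distance maximum-likelihood estimator."""

    def __init__(self, k: int = 10, ver: str = "MLi", D_max: int | None = None):
        self.k = k
        self.ver = ver
        self.D_max = D_max

    @property
    def _method_tag(self) -> str:
        return f"MiND_{self.ver}"

    def _fit(self, X):
        nt = build_neighbor_table(X, k=min(self.k, X.shape[0] - 1))
        d_max = self.D_max if self.D_max is not None else X.shape[1]
        return mind_ml(nt, variant=self.ver, D_max=d_max)


# ---------------------------------------------------------------------------
# kNN-graph length scaling


def knn_graph_length(X: np.ndarray, k: int, gamma: float) -> float:
    """Total edge weight Σ |e|^gamma over the directed kNN graph."""
    nt = build_neighbor_table(X, k=k)
    return float(np.sum(nt.distances**gamma))


def knn_graph_id(
    X,
    k: int = 5,
    gamma: float = 1.0,
    sizes: tuple[int, ...] | None = None,
    n_boot: int = 10,
    seed: int = 0,
    D_max: int | None = None,
) -> tuple[float, str, dict]:
    """Dimension from how kNN-graph length grows with sample size.

    The total graph length of a uniform sample of size n on a d-manifold
    scales as n^{(d−γ)/d}; the log-log slope a of mean length against n
    gives d = γ/(1 − a), rounded and clamped to [1, D_max].
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if sizes is None:
        sizes = tuple(sorted({max(m // 4, k + 2), max(m // 2, k + 3), m}))
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 subsample sizes")
    if any(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if sizes[-1] > m:
        raise ValueError("largest size exceeds the number of points")
    if k >= sizes[0]:
        raise ValueError("k must be smaller than the smallest subsample size")
    rng = np.random.default_rng(seed)
    mean_lengths = []
    for n_q in sizes:
        lengths = []
        for _ in range(n_boot):
            sel = rng.choice(m, size=n_q, replace=False) if n_q < m else np.arange(m)
            lengths.append(knn_graph_length(X[sel], k=k, gamma=gamma))
        mean_lengths.append(np.mean(lengths))
    log_n = np.log(np.asarray(sizes, dtype=float))
    log_l = np.log(np.asarray(mean_lengths))
    a, b = np.polyfit(log_n, log_l, 1)
    info = {"slope": float(a), "intercept": float(b), "sizes": sizes}
    if a >= 1:
        return float("nan"), STATUS_INFINITE, info
    d_max = int(D_max) if D_max is not None else X.shape[1]
    d = float(np.clip(round(gamma / (1.0 - a)), 1, d_max))
    return d, STATUS_OK, info


class KNN(BaseIDEstimator):
    """kNN-graph length-scaling estimator (graph analogue of the minimum
    spanning tree functional)."""

    _method_tag = "KNN"

    def __init__(
        self,
        k: int = 5,
        gamma: float = 1.0,
        sizes: tuple[int, ...] | None = None,
        n_boot: int = 10,
        seed: int = 0,
        D_max: int | None = None,
    ):
        self.k = k
        self.gamma = gamma
        self.sizes = sizes
        self.n_boot = n_boot
        self.seed = seed
        self.D_max = D_max

    def _fit(self, X):
        d_max = self.D_max if self.D_max is not None else X.shape[1]
        d, status, self.details_ = knn_graph_id(
            X,
            k=self.k,
            gamma=self.gamma,
            sizes=self.sizes,
            n_boot=self.n_boot,
            seed=self.seed,
            D_max=d_max,
        )
        return d, status
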