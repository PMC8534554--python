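"""Meta-analysis machinery for running many estimators over many datasets.

Provides batch profiling with per-method size caps, validity accounting,
deterministic chained-regression imputation of failed cells, the consensus
dimension (mean of per-method z-scores), method correlation, PCA of the ID
profiles, redundancy sensitivity under feature duplication, and the
multiplicative wall-clock model Time = c · Nobj^α · Nvar^β.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import STATUS_DEGENERATE, STATUS_OK
from .core import preprocess
from .registry import get_estimator, resolve_tag

__all__ = [
    "ProfileMatrix",
    "ConsensusResult",
    "TimingRecord",
    "TimeModelFit",
    "SensitivityResult",
    "DEFAULT_CAPS",
    "run_profile",
    "impute_profile",
    "consensus_id",
    "method_correlation",
    "redundancy_sensitivity",
    "fit_time_model",
    "uniformity_cv",
]

# Per-method input caps: a bare integer caps rows, a pair caps (rows, cols).
DEFAULT_CAPS: dict[str, int | tuple[int, int]] = {
    "all": 100_000,
    "KNN": 20_000,
    "MADA": 20_000,
    "DANCo": (10_000, 100),
    "ESS": (2_000, 20),
}


@dataclass
class ProfileMatrix:
    """Datasets × methods table of ID estimates with parallel statuses."""

    values: pd.DataFrame
    statuses: pd.DataFrame

    @property
    def datasets(self) -> list[str]:
        return list(self.values.index)

    @property
    def methods(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())


@dataclass
class ConsensusResult:
    """Consensus dimension and PCA of the z-scored profile matrix."""

    zscores: pd.DataFrame
    mean_z: pd.Series
    explained_variance: np.ndarray
    loadings: pd.DataFrame = field(default=None)


@dataclass
class TimingRecord:
    method: str
    n_obj: int
    n_var: int
    seconds: float


@dataclass
class TimeModelFit:
    """Fit of ln t = ln c + α ln Nobj + β ln Nvar."""

    c: float
    alpha: float
    beta: float
    r_squared: float

    def predict(self, n_obj, n_var):
        return self.c * np.asarray(n_obj, float) ** self.alpha * np.asarray(
            n_var, float
        ) ** self.beta


@dataclass
class SensitivityResult:
    method: str
    id_original: float
    id_duplicated: float
    status_original: str
    status_duplicated: str

    @property
    def ratio(self) -> float:
        if self.status_original == STATUS_OK and self.status_duplicated == STATUS_OK:
            return self.id_duplicated / self.id_original
        return float("nan")


def _pca_reduce(X: np.ndarray, n_components: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt[:n_components].T


def apply_caps(X: np.ndarray, method: str, caps: dict, seed: int) -> np.ndarray:
    """Reduce a matrix to a method's cap: rows by seeded subsampling,
    columns by projecting onto leading PCA coordinates."""
    cap = caps.get(resolve_tag(method), caps.get("all"))
    if cap is None:
        return X
    max_rows, max_cols = cap if isinstance(cap, tuple) else (cap, None)
    global_cap = caps.get("all")
    if isinstance(global_cap, int):
        max_rows = min(max_rows, global_cap) if max_rows else global_cap
    if max_cols is not None and X.shape[1] > max_cols:
        X = _pca_reduce(X, max_cols)
    if max_rows is not None and X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[np.sort(rng.choice(X.shape[0], size=max_rows, replace=False))]
    return X


def run_profile(
    collection: dict[str, np.ndarray],
    methods: list[str] | None = None,
    caps: dict | None = None,
    seed: int = 0,
    do_preprocess: bool = True,
) -> ProfileMatrix:
    """Apply a panel of estimators to every dataset of a collection.

    Each matrix is preprocessed (min/max scaling, near-duplicate removal,
    global row cap), then reduced to each method's cap before estimation.
    A failing cell records its status; the batch never aborts.
    """
    from .registry import all_methods

    if methods is None:
        methods = all_methods()
    methods = [resolve_tag(m) for m in methods]
    caps = dict(DEFAULT_CAPS, **(caps or {}))
    names = list(collection)
    values = pd.DataFrame(np.nan, index=names, columns=methods)
    statuses = pd.DataFrame("", index=names, columns=methods)
    for name in names:
        X = np.asarray(collection[name], dtype=float)
        if do_preprocess:
            global_cap = caps.get("all", 100_000)
            try:
                X = preprocess(X, max_rows=global_cap, seed=seed)
            except ValueError:
                statuses.loc[name, :] = STATUS_DEGENERATE
                continue
        for method in methods:
            Xm = apply_caps(X, method, caps, seed=seed)
            est = get_estimator(method, seed=seed)
            try:
                est.fit(Xm)
                values.loc[name, method] = (
                    est.dimension_ if est.status_ == STATUS_OK else np.nan
                )
                statuses.loc[name, method] = est.status_
            except ValueError:
                statuses.loc[name, method] = STATUS_DEGENERATE
    return ProfileMatrix(values=values, statuses=statuses)


def impute_profile(pm: ProfileMatrix, max_iter: int = 100, tol: float = 1e-6) -> ProfileMatrix:
    """Fill missing cells by deterministic chained least-squares regression.

    Missing cells start at their column mean; each incomplete column is then
    repeatedly regressed on all the others over originally-complete rows and
    its missing entries replaced by the prediction, until the largest change
    falls below ``tol``.
    """
    V = pm.values.to_numpy(dtype=float).copy()
    mask = np.isnan(V)
    if mask.all(axis=0).any():
        bad = [pm.methods[j] for j in np.flatnonzero(mask.all(axis=0))]
        raise ValueError(f"cannot impute all-missing method column(s): {bad}")
    if V.shape[1] < 2:
        raise ValueError("imputation needs at least 2 method columns")
    col_means = np.nanmean(V, axis=0)
    V[mask] = np.take(col_means, np.where(mask)[1])
    complete_rows = ~mask.any(axis=1)
    for _ in range(max_iter):
        delta = 0.0
        for j in np.flatnonzero(mask.any(axis=0)):
            others = np.delete(np.arange(V.shape[1]), j)
            rows = complete_rows
            if rows.sum() < 2:  # fall back to all rows under current fill
                rows = np.ones(len(V), dtype=bool)
            A = np.column_stack([np.ones(rows.sum()), V[rows][:, others]])
            coef, *_ = np.linalg.lstsq(A, V[rows, j], rcond=None)
            miss = mask[:, j]
            pred = np.column_stack([np.ones(miss.sum()), V[miss][:, others]]) @ coef
            delta = max(delta, float(np.max(np.abs(V[miss, j] - pred), initial=0.0)))
            V[miss, j] = pred
        if delta < tol:
            break
    out = pd.DataFrame(V, index=pm.datasets, columns=pm.methods)
    return ProfileMatrix(values=out, statuses=pm.statuses.copy())


def consensus_id(pm: ProfileMatrix) -> ConsensusResult:
    """Consensus dimension: mean of per-method z-scores, plus a PCA of the
    z-scored profile matrix (explained-variance fractions and loadings with
    the largest-magnitude loading of each component made positive)."""
    V = pm.values.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("profile matrix has missing cells; impute first")
    if V.shape[0] < 3:
        raise ValueError("consensus needs at least 3 datasets")
    std = V.std(axis=0)
    if np.any(std == 0):
        bad = [pm.methods[j] for j in np.flatnonzero(std == 0)]
        raise ValueError(f"zero-variance method column(s): {bad}")
    Z = (V - V.mean(axis=0)) / std
    mean_z = Z.mean(axis=1)
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    ev = s**2 / np.sum(s**2)
    loadings = vt.T.copy()
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return ConsensusResult(
        zscores=pd.DataFrame(Z, index=pm.datasets, columns=pm.methods),
        mean_z=pd.Series(mean_z, index=pm.datasets, name="mean_z"),
        explained_variance=ev,
        loadings=pd.DataFrame(loadings, index=pm.methods, columns=pcs),
    )


def method_correlation(pm: ProfileMatrix) -> pd.DataFrame:
    """Pearson correlation between methods across datasets."""
    V = pm.values.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("profile matrix has missing cells; impute first")
    if V.shape[0] < 3:
        raise ValueError("correlation needs at least 3 datasets")
    if np.any(V.std(axis=0) == 0):
        bad = [pm.methods[j] for j in np.flatnonzero(V.std(axis=0) == 0)]
        raise ValueError(f"zero-variance method column(s): {bad}")
    corr = np.corrcoef(V, rowvar=False)
    return pd.DataFrame(corr, index=pm.methods, columns=pm.methods)


def redundancy_sensitivity(X, method: str, seed: int = 0, **params) -> SensitivityResult:
    """ID ratio after duplicating every feature: fit on X and on [X X]."""
    X = np.asarray(X, dtype=float)
    dup = np.hstack([X, X])
    results = []
    for mat in (X, dup):
        est = get_estimator(method, seed=seed, **params)
        est.fit(mat)
        results.append((est.dimension_, est.status_))
    return SensitivityResult(
        method=resolve_tag(method),
        id_original=results[0][0],
        id_duplicated=results[1][0],
        status_original=results[0][1],
        status_duplicated=results[1][1],
    )


def fit_time_model(records: list[TimingRecord]) -> TimeModelFit:
    """Least-squares fit of the multiplicative runtime model
    Time = c · Nobj^α · Nvar^β in log space."""
    if len(records) < 3:
        raise ValueError("need at least 3 timing records")
    n_obj = np.array([r.n_obj for r in records], dtype=float)
    n_var = np.array([r.n_var for r in records], dtype=float)
    secs = np.array([r.seconds for r in records], dtype=float)
    if np.any(secs <= 0):
        raise ValueError("timing records must have positive seconds")
    if len(set(n_obj)) < 2 or len(set(n_var)) < 2:
        raise ValueError("need at least 2 distinct Nobj and 2 distinct Nvar")
    A = np.column_stack([np.ones(len(records)), np.log(n_obj), np.log(n_var)])
    y = np.log(secs)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return TimeModelFit(
        c=float(np.exp(coef[0])),
        alpha=float(coef[1]),
        beta=float(coef[2]),
        r_squared=float(r2),
    )


def uniformity_cv(values) -> float:
    """Coefficient of variation (std/mean) of a method's estimates over a
    group of similar datasets — low values mean uniform estimation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0 or v.mean() == 0:
        return float("nan")
    return float(v.std() / v.mean())
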