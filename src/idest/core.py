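"""Core plumbing: exact k-nearest-neighbor tables, covariance spectra,
preprocessing, delimited-text I/O, and the local-estimation driver that
repurposes any global estimator pointwise.

All randomness is controlled by explicit integer seeds; nearest-neighbor
ties are broken by lower row index so results are reproducible and testable
against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.utils.validation import check_array

from .base import STATUS_OK

__all__ = [
    "NeighborTable",
    "LocalIDField",
    "build_neighbor_table",
    "covariance_spectrum",
    "preprocess",
    "estimate_local",
    "read_matrix",
]


@dataclass
class NeighborTable:
    """Sorted k-nearest-neighbor indices and distances, self excluded.

    ``distances[i]`` is non-decreasing; ``indices[i, j]`` is the row index of
    the j-th nearest neighbor of point i.  ``has_duplicates`` flags zero
    distances so downstream estimators can declare degenerate input.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray

    @property
    def n_points(self) -> int:
        return self.indices.shape[0]

    @property
    def has_duplicates(self) -> bool:
        return bool(np.any(self.distances == 0.0))


@dataclass
class LocalIDField:
    """Per-point local intrinsic-dimension estimates.

    ``values[i]`` is NaN when ``statuses[i] != "ok"``; failures are recorded,
    never silently dropped.
    """

    method: str
    k: int
    values: np.ndarray
    statuses: list[str] = field(default_factory=list)

    def to_frame(self, row_ids=None) -> pd.DataFrame:
        ids = row_ids if row_ids is not None else np.arange(len(self.values))
        return pd.DataFrame(
            {"row_id": ids, "local_id": self.values, "status": self.statuses}
        )


def build_neighbor_table(X, k: int, metric: str = "euclidean", chunk: int = 512) -> NeighborTable:
    """Exact k nearest neighbors under the Euclidean metric.

    Distances are computed by chunked brute force and sorted with a stable
    sort, so ties are deterministically broken by lower row index.  The point
    itself is never its own neighbor.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric: {metric!r}")
    X = check_array(X, dtype=float)
    m = X.shape[0]
    if not (1 <= k <= m - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n_samples-1, got k={k}, n={m}")
    sq = np.einsum("ij,ij->i", X, X)
    indices = np.empty((m, k), dtype=np.intp)
    distances = np.empty((m, k), dtype=float)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        # squared distances from the chunk to all points
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        distances[start:stop] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighborTable(k=k, indices=indices, distances=distances)


def covariance_spectrum(X, clamp_rtol: float = 1e-12) -> np.ndarray:
    """Eigenvalues of the sample covariance (1/(M-1) normalization).

    Returned sorted non-increasing, padded with zeros to the ambient
    dimension; values below ``clamp_rtol * lambda_1`` are clamped to 0.
    Computed through the SVD of the centered matrix, which is
    cheaper and more stable than forming the covariance when p is large.
    """
    X = check_array(X, ensure_min_samples=2, dtype=float)
    m, p = X.shape
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    lam = np.zeros(p)
    lam[: len(s)] = s**2 / (m - 1)
    if lam[0] > 0:
        lam[lam < clamp_rtol * lam[0]] = 0.0
    return lam


def _dedup_axis(X: np.ndarray, tol: float, axis: int) -> np.ndarray:
    """Indices (in original order) of rows (axis=0) or columns (axis=1) kept
    after removing entries whose Chebyshev distance to an earlier kept entry
    is <= tol.  First occurrence wins."""
    A = X if axis == 0 else X.T
    n = A.shape[0]
    keep: list[int] = []
    kept_rows: list[np.ndarray] = []
    for i in range(n):
        if kept_rows:
            K = np.asarray(kept_rows)
            if np.any(np.max(np.abs(K - A[i]), axis=1) <= tol):
                continue
        keep.append(i)
        kept_rows.append(A[i])
    return np.asarray(keep, dtype=np.intp)


def preprocess(
    X,
    scale: bool = True,
    dedup_tol: float = 1e-8,
    max_rows: int = 100_000,
    seed: int = 0,
):
    """Standard preparation of a raw data matrix before estimation.

    Applies, in order: per-feature min/max scaling to [0, 1] (constant
    features map to 0), removal of approximately duplicated columns and rows
    (max absolute difference <= ``dedup_tol`` to an earlier one, first kept),
    and a seeded uniform subsample to at most ``max_rows`` rows.
    """
    X = check_array(X, ensure_min_samples=2, dtype=float)
    if scale:
        lo = X.min(axis=0)
        rng_span = X.max(axis=0) - lo
        span = np.where(rng_span > 0, rng_span, 1.0)
        X = (X - lo) / span
        X[:, rng_span == 0] = 0.0
    cols = _dedup_axis(X, dedup_tol, axis=1)
    X = X[:, cols]
    rows = _dedup_axis(X, dedup_tol, axis=0)
    if len(rows) < 2:
        raise ValueError("fewer than 2 distinct rows remain after deduplication")
    X = X[rows]
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(X.shape[0], size=max_rows, replace=False))
        X = X[sel]
    return X


def estimate_local(estimator, X, k: int) -> LocalIDField:
    """Apply a global estimator to each point's k-nearest-neighbor sub-cloud.

    For every point the estimator is fitted on the sub-cloud made of the
    point and its ``k`` nearest neighbors; invalid per-point results carry a
    status rather than a silent NaN.

    Parameters
    ----------
    estimator : BaseIDEstimator or str
        A fitted-or-not estimator instance, or a registered method tag.
    X : array-like of shape (M, p)
    k : int
        Neighborhood size; ``k + 1 <= M`` required.
    """
    from .registry import get_estimator

    if isinstance(estimator, str):
        estimator = get_estimator(estimator)
    X = check_array(X, dtype=float)
    m = X.shape[0]
    if k + 1 > m:
        raise ValueError(f"k+1={k + 1} exceeds number of points {m}")
    nt = build_neighbor_table(X, k=k)
    est = clone(estimator)
    values = np.full(m, np.nan)
    statuses: list[str] = []
    for i in range(m):
        sub = X[np.concatenate(([i], nt.indices[i]))]
        est.fit(sub)
        statuses.append(est.status_)
        if est.status_ == STATUS_OK:
            values[i] = est.dimension_
    tag = getattr(est, "_method_tag", type(est).__name__)
    return LocalIDField(method=tag, k=k, values=values, statuses=statuses)


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_matrix(path, delimiter: str | None = None, header: str = "infer",
                row_ids: bool | str = "infer") -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Read a dense numeric matrix from delimited text (CSV/TSV).

    Returns ``(values, feature_names, row_ids)``; names are None when the
    file has no header row / row-name column.  The row-name column is
    auto-detected as a non-numeric first column when ``row_ids="infer"``.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    if header == "infer":
        with open(path) as fh:
            fields = fh.readline().rstrip("\n").split(delimiter)
        trailing = fields[1:] if len(fields) > 1 else fields
        header = 0 if any(not _is_number(f) for f in trailing) else None
    df = pd.read_csv(path, sep=delimiter, header=header)
    df.columns = [str(c) for c in df.columns]
    ids = None
    first = df.columns[0]
    if row_ids is True or (
        row_ids == "infer" and not pd.api.types.is_numeric_dtype(df[first])
    ):
        ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    values = df.to_numpy(dtype=float)
    names = [str(c) for c in df.columns]
    return values, names, ids
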