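"""Shared estimator machinery: result records, validity statuses, base class.

Every estimator in this package reports its result as an :class:`IDEstimate`
carrying an explicit validity status instead of a bare NaN.  The categories
mirror the failure modes observed when running many intrinsic-dimension
methods over heterogeneous data: a method can emit NaN, a negative value,
an infinite value, or refuse a degenerate input (duplicate points, constant
matrices) outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

STATUS_OK = "ok"
STATUS_NAN = "invalid_nan"
STATUS_NEGATIVE = "invalid_negative"
STATUS_INFINITE = "invalid_infinite"
STATUS_DEGENERATE = "degenerate_input"

STATUSES = (STATUS_OK, STATUS_NAN, STATUS_NEGATIVE, STATUS_INFINITE, STATUS_DEGENERATE)


@dataclass
class IDEstimate:
    """A single intrinsic-dimension estimate with validity accounting.

    Attributes
    ----------
    method : str
        Short method tag (e.g. ``"MLE"``, ``"lPCA_FO"``).
    value : float
        The estimate; NaN whenever ``status != "ok"``.
    status : str
        One of :data:`STATUSES`.  ``status == "ok"`` iff ``value`` is a
        positive finite number.
    params : dict
        Estimator parameters used for the run.
    n_used : int
        Number of observations actually consumed (after caps/subsampling).
    """

    method: str
    value: float
    status: str
    params: dict[str, Any] = field(default_factory=dict)
    n_used: int = 0

    def __post_init__(self) -> None:
        ok = np.isfinite(self.value) and self.value > 0
        if (self.status == STATUS_OK) != ok:
            raise ValueError(
                f"inconsistent estimate: value={self.value!r}, status={self.status!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        value = float(self.value) if np.isfinite(self.value) else None
        return {
            "method": self.method,
            "value": value,
            "status": self.status,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "n_used": int(self.n_used),
        }


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def classify_value(value: float) -> str:
    """Map a raw numeric result onto a validity status."""
    if value is None or np.isnan(value):
        return STATUS_NAN
    if np.isinf(value):
        return STATUS_INFINITE
    if value <= 0:
        return STATUS_NEGATIVE
    return STATUS_OK


class BaseIDEstimator(BaseEstimator):
    """Base class for all intrinsic-dimension estimators.

    Subclasses implement ``_fit(X)`` returning ``(value, status)`` (status
    may be ``None`` to classify from the value) and set ``_method_tag``.
    After ``fit`` the instance exposes:

    - ``dimension_`` : the estimate (NaN when invalid),
    - ``status_`` : validity status string,
    - ``n_used_`` : rows consumed.
    """

    _method_tag = "base"

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_all_finite=True, dtype=float)
        value, status = self._fit(X)
        if status is None:
            status = classify_value(value)
        if status != STATUS_OK:
            value = float("nan")
        self.dimension_ = float(value)
        self.status_ = status
        if not hasattr(self, "n_used_"):
            self.n_used_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        return self

    def _fit(self, X: np.ndarray) -> tuple[float, str | None]:  # pragma: no cover
        raise NotImplementedError

    @property
    def estimate_(self) -> IDEstimate:
        check_is_fitted(self, "dimension_")
        return IDEstimate(
            method=self._method_tag,
            value=self.dimension_ if self.status_ == STATUS_OK else float("nan"),
            status=self.status_,
            params=self.get_params(),
            n_used=self.n_used_,
        )

    def fit_estimate(self, X) -> IDEstimate:
        """Fit and return the :class:`IDEstimate` record in one call."""
        return self.fit(X).estimate_
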