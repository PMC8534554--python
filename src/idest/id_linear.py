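"""Eigenvalue-spectrum ("linear" / PCA) dimension criteria.

Seven classical rules that read an intrinsic dimension off the non-increasing
covariance eigenvalues λ1 ≥ λ2 ≥ … ≥ λp: Fukunaga–Olsen thresholding, the
Fan ratio/cumulative rule, the largest consecutive-ratio gap, the cumulative
explained-variance ratio, the participation ratio, the Kaiser rule, and the
broken-stick model.  All are invariant to multiplying the spectrum by a
positive constant.
"""

from __future__ import annotations

import numpy as np

from .base import (
    STATUS_DEGENERATE,
    STATUS_OK,
    BaseIDEstimator,
)
from .core import covariance_spectrum

__all__ = ["lPCA", "pca_dimension", "PCA_VARIANTS"]

PCA_VARIANTS = (
    "FO",
    "Fan",
    "maxgap",
    "ratio",
    "participation_ratio",
    "Kaiser",
    "broken_stick",
)


def _consecutive_ratios(lam: np.ndarray) -> np.ndarray:
    """λi/λi+1 for i = 1..p-1, with λi/0 = +inf when λi > 0 and 1 when both
    vanish — so a hard rank boundary always dominates the gap search."""
    num, den = lam[:-1], lam[1:]
    out = np.empty(len(lam) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    out[:] = np.where(den > 0, ratio, np.where(num > 0, np.inf, 1.0))
    return out


def pca_dimension(
    lambdas,
    variant: str = "FO",
    alpha_FO: float = 0.05,
    fan_ratio_R: float = 10.0,
    fan_cum_C: float = 0.8,
    ratio_tau: float = 0.95,
    round_pr: bool = False,
) -> tuple[float, str]:
    """Apply one spectral dimension criterion to an eigenvalue spectrum.

    Returns ``(dimension, status)``.  The spectrum must be non-negative and
    non-increasing; an all-zero spectrum is degenerate input.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.ndim != 1 or len(lam) == 0:
        raise ValueError("spectrum must be a 1-D sequence of eigenvalues")
    if np.any(lam < 0) or np.any(np.diff(lam) > 0):
        raise ValueError("spectrum must be non-negative and non-increasing")
    if variant not in PCA_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {PCA_VARIANTS}")
    total = lam.sum()
    if total == 0:
        return float("nan"), STATUS_DEGENERATE
    p = len(lam)
    p_nz = int(np.count_nonzero(lam))
    ell = lam / total

    if variant == "participation_ratio":
        d = float(np.clip(total**2 / np.sum(lam**2), 1.0, p))
        return (float(round(d)) if round_pr else d), STATUS_OK
    if variant == "FO":
        return float(np.count_nonzero(lam / lam[0] > alpha_FO)), STATUS_OK
    if variant == "Kaiser":
        # ties at the mean excluded; a flat spectrum still reports 1
        return float(max(np.count_nonzero(lam > lam.mean()), 1)), STATUS_OK
    if variant == "ratio":
        cum = np.cumsum(ell)
        return float(np.argmax(cum >= ratio_tau) + 1), STATUS_OK
    if variant == "broken_stick":
        # b_i = (1/p) * sum_{j=i..p} 1/j — expected proportions from a random
        # division of unit total variance
        b = np.cumsum(1.0 / np.arange(p, 0, -1))[::-1] / p
        above = ell > b
        d = int(np.argmin(above)) if not above.all() else p
        return float(max(d, 1)), STATUS_OK
    if p_nz == 1 or p == 1:
        # ratio-based rules on a rank-1 spectrum
        return 1.0, STATUS_OK
    ratios = _consecutive_ratios(lam)
    if variant == "maxgap":
        return float(int(np.argmax(ratios)) + 1), STATUS_OK
    # Fan: smallest i with (λi/λi+1 > R) and (cumulative proportion >= C);
    # if no index qualifies, the number of nonzero eigenvalues.
    cum = np.cumsum(ell)
    hits = np.flatnonzero((ratios > fan_ratio_R) & (cum[:-1] >= fan_cum_C))
    d = int(hits[0]) + 1 if len(hits) else p_nz
    return float(d), STATUS_OK


class lPCA(BaseIDEstimator):
    """Intrinsic dimension from the covariance eigenvalue spectrum.

    Parameters
    ----------
    ver : str
        One of ``FO`` (count eigenvalues above ``alpha_FO`` relative to the
        largest), ``Fan`` (ratio-and-cumulative stopping rule), ``maxgap``
        (largest consecutive eigenvalue ratio), ``ratio`` (cumulative
        explained variance >= ``ratio_tau``), ``participation_ratio``
        ((Σλ)²/Σλ², continuous), ``Kaiser`` (eigenvalues above the mean),
        ``broken_stick`` (initial run above the broken-stick proportions).
    """

    def __init__(
        self,
        ver: str = "FO",
        alpha_FO: float = 0.05,
        fan_ratio_R: float = 10.0,
        fan_cum_C: float = 0.8,
        ratio_tau: float = 0.95,
        round_pr: bool = False,
    ):
        self.ver = ver
        self.alpha_FO = alpha_FO
        self.fan_ratio_R = fan_ratio_R
        self.fan_cum_C = fan_cum_C
        self.ratio_tau = ratio_tau
        self.round_pr = round_pr

    @property
    def _method_tag(self) -> str:
        short = {
            "FO": "lPCA_FO",
            "Fan": "lPCA_Fan",
            "maxgap": "lPCA_maxgap",
            "ratio": "lPCA_ratio",
            "participation_ratio": "lPCA_PR",
            "Kaiser": "lPCA_Kaiser",
            "broken_stick": "lPCA_BS",
        }
        return short.get(self.ver, f"lPCA_{self.ver}")

    def _fit(self, X):
        if not (0 < self.alpha_FO < 1):
            raise ValueError("alpha_FO must lie in (0, 1)")
        if self.fan_ratio_R <= 1:
            raise ValueError("fan_ratio_R must exceed 1")
        if not (0 < self.fan_cum_C < 1) or not (0 < self.ratio_tau < 1):
            raise ValueError("fan_cum_C and ratio_tau must lie in (0, 1)")
        lam = covariance_spectrum(X)
        self.spectrum_ = lam
        return pca_dimension(
            lam,
            variant=self.ver,
            alpha_FO=self.alpha_FO,
            fan_ratio_R=self.fan_ratio_R,
            fan_cum_C=self.fan_cum_C,
            ratio_tau=self.ratio_tau,
            round_pr=self.round_pr,
        )
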