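"""idest: global and local intrinsic dimension estimation.

A uniform, scikit-learn-style collection of intrinsic-dimension estimators
(spectral, fractal/nearest-neighbor and concentration-of-measure families),
seeded synthetic benchmark manifolds, and a meta-analysis layer (batch
profiling, consensus dimension, redundancy sensitivity, runtime model).
"""

from . import bench, core, datasets
from .base import IDEstimate, STATUSES
from .core import (
    build_neighbor_table,
    covariance_spectrum,
    estimate_local,
    preprocess,
    read_matrix,
)
from .id_concentration import DANCo, ESS, FisherS
from .id_geometric import KNN, MADA, MLE, MOM, TLE, CorrInt, MiND_ML, TwoNN
from .id_linear import lPCA
from .registry import all_methods, get_estimator

__version__ = "0.1.0"

__all__ = [
    "IDEstimate",
    "STATUSES",
    "build_neighbor_table",
    "covariance_spectrum",
    "estimate_local",
    "preprocess",
    "read_matrix",
    "lPCA",
    "CorrInt",
    "MLE",
    "TwoNN",
    "MADA",
    "MOM",
    "TLE",
    "MiND_ML",
    "KNN",
    "FisherS",
    "ESS",
    "DANCo",
    "get_estimator",
    "all_methods",
    "estimate",
    "datasets",
    "bench",
    "core",
]


def estimate(X, method: str = "MLE", **params) -> IDEstimate:
    """One-call global intrinsic dimension estimate.

    >>> import idest
    >>> ball = idest.datasets.generate("hyperball", 1000, {"d": 2}, seed=0)
    >>> idest.estimate(ball.points, "MLE").value  # doctest: +SKIP
    2.0...
    """
    return get_estimator(method, **params).fit_estimate(X)
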