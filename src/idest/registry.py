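"""Method registry: the 19 estimator tags and their default configurations.

Long tags (``lPCA_FO``, ``MLE``, ``MiND_MLi`` …) and the short two/three
letter aliases (``PFO``, ``MMi`` …) both resolve; ``all_methods()`` lists
the canonical 19-method panel used by the batch profiler.
"""

from __future__ import annotations

from .base import BaseIDEstimator
from .id_concentration import DANCo, ESS, FisherS
from .id_geometric import KNN, MADA, MLE, MOM, TLE, CorrInt, MiND_ML, TwoNN
from .id_linear import lPCA

__all__ = ["get_estimator", "all_methods", "METHOD_ALIASES"]

_FACTORIES = {
    "lPCA_FO": lambda: lPCA(ver="FO"),
    "lPCA_Fan": lambda: lPCA(ver="Fan"),
    "lPCA_maxgap": lambda: lPCA(ver="maxgap"),
    "lPCA_ratio": lambda: lPCA(ver="ratio"),
    "lPCA_PR": lambda: lPCA(ver="participation_ratio"),
    "lPCA_Kaiser": lambda: lPCA(ver="Kaiser"),
    "lPCA_BS": lambda: lPCA(ver="broken_stick"),
    "CorrInt": CorrInt,
    "FisherS": FisherS,
    "KNN": KNN,
    "MADA": MADA,
    "MiND_MLi": lambda: MiND_ML(ver="MLi"),
    "MiND_MLk": lambda: MiND_ML(ver="MLk"),
    "MLE": MLE,
    "MOM": MOM,
    "TLE": TLE,
    "TwoNN": TwoNN,
    "DANCo": DANCo,
    "ESS": ESS,
}

METHOD_ALIASES = {
    "PFO": "lPCA_FO",
    "PFN": "lPCA_Fan",
    "PMG": "lPCA_maxgap",
    "PRT": "lPCA_ratio",
    "PPR": "lPCA_PR",
    "PKS": "lPCA_Kaiser",
    "PBS": "lPCA_BS",
    "CID": "CorrInt",
    "FSH": "FisherS",
    "MDA": "MADA",
    "MMi": "MiND_MLi",
    "MMk": "MiND_MLk",
    "TNN": "TwoNN",
    "DNC": "DANCo",
}


def resolve_tag(method: str) -> str:
    tag = METHOD_ALIASES.get(method, method)
    if tag not in _FACTORIES:
        raise ValueError(f"unknown method {method!r}; known: {sorted(_FACTORIES)}")
    return tag


def get_estimator(method: str, **params) -> BaseIDEstimator:
    """Instantiate the estimator behind a method tag (aliases accepted)."""
    est = _FACTORIES[resolve_tag(method)]()
    if params:
        valid = est.get_params()
        est.set_params(**{k: v for k, v in params.items() if k in valid})
    return est


def all_methods() -> list[str]:
    """Canonical ordering of the 19-method panel."""
    return list(_FACTORIES)
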