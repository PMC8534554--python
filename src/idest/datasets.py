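"""Seeded generators of synthetic manifolds with known intrinsic dimension.

Every generator draws from ``numpy.random.default_rng(seed)`` so that equal
arguments give byte-identical samples.  The registry covers the standard
benchmark shapes — uniform balls, sphere surfaces, cubes, Gaussians, the
swiss roll, a Möbius band, a helix, smooth nonlinear embeddings, affine
subspaces — plus the Line–Disk–Ball mixture whose segments have local
intrinsic dimension 1, 2 and 3.  Additional maps can be registered through
:data:`MANIFOLDS`; each entry returns points, the intrinsic dimension and
optional per-point labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ManifoldSample", "MANIFOLDS", "generate", "line_disk_ball"]


@dataclass
class ManifoldSample:
    """A generated point cloud with its ground-truth dimension."""

    name: str
    points: np.ndarray
    intrinsic_dim: int | tuple[int, ...]
    ambient_dim: int
    seed: int
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i}": self.points[:, i] for i in range(self.points.shape[1])}
        df = pd.DataFrame(cols)
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _ball(rng, n, d=2, radius=1.0):
    g = rng.standard_normal((n, d))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / d)
    return g * r[:, None], d


def _sphere(rng, n, d=2):
    g = rng.standard_normal((n, d + 1))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g, d


def _gaussian(rng, n, d=2, sigma=1.0):
    return sigma * rng.standard_normal((n, d)), d


def _cube(rng, n, d=2):
    return rng.random((n, d)), d


def _swiss_roll(rng, n):
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.random(n))
    y = 21.0 * rng.random(n)
    pts = np.column_stack([t * np.cos(t), y, t * np.sin(t)])
    return pts, 2


def _moebius(rng, n):
    theta = 2.0 * np.pi * rng.random(n)
    w = rng.uniform(-1.0, 1.0, n)
    rad = 1.0 + 0.5 * w * np.cos(theta / 2.0)
    pts = np.column_stack(
        [rad * np.cos(theta), rad * np.sin(theta), 0.5 * w * np.sin(theta / 2.0)]
    )
    return pts, 2


def _helix(rng, n, turns=2.0, pitch=0.3):
    t = 2.0 * np.pi * turns * rng.random(n)
    return np.column_stack([np.cos(t), np.sin(t), pitch * t]), 1


def _orthonormal(rng, rows, cols):
    q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q


def _nonlinear_sphere_embedding(rng, n, d=2, D=10):
    if d >= D:
        raise ValueError("latent dimension d must be smaller than ambient D")
    latent, _ = _sphere(rng, n, d)
    w = _orthonormal(rng, D, d + 1)
    return np.tanh(2.0 * latent @ w.T), d


def _affine_subspace(rng, n, d=2, D=10, whiten=False):
    if d > D:
        raise ValueError("latent dimension d must not exceed ambient D")
    latent = rng.uniform(-1.0, 1.0, (n, d))
    if whiten:
        # make the sample covariance exactly the identity
        latent -= latent.mean(axis=0)
        u, s, vt = np.linalg.svd(latent, full_matrices=False)
        latent = u @ vt * np.sqrt(n - 1)
    w = _orthonormal(rng, D, d)
    offset = rng.standard_normal(D)
    return latent @ w.T + offset, d


MANIFOLDS = {
    "hyperball": _ball,
    "hypersphere": _sphere,
    "gaussian": _gaussian,
    "hypercube": _cube,
    "swiss_roll": _swiss_roll,
    "moebius": _moebius,
    "helix": _helix,
    "nonlinear_sphere_embedding": _nonlinear_sphere_embedding,
    "affine_subspace": _affine_subspace,
}


def generate(name: str, n: int, params: dict | None = None, seed: int = 0) -> ManifoldSample:
    """Generate ``n`` points of a registered manifold.

    ``params`` are passed to the registry function (e.g. ``{"d": 3}`` for a
    3-ball).  Identical arguments always produce identical samples.
    """
    if name == "line_disk_ball":
        p = dict(params or {})
        return line_disk_ball(p.pop("n_per_segment", (n // 3,) * 3), seed=seed)
    if name not in MANIFOLDS:
        raise ValueError(f"unknown manifold {name!r}; known: {sorted(MANIFOLDS)}")
    rng = np.random.default_rng(seed)
    pts, d = MANIFOLDS[name](rng, n, **(params or {}))
    return ManifoldSample(
        name=name,
        points=pts,
        intrinsic_dim=d,
        ambient_dim=pts.shape[1],
        seed=seed,
    )


def line_disk_ball(n_per_segment=(1000, 1000, 1000), seed: int = 0) -> ManifoldSample:
    """A 1-D segment, a 2-D disk and a 3-D ball placed disjointly in 3-D.

    The three pieces have local intrinsic dimension 1, 2 and 3 and sit far
    enough apart that k-nearest-neighbor neighborhoods of the default sizes
    never span two segments; per-point labels name the segment.
    """
    n_line, n_disk, n_ball = (int(v) for v in n_per_segment)
    if min(n_line, n_disk, n_ball) < 1:
        raise ValueError("each segment needs at least one point")
    rng = np.random.default_rng(seed)
    line = np.zeros((n_line, 3))
    line[:, 0] = rng.random(n_line)
    disk2, _ = _ball(rng, n_disk, d=2)
    disk = np.column_stack([disk2[:, 0] + 4.0, disk2[:, 1], np.zeros(n_disk)])
    ball, _ = _ball(rng, n_ball, d=3)
    ball = ball + np.array([8.0, 0.0, 0.0])
    pts = np.vstack([line, disk, ball])
    labels = np.array(["line"] * n_line + ["disk"] * n_disk + ["ball"] * n_ball)
    return ManifoldSample(
        name="line_disk_ball",
        points=pts,
        intrinsic_dim=(1, 2, 3),
        ambient_dim=3,
        seed=seed,
        labels=labels,
    )
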