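"""2D embedding of enriched terms by metric MDS on semantic distances.

Distances are the simplest monotone transform of similarity, d = 1 - sim.
The embedding is classical (Torgerson) MDS refined by seeded SMACOF, then
min-max scaled per axis to the unit square — the coordinates consumers
multiply by their canvas size. An axis with zero spread collapses to 0.5.

An optional deterministic jitter can separate exactly coincident points
(a stand-in for force-directed dispersal in interactive viewers); it is off
by default and never moves points out of the unit square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.manifold import smacof

from .semsim import SimilarityMatrix

__all__ = ["Embedding", "mds_embed", "jitter_coincident"]


@dataclass(frozen=True)
class Embedding:
    terms: tuple[str, ...]
    coords: np.ndarray  # (n, 2), each axis min-max scaled to [0, 1]
    raw_coords: np.ndarray  # (n, 2) MDS solution before scaling

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.terms), 2):
            raise ValueError("coords must be (n_terms, 2)")
        object.__setattr__(self, "coords", c)


def _classical_mds(d: np.ndarray) -> np.ndarray:
    """Torgerson double-centering; exact for Euclidean-embeddable input."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    w, v = eigh(b)
    # top-2 components, clipped at zero for non-Euclidean directions
    w2 = np.clip(w[-2:][::-1], 0.0, None)
    y = v[:, -2:][:, ::-1] * np.sqrt(w2)
    # fix reflection signs so output is deterministic
    for ax in range(2):
        col = y[:, ax]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            y[:, ax] = -col
    return y


def _minmax_unit_square(y: np.ndarray) -> np.ndarray:
    out = np.empty_like(y)
    # an axis whose spread is numerical noise (e.g. a collinear layout)
    # collapses to the center instead of amplifying the noise to [0, 1]
    tol = 1e-8 * max(1.0, float(np.abs(y).max(initial=0.0)))
    for ax in range(y.shape[1]):
        lo, hi = y[:, ax].min(), y[:, ax].max()
        out[:, ax] = 0.5 if hi - lo <= tol else (y[:, ax] - lo) / (hi - lo)
    return out


def mds_embed(sim: SimilarityMatrix, seed: int = 0) -> Embedding:
    """Embed the terms of ``sim`` into the unit square.

    Classical MDS provides the start; SMACOF (metric stress majorization,
    seeded) polishes it. Identical similarity rows yield identical
    coordinates; a fully degenerate (all-equal) distance matrix falls back
    to the deterministic classical solution.
    """
    n = len(sim.terms)
    if n < 2:
        raise ValueError("embedding needs at least 2 terms")
    d = 1.0 - np.asarray(sim.values, dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)

    y0 = _classical_mds(d)
    if np.allclose(d, 0.0):
        raw = y0  # all points coincide; nothing to majorize
    else:
        raw, _ = smacof(
            d,
            n_components=2,
            init=y0,
            n_init=1,
            metric=True,
            random_state=int(seed),
        )
    return Embedding(
        terms=sim.terms, coords=_minmax_unit_square(raw), raw_coords=raw
    )


def jitter_coincident(
    emb: Embedding, eps: float = 1e-3, seed: int = 0
) -> Embedding:
    """Separate exactly coincident points by ``eps`` along seeded directions.

    Deterministic given the seed; results are clipped to the unit square.
    """
    rng = np.random.default_rng(int(seed))
    coords = emb.coords.copy()
    seen: dict[tuple[float, float], int] = {}
    for i in range(coords.shape[0]):
        key = (float(coords[i, 0]), float(coords[i, 1]))
        dup = seen.get(key, 0)
        if dup:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            coords[i] += dup * eps * np.array([np.cos(theta), np.sin(theta)])
        seen[key] = dup + 1
    coords = np.clip(coords, 0.0, 1.0)
    return Embedding(terms=emb.terms, coords=coords, raw_coords=emb.raw_coords)
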