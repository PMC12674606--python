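"""Gaussian random projections, feature fusion and distance preservation.

A random projection maps an n × d data matrix X to Y = X·R with a random
d × k matrix R whose entries are i.i.d. N(0, 1/k).  With this variance the
projection approximately preserves pairwise Euclidean distances
(Johnson–Lindenstrauss): E‖xR‖² = ‖x‖².  The classifier builds m independent
projections and fuses them by column-wise concatenation into an n × (m·k)
feature block; the distance-preservation harness quantifies geometric
fidelity of any reduced representation via the Pearson correlation of
pairwise-distance vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .preprocess import ExpressionMatrix

logger = logging.getLogger("rpslearner")


@dataclass
class RPMatrix:
    """One d × k Gaussian projection matrix, fully determined by its seed."""

    entries: np.ndarray
    d: int
    k: int
    seed: int

    def __post_init__(self) -> None:
        if self.entries.shape != (self.d, self.k):
            raise ValueError(f"entries shape {self.entries.shape} != ({self.d}, {self.k})")


@dataclass
class FusedFeatures:
    """n × (m·k) concatenation of m independent k-dimensional projections."""

    values: np.ndarray
    m: int
    k: int
    source_seeds: list[int]

    @property
    def block_boundaries(self) -> list[tuple[int, int]]:
        """Column index range (start, stop) for each source projection."""
        return [(i * self.k, (i + 1) * self.k) for i in range(self.m)]

    def block(self, i: int) -> np.ndarray:
        lo, hi = self.block_boundaries[i]
        return self.values[:, lo:hi]


def make_rp_matrix(d: int, k: int, seed: int) -> RPMatrix:
    """Draw a d × k matrix with i.i.d. N(0, 1/k) entries, deterministic in seed.

    k < d is the intended use; k >= d is allowed with a warning since it no
    longer reduces dimension.
    """
    if d < 1 or k < 1:
        raise ValueError(f"d and k must be positive, got d={d}, k={k}")
    if k >= d:
        warnings.warn(f"k={k} >= d={d}: projection does not reduce dimensionality")
    rng = np.random.default_rng(seed)
    entries = rng.normal(loc=0.0, scale=1.0 / np.sqrt(k), size=(d, k))
    return RPMatrix(entries=entries, d=d, k=k, seed=seed)


def project(X, R: RPMatrix) -> np.ndarray:
    """Exact matrix product X·R; accepts an ExpressionMatrix or an ndarray."""
    vals = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if vals.ndim == 1:
        vals = vals[None, :]
    if vals.shape[1] != R.d:
        raise ValueError(
            f"dimension mismatch: data has {vals.shape[1]} columns "
            f"but RP matrix is {R.d} x {R.k}"
        )
    return vals @ R.entries


def fuse_projections(X, k: int, m: int, base_seed: int) -> FusedFeatures:
    """Project X with m independent RP matrices (seeds base_seed..base_seed+m-1)
    and concatenate the projections column-wise in seed order."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    vals = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    d = vals.shape[1]
    seeds = [base_seed + i for i in range(m)]
    blocks = [project(vals, make_rp_matrix(d, k, s)) for s in seeds]
    return FusedFeatures(values=np.hstack(blocks), m=m, k=k, source_seeds=seeds)


def distance_preservation_score(A, B, return_distances: bool = False):
    """Pearson correlation between pairwise-distance vectors of A and B.

    Computes the n(n-1)/2 pairwise Euclidean distances within A and within B
    (same (i<j) row-major pair order) and correlates them.  Returns the
    correlation, or ``(r, dist_A, dist_B)`` when ``return_distances`` so the
    distance-fitting curve can be plotted.  If either distance vector has zero
    variance (all points coincident) the correlation is defined as 0, with a
    warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"row counts differ: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 rows for a meaningful correlation")
    da = pdist(A)
    db = pdist(B)
    if np.std(da) == 0 or np.std(db) == 0:
        warnings.warn("zero variance in a distance vector; correlation defined as 0")
        r = 0.0
    else:
        r = float(np.corrcoef(da, db)[0, 1])
    if return_distances:
        return r, da, db
    return r
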