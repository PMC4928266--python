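"""Distribution overlap and matrix-correlation tests.

The Jaccard-type overlap index D_O = O_AB / (S_A + S_B − O_AB) measures how
much two species' ranges coincide (1 = identical, 0 = disjoint); its
complement D_AB = 1 − D_O serves as a between-species distributional
distance, computed both for geographic range areas and for altitudinal
intervals. The partial Mantel test correlates a morphological distance
matrix with a distributional one while controlling for phylogenetic
(patristic) distance, with significance from joint row/column permutations
of the residualized matrix (Legendre's residual-permutation method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import Phylogeny, RangeRecord
from .morphostats import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MantelResult",
    "overlap_index",
    "overlap_distance_matrix",
    "altitudinal_overlap_distance",
    "phylogenetic_distance_matrix",
    "partial_mantel",
    "mantel",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    controlled: bool

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")
        self.r = float(np.clip(self.r, -1.0, 1.0))


def overlap_index(s_a: float, s_b: float, o_ab: float) -> float:
    """D_O = O_AB / (S_A + S_B − O_AB), the proportion of the joint range
    shared by both species."""
    if s_a <= 0 or s_b <= 0:
        raise ValueError("range areas must be positive")
    if o_ab < 0 or o_ab > min(s_a, s_b) + 1e-9 * min(s_a, s_b):
        raise ValueError(f"overlap {o_ab} outside [0, min(S_A, S_B)]")
    return float(o_ab / (s_a + s_b - o_ab))


def overlap_distance_matrix(ranges: Sequence[RangeRecord]) -> DistanceMatrix:
    """Pairwise geographic distributional distances D_AB = 1 − D_O."""
    labels = tuple(r.species for r in ranges)
    n = len(ranges)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ranges[i], ranges[j]
            o = a.pairwise_overlap.get(b.species)
            if o is None:
                logger.info("no overlap recorded for (%s, %s); using 0", a.species, b.species)
                o = 0.0
            D[i, j] = D[j, i] = 1.0 - overlap_index(a.area, b.area, o)
    return DistanceMatrix(labels=labels, values=D)


def _interval_distance(lo_a, hi_a, lo_b, hi_b) -> float:
    len_a = hi_a - lo_a
    len_b = hi_b - lo_b
    if len_a == 0 and len_b == 0:
        # degenerate point ranges: identical points overlap fully
        return 0.0 if lo_a == lo_b else 1.0
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    union = len_a + len_b - inter
    return 1.0 - inter / union


def altitudinal_overlap_distance(intervals) -> DistanceMatrix:
    """D_AB over altitudinal intervals; accepts RangeRecords or a mapping of
    species to (alt_min, alt_max)."""
    if isinstance(intervals, dict):
        items = [(s, lo, hi) for s, (lo, hi) in intervals.items()]
    else:
        intervals = list(intervals)
        if intervals and isinstance(intervals[0], RangeRecord):
            items = [(r.species, r.alt_min, r.alt_max) for r in intervals]
        else:
            items = [(s, lo, hi) for s, (lo, hi) in intervals]
    for s, lo, hi in items:
        if lo > hi:
            raise ValueError(f"alt_min > alt_max for {s}")
    labels = tuple(s for s, _, _ in items)
    n = len(items)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, lo_a, hi_a = items[i]
            _, lo_b, hi_b = items[j]
            D[i, j] = D[j, i] = _interval_distance(lo_a, hi_a, lo_b, hi_b)
    return DistanceMatrix(labels=labels, values=D)


def phylogenetic_distance_matrix(tree: Phylogeny) -> DistanceMatrix:
    """Patristic distances: summed branch lengths on each tip-to-tip path."""
    labels, D = tree.patristic_distances()
    return DistanceMatrix(labels=tuple(labels), values=D)


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), on])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix | None,
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel correlation of A with B controlling for C.

    Off-diagonal vectors of A and B are each residualized on C; r is their
    Pearson correlation. Significance comes from ``n_perm`` joint row/column
    permutations of the residualized A matrix, one-tailed for positive
    association by default (``tail="two-sided"`` for the magnitude test),
    with the +1 exactness correction. With ``C=None`` this is the simple
    Mantel test.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    labels = A.labels
    for other in (B, C):
        if other is not None and other.labels != labels:
            raise ValueError("distance matrices must share labels and order")
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 items")
    iu = np.triu_indices(n, k=1)
    a = A.values[iu]
    b = B.values[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in off-diagonal distances")
    if C is not None:
        c = C.values[iu]
        ra = _residualize(a, c)
        rb = _residualize(b, c)
    else:
        ra = a - a.mean()
        rb = b - b.mean()

    def corr(u: np.ndarray, v: np.ndarray) -> float:
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    r_obs = corr(ra, rb)

    # residuals back in matrix form for joint row/column permutation
    RA = np.zeros((n, n))
    RA[iu] = ra
    RA = RA + RA.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        rp = RA[np.ix_(idx, idx)][iu]
        r_perm = corr(rp, rb)
        if tail == "greater":
            if r_perm >= r_obs:
                count += 1
        else:
            if abs(r_perm) >= abs(r_obs):
                count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, p=float(p), n_permutations=n_perm, controlled=C is not None
    )


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Simple Mantel test (no controlled matrix)."""
    return partial_mantel(A, B, None, n_perm=n_perm, seed=seed, tail=tail)
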