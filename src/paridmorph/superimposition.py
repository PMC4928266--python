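"""Procrustes superimposition: centroid size, pairwise fits, generalized
Procrustes analysis (GPA), sliding semilandmarks and tangent projection.

Conventions (full Procrustes, reflections disallowed):

* every configuration is translated so its centroid is at the origin and
  scaled to unit centroid size;
* rotations are proper (determinant +1) — beaks are digitised in a single
  orientation, so a mirror image is a different shape;
* the consensus is the normalized arithmetic mean of the aligned shapes,
  rescaled to unit centroid size each iteration.

Shapes are ``(k, 2)`` arrays throughout; :class:`AlignedShapeSet` stores the
whole superimposed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import LandmarkConfiguration

__all__ = [
    "AlignedShapeSet",
    "ConvergenceError",
    "centroid_size",
    "procrustes_fit",
    "gpa",
    "slide_semilandmarks",
    "procrustes_distance",
    "tangent_project",
    "default_curves",
]


class ConvergenceError(RuntimeError):
    pass


def _as_points(shape) -> np.ndarray:
    if isinstance(shape, LandmarkConfiguration):
        return shape.points
    return np.asarray(shape, dtype=float)


def centroid_size(shape) -> float:
    """Square root of the summed squared distances of the points from their
    centroid — the standard geometric size measure."""
    pts = _as_points(shape)
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 1e-300:
        raise ValueError("all points coincident: centroid size is zero")
    return size


def _center_scale(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(pts)


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||moving @ R - target||."""
    H = moving.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def procrustes_fit(moving, reference) -> tuple[np.ndarray, float]:
    """Translate, scale and rotate ``moving`` onto a centered unit-size
    ``reference``; returns the aligned points and the residual
    root-sum-of-squares."""
    m = _as_points(moving)
    r = _as_points(reference)
    if m.shape != r.shape:
        raise ValueError(f"point-count mismatch: {m.shape} vs {r.shape}")
    m = _center_scale(m)
    aligned = m @ _optimal_rotation(m, r)
    return aligned, float(np.linalg.norm(aligned - r))


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance: both shapes centered and unit-scaled,
    then optimally rotated; symmetric and a metric on shape space."""
    _, resid = procrustes_fit(a, _center_scale(_as_points(b)))
    return resid


@dataclass
class AlignedShapeSet:
    """Output of GPA: superimposed shapes, sizes, consensus, roles."""

    shapes: np.ndarray  # (n, k, 2), each centered, unit centroid size
    centroid_sizes: np.ndarray  # (n,) original sizes
    consensus: np.ndarray  # (k, 2), centered, unit centroid size
    semi_roles: tuple[str, ...]
    iterations_used: int
    specimen_ids: tuple[str, ...] = ()
    species: tuple[str, ...] = ()
    curves: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = self.shapes.shape[0]
        if self.centroid_sizes.shape != (n,):
            raise ValueError("shapes and centroid_sizes length mismatch")

    @property
    def n_specimens(self) -> int:
        return int(self.shapes.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.shapes.shape[1])

    @property
    def semi_mask(self) -> np.ndarray:
        return np.array([r == "semi" for r in self.semi_roles])

    def flat(self) -> np.ndarray:
        """Shapes as an (n, 2k) matrix of x1 y1 x2 y2 ... rows."""
        return self.shapes.reshape(self.n_specimens, -1)

    def total_ss(self) -> float:
        """Total Procrustes sum of squares around the consensus."""
        return float(((self.shapes - self.consensus) ** 2).sum())


def _mean_consensus(shapes: np.ndarray) -> np.ndarray:
    mean = shapes.mean(axis=0)
    mean = mean - mean.mean(axis=0)
    size = np.sqrt((mean**2).sum())
    if size < 1e-9:
        # degenerate (inputs cancel); fall back to the first shape
        return shapes[0].copy()
    return mean / size


def gpa(
    configs,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> AlignedShapeSet:
    """Generalized Procrustes analysis.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus until the consensus RMS
    change falls below ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    pts = [_as_points(c) for c in configs]
    k = pts[0].shape[0]
    if any(p.shape != (k, 2) for p in pts):
        raise ValueError("all configurations must have the same point count")
    sizes = np.array([centroid_size(p) for p in pts])
    X = np.stack([_center_scale(p) for p in pts])

    consensus = _mean_consensus(X)
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_c = _mean_consensus(X)
        # remove rotational drift before measuring the change
        new_c = new_c @ _optimal_rotation(new_c, consensus)
        delta = float(np.sqrt(((new_c - consensus) ** 2).mean()))
        consensus = new_c
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {delta:g})"
        )
    for i in range(X.shape[0]):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)

    if isinstance(configs[0], LandmarkConfiguration):
        roles = configs[0].roles
        ids = tuple(c.specimen_id for c in configs)
        species = tuple(c.species for c in configs)
    else:
        roles = ("fixed",) * k
        ids = tuple(f"shape_{i + 1}" for i in range(len(configs)))
        species = ("",) * len(configs)
    return AlignedShapeSet(
        shapes=X,
        centroid_sizes=sizes,
        consensus=consensus,
        semi_roles=roles,
        iterations_used=iterations,
        specimen_ids=ids,
        species=species,
    )


# ---------------------------------------------------------------------------
# sliding semilandmarks
# ---------------------------------------------------------------------------


def default_curves(roles) -> tuple[tuple[int, ...], ...]:
    """Infer the outline curves along which semilandmarks slide.

    For the 21-point beak scheme (points 1-3 fixed, 9 semis on the upper
    profile between LM1 and LM3, 9 on the lower between LM2 and LM3) the two
    profile chains are returned. Otherwise the point order itself is treated
    as one curve, which must start and end with a fixed anchor.
    """
    roles = tuple(roles)
    k = len(roles)
    if k == 21 and roles == ("fixed",) * 3 + ("semi",) * 18:
        upper = (0,) + tuple(range(3, 12)) + (2,)
        lower = (1,) + tuple(range(12, 21)) + (2,)
        return (upper, lower)
    if roles[0] == "semi" or roles[-1] == "semi":
        raise ValueError(
            "cannot infer sliding curves: first/last point is a semilandmark "
            "with no fixed anchor; pass curves explicitly"
        )
    return (tuple(range(k)),)


def _neighbors(curves, k: int) -> dict[int, tuple[int, int]]:
    nbr: dict[int, tuple[int, int]] = {}
    for chain in curves:
        for pos in range(1, len(chain) - 1):
            nbr[chain[pos]] = (chain[pos - 1], chain[pos + 1])
    return nbr


def _bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix L_k^-1 (top-left block)."""
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(np.sqrt(d2)), 0.0)
    Q = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    return Linv[:k, :k]


def slide_semilandmarks(
    aligned: AlignedShapeSet,
    curves=None,
    criterion: str = "procrustes",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> AlignedShapeSet:
    """Slide semilandmarks along their outline tangents.

    Each semilandmark may move along the chord between its curve neighbours;
    with the default ``"procrustes"`` criterion the displacement minimizes
    the specimen's squared distance to the consensus (an exact per-point
    projection), with ``"bending"`` it minimizes the thin-plate-spline
    bending energy of the deformation from the consensus. Sliding alternates
    with consensus updates until the total Procrustes sum of squares
    stabilises. A specimen's slide is only accepted if it does not increase
    its distance to the consensus, so the total sum of squares never
    increases. Fixed landmarks never move.
    """
    if criterion not in ("procrustes", "bending", "none"):
        raise ValueError(f"unknown sliding criterion {criterion!r}")
    if criterion == "none":
        return aligned
    semi = aligned.semi_mask
    if not semi.any():
        raise ValueError("no semilandmarks flagged; nothing to slide")
    if curves is None:
        curves = aligned.curves or default_curves(aligned.semi_roles)
    nbr = _neighbors(curves, aligned.n_points)
    missing = [j for j in np.flatnonzero(semi) if j not in nbr]
    if missing:
        raise ValueError(f"semilandmarks without curve neighbours: {missing}")

    X = aligned.shapes.copy()
    consensus = aligned.consensus.copy()
    semi_idx = np.flatnonzero(semi)
    last_ss = float(((X - consensus) ** 2).sum())
    iterations = aligned.iterations_used

    for _ in range(max_iter):
        if criterion == "bending":
            B = _bending_energy_matrix(consensus)
        for i in range(X.shape[0]):
            x = X[i]
            tangents = np.zeros((len(semi_idx), 2))
            for t_row, j in enumerate(semi_idx):
                a, b = nbr[j]
                t = x[b] - x[a]
                norm = np.linalg.norm(t)
                tangents[t_row] = t / norm if norm > 0 else 0.0
            if criterion == "procrustes":
                cand = x.copy()
                for t_row, j in enumerate(semi_idx):
                    disp = float(np.dot(consensus[j] - x[j], tangents[t_row]))
                    cand[j] = x[j] + disp * tangents[t_row]
            else:
                cand = _bending_slide(x, consensus, B, semi_idx, tangents)
            cand = cand - cand.mean(axis=0)
            cand = cand / np.sqrt((cand**2).sum())
            cand = cand @ _optimal_rotation(cand, consensus)
            if ((cand - consensus) ** 2).sum() <= ((x - consensus) ** 2).sum() or (
                criterion == "bending"
            ):
                X[i] = cand
        new_c = _mean_consensus(X)
        new_c = new_c @ _optimal_rotation(new_c, consensus)
        consensus = new_c
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        ss = float(((X - consensus) ** 2).sum())
        iterations += 1
        if abs(last_ss - ss) < tol:
            last_ss = ss
            break
        last_ss = ss

    return AlignedShapeSet(
        shapes=X,
        centroid_sizes=aligned.centroid_sizes.copy(),
        consensus=consensus,
        semi_roles=aligned.semi_roles,
        iterations_used=iterations,
        specimen_ids=aligned.specimen_ids,
        species=aligned.species,
        curves=tuple(tuple(c) for c in curves),
    )


def _bending_slide(x, consensus, B, semi_idx, tangents) -> np.ndarray:
    """Minimize bending energy of (x' - consensus) over tangent displacements.

    x' = x + T lam with T mapping each semilandmark's scalar displacement to
    its tangent direction; energy(d) = dx' B dx + dy' B dy.
    """
    m = len(semi_idx)
    k = x.shape[0]
    # T is (k, m) per coordinate axis
    Tx = np.zeros((k, m))
    Ty = np.zeros((k, m))
    for col, j in enumerate(semi_idx):
        Tx[j, col] = tangents[col, 0]
        Ty[j, col] = tangents[col, 1]
    rx = x[:, 0] - consensus[:, 0]
    ry = x[:, 1] - consensus[:, 1]
    A = Tx.T @ B @ Tx + Ty.T @ B @ Ty
    b = -(Tx.T @ B @ rx + Ty.T @ B @ ry)
    lam, *_ = np.linalg.lstsq(A, b, rcond=None)
    out = x.copy()
    out[semi_idx, 0] += lam * tangents[:, 0]
    out[semi_idx, 1] += lam * tangents[:, 1]
    return out


def tangent_project(aligned: AlignedShapeSet) -> np.ndarray:
    """Orthogonal projection of the aligned shapes onto the tangent space at
    the consensus; the consensus maps to the origin.

    Returns an ``(n, 2k)`` matrix whose Euclidean geometry approximates
    Procrustes distance to first order near the consensus.
    """
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    X = aligned.flat()
    return X - np.outer(X @ c, c)
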