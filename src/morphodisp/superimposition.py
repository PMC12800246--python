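"""Generalized Procrustes analysis with sliding semi-landmarks.

Superimposition removes the nuisance components of a landmark configuration
— position, size and orientation — leaving only shape. Each configuration is
translated so its centroid is at the origin, scaled to unit centroid size,
and rotated to least-squares fit a consensus; the consensus is the mean of
the aligned configurations and the procedure iterates until it stops moving.
Rotations are proper (determinant +1): all specimens are digitised in the
same orientation, so reflections are disallowed.

Semi-landmarks, which carry no point-wise homology along an outline, are
allowed to slide along the local curve tangent between rotation passes. The
sliding criterion is Procrustes-distance minimisation: each semi-landmark's
deviation from the consensus point is projected onto the tangent direction
(the chord between its two curve neighbours), which minimises the squared
distance to the consensus achievable along the tangent line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import LandmarkConfiguration, SliderDefinition

logger = logging.getLogger(__name__)


@dataclass
class AlignedSample:
    """Procrustes-aligned coordinates for a sample of specimens.

    Attributes
    ----------
    coords : (n, k, 2) ndarray
        Aligned coordinates; each specimen is centered at the origin with
        unit centroid size (dimensionless shape units).
    consensus : (k, 2) ndarray
        Arithmetic mean of the aligned coordinates.
    centroid_sizes : (n,) ndarray
        Original centroid sizes, in the input units.
    specimen_ids : list of str
    n_iterations : int
    converged : bool
    """

    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    n_iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """Coordinates as an (n, 2k) matrix ordered (x1, y1, ..., xk, yk)."""
        return self.coords.reshape(self.n, -1)

    def subset(self, mask: np.ndarray) -> "AlignedSample":
        """Row subset without re-alignment (consensus recomputed on the subset)."""
        mask = np.asarray(mask)
        coords = self.coords[mask]
        ids = [sid for sid, m in zip(self.specimen_ids, mask) if m] if mask.dtype == bool else [
            self.specimen_ids[i] for i in mask
        ]
        return AlignedSample(
            coords=coords,
            consensus=coords.mean(axis=0),
            centroid_sizes=self.centroid_sizes[mask],
            specimen_ids=ids,
            n_iterations=self.n_iterations,
            converged=self.converged,
        )


def centroid_size(points: np.ndarray | LandmarkConfiguration) -> float:
    """Square root of summed squared distances of points from their centroid.

    Returns 0 for a configuration of identical points; callers must treat a
    zero size as degenerate before scaling by it.
    """
    pts = points.points if isinstance(points, LandmarkConfiguration) else np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _center_scale(points: np.ndarray) -> tuple[np.ndarray, float]:
    centered = points - points.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / size, size


def opa_rotate(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation of ``moving`` onto ``target`` (both centered, unit size).

    The least-squares rotation is obtained from the SVD of the 2x2
    cross-product matrix ``target.T @ moving`` with the determinant
    constrained to +1 (no reflection). Returns the rotated shape and the
    rotation angle in radians (counter-clockwise).
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    M = target.T @ moving
    if np.allclose(M, 0):
        logger.warning("degenerate cross-product matrix; returning identity rotation")
        return moving.copy(), 0.0
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    rotated = moving @ R.T
    angle = float(np.arctan2(R[1, 0], R[0, 0]))
    return rotated, angle


def _batch_rotate(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate every (k,2) configuration in (n,k,2) onto target; proper rotations only."""
    # cross-product matrices, batched: M_i = target.T @ coords_i
    M = np.einsum("ka,nkb->nab", target, coords)
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(np.einsum("nab,nbc->nac", U, Vt))
    D = np.zeros_like(M)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = np.sign(det)
    R = np.einsum("nab,nbc,ncd->nad", U, D, Vt)
    return np.einsum("nkb,nab->nka", coords, R)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between two shapes after optimal rotation.

    Both inputs must be centered and of unit centroid size; the distance is
    minimised over proper rotations only.
    """
    rotated, _ = opa_rotate(np.asarray(a, float), np.asarray(b, float))
    return float(np.sqrt(((rotated - b) ** 2).sum()))


def slide_semilandmarks(
    coords: np.ndarray, consensus: np.ndarray, sliders: SliderDefinition
) -> np.ndarray:
    """Slide semi-landmarks along their tangent toward the consensus.

    For each specimen and each slider point ``p`` with neighbours ``(b, a)``,
    the tangent is the unit chord from point ``b`` to point ``a`` (for a
    terminal semi-landmark with one neighbour, the chord from the slider to
    that neighbour). The new position is ``p + t*u`` with
    ``t = (consensus_p - p) . u``: the projection of the deviation onto the
    tangent, the minimiser of squared distance to the consensus point along
    the tangent line. Fixed landmarks are untouched. Coincident neighbours
    (zero-length tangent) leave the point unslid with a warning.
    """
    coords = np.array(coords, float, copy=True)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    for b, s, a in sliders.triples:
        if b < 0 or a < 0:
            nb = a if b < 0 else b
            tangent = coords[:, nb] - coords[:, s]
        else:
            tangent = coords[:, a] - coords[:, b]
        norm = np.linalg.norm(tangent, axis=1, keepdims=True)
        zero = norm[:, 0] == 0
        if zero.any():
            logger.warning("zero-length tangent at slider %d for %d specimen(s); left unslid", s, int(zero.sum()))
            norm[zero] = 1.0
        u = tangent / norm
        t = np.einsum("ni,ni->n", consensus[s] - coords[:, s], u)
        t = np.where(zero, 0.0, t)
        coords[:, s] += t[:, None] * u
    return coords[0] if single else coords


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus onto its principal axes.

    The major axis of the consensus goes to x. Of the two 180-degree-apart
    candidates, the one giving the rotated consensus a nonnegative third
    moment along x (falling back to y, then to the first point's sign) is
    chosen, which pins the orientation deterministically for generic shapes.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    major = vecs[:, -1]  # eigenvalues ascending
    angle = np.arctan2(major[1], major[0])
    c, s = np.cos(-angle), np.sin(-angle)
    R = np.array([[c, -s], [s, c]])
    rotated = consensus @ R.T
    for moment in ((rotated[:, 0] ** 3).sum(), (rotated[:, 1] ** 3).sum(), rotated[0, 0], rotated[0, 1]):
        if abs(moment) > 1e-12:
            if moment < 0:
                R = -R  # 180-degree flip (still proper: det(+R) = det(-R) in 2D)
            break
    return R


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    sliders: SliderDefinition | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    specimen_ids: list[str] | None = None,
) -> AlignedSample:
    """Generalized Procrustes analysis of a landmark sample.

    Iterates: align every configuration to the current consensus (center,
    scale to unit centroid size, proper rotation); slide semi-landmarks if a
    slider definition is given, re-centering and re-scaling afterwards;
    recompute the consensus. Stops when the consensus moves by less than
    ``tol`` (root summed squared difference) or after ``max_iter`` passes,
    in which case the best state is returned with ``converged=False``.

    Accepts a list of :class:`LandmarkConfiguration` or a raw (n, k, 2) array.
    """
    if isinstance(configs, np.ndarray):
        raw = np.asarray(configs, float)
        ids = specimen_ids or [str(i) for i in range(raw.shape[0])]
    else:
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise ValueError(f"configurations disagree on landmark count: {sorted(ks)}")
        raw = np.stack([c.points for c in configs])
        ids = specimen_ids or [c.specimen_id for c in configs]
    n = raw.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    sizes = np.empty(n)
    X = np.empty_like(raw)
    for i in range(n):
        X[i], sizes[i] = _center_scale(raw[i])

    consensus, _ = _center_scale(X[0])
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        X = _batch_rotate(X, consensus)
        if sliders is not None:
            X = slide_semilandmarks(X, consensus, sliders)
            for i in range(n):
                X[i], _ = _center_scale(X[i])
            X = _batch_rotate(X, consensus)
        new_consensus, _ = _center_scale(X.mean(axis=0))
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations (last delta %.3g)", max_iter, delta)

    # final alignment pass so coordinates match the reported consensus
    X = _batch_rotate(X, consensus)
    # canonical global orientation: rotate the whole solution so the consensus
    # lies along its principal axes, with a deterministic sign rule; without
    # this the output would inherit the arbitrary orientation of the first
    # input, breaking similarity invariance
    R = _canonical_rotation(X.mean(axis=0))
    X = X @ R.T
    return AlignedSample(
        coords=X,
        consensus=X.mean(axis=0),
        centroid_sizes=sizes,
        specimen_ids=list(ids),
        n_iterations=iteration,
        converged=converged,
    )
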