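"""Principal component analysis of aligned shape coordinates and morphospaces.

PCA runs on the flattened Procrustes coordinates (x1, y1, ..., xk, yk)
about their mean, with covariance divisor n-1. Shape variation in these
samples is small relative to the curvature of shape space, so by default no
projection to tangent space is applied before the decomposition; pass
``tangent_projection=True`` to orthogonalise the centered data against the
mean shape direction first and check sensitivity.

Axis signs are fixed deterministically: the largest-magnitude loading of
each axis is made positive. PCA signs are otherwise arbitrary, so any
comparison with published morphospaces must be sign-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimposition import AlignedSample


@dataclass
class Ordination:
    """Result of a shape-space PCA.

    Attributes
    ----------
    scores : (n, m) ndarray
        Specimen scores on the m retained (non-degenerate) axes.
    eigenvalues : (m,) ndarray
        Variances along each axis, non-increasing.
    prop_variance : (m,) ndarray
        Proportion of total variance per axis; sums to 1.
    loadings : (2k, m) ndarray
        Orthonormal axis directions in flattened-coordinate space.
    mean_vector : (2k,) ndarray
    specimen_ids : list of str
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    prop_variance: np.ndarray
    loadings: np.ndarray
    mean_vector: np.ndarray
    specimen_ids: list[str]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Flattened coordinates rebuilt from scores and loadings."""
        return self.mean_vector + self.scores @ self.loadings.T

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.scores, index=self.specimen_ids, columns=cols)


def pca(sample: AlignedSample, tangent_projection: bool = False) -> Ordination:
    """Eigen-decomposition of the covariance of flattened aligned coordinates.

    Zero eigenvalues (beyond numerical rank) are truncated; requires n >= 3.
    """
    if sample.n < 3:
        raise ValueError(f"PCA needs at least 3 specimens, got {sample.n}")
    flat = sample.flattened()
    mean_vector = flat.mean(axis=0)
    centered = flat - mean_vector
    if tangent_projection:
        # remove the component along the consensus direction (orthogonal
        # projection onto the tangent space at the mean shape)
        m = mean_vector / np.linalg.norm(mean_vector)
        centered = centered - np.outer(centered @ m, m)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (sample.n - 1)
    if eigenvalues[0] == 0:
        raise ValueError("aligned sample has no shape variation")
    keep = eigenvalues > eigenvalues[0] * 1e-12
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    eigenvalues = eigenvalues[keep]

    loadings = Vt.T
    scores = U * s
    # deterministic sign: largest-|loading| entry of each axis positive
    flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    loadings *= flips
    scores *= flips
    return Ordination(
        scores=scores,
        eigenvalues=eigenvalues,
        prop_variance=eigenvalues / eigenvalues.sum(),
        loadings=loadings,
        mean_vector=mean_vector,
        specimen_ids=list(sample.specimen_ids),
    )


def morphospace(
    ord: Ordination,
    axes: tuple[int, int] = (0, 1),
    groups: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Tabulate specimen positions on a PC plane, grouped by label.

    ``axes`` are 0-based axis indices. Returns a DataFrame with columns
    ``specimen, group, x, y``; single-member groups are legitimate (they plot
    as a single point, with no hull).
    """
    for ax in axes:
        if not 0 <= ax < ord.n_axes:
            raise ValueError(f"axis {ax} out of range (have {ord.n_axes} axes)")
    if groups is None:
        labels = ["all"] * len(ord.specimen_ids)
    elif isinstance(groups, dict):
        labels = [groups[sid] for sid in ord.specimen_ids]
    else:
        labels = [groups.loc[sid] for sid in ord.specimen_ids]
    return pd.DataFrame(
        {
            "specimen": ord.specimen_ids,
            "group": labels,
            "x": ord.scores[:, axes[0]],
            "y": ord.scores[:, axes[1]],
        }
    )


def plot_morphospace(
    ord: Ordination,
    axes: tuple[int, int] = (0, 1),
    groups: pd.Series | dict | None = None,
    hulls: bool = True,
    ax=None,
):
    """Scatter a PC plane with optional per-group convex hulls.

    Groups with fewer than three members are drawn as bare points (a hull is
    undefined there). Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    from .disparity import convex_hull

    table = morphospace(ord, axes=axes, groups=groups)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for label, sub in table.groupby("group", sort=True):
        pts = sub[["x", "y"]].to_numpy()
        sc = ax.scatter(pts[:, 0], pts[:, 1], label=str(label), s=25)
        if hulls and len(pts) >= 3:
            hull = convex_hull(pts)
            closed = np.vstack([hull, hull[:1]])
            ax.plot(closed[:, 0], closed[:, 1], color=sc.get_facecolor()[0], alpha=0.4)
    ax.set_xlabel(f"PC{axes[0] + 1} ({100 * ord.prop_variance[axes[0]]:.1f}%)")
    ax.set_ylabel(f"PC{axes[1] + 1} ({100 * ord.prop_variance[axes[1]]:.1f}%)")
    ax.legend(fontsize=8)
    return ax
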