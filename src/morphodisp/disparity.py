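"""Group-wise morphological disparity statistics.

Two complementary metrics are provided. Procrustes variance — a group's mean
squared deviation, in flattened Procrustes coordinates, from its own mean
shape — measures the dispersal of taxa in shape space. Convex-hull area on a
PC plane measures the extent of morphospace occupied; it is more sensitive
to extreme values and is undefined for groups of two species or fewer. A
variance-weighted multi-PC hull area aggregates hull areas over all pairs of
the first few PCs, weighting each pairwise area by the combined proportion
of variance the two axes explain.

The Procrustes-variance divisor is n (the group size), matching the
group-wise disparity convention of the standard morphometrics tooling; pass
``ddof=1`` for the sample-variance convention. Pairwise significance is
assessed by permuting group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ordination import Ordination
from .superimposition import AlignedSample

logger = logging.getLogger(__name__)


@dataclass
class DisparityTable:
    """Per-group disparity summary.

    ``group_pv`` maps group to Procrustes variance; ``group_share`` to its
    fraction of the summed group PVs (the pie-chart statistic). Hull areas
    are absent (missing key) for groups with fewer than three members.
    """

    group_pv: dict[str, float]
    group_share: dict[str, float]
    n_per_group: dict[str, int]
    pairwise_abs_diff: pd.DataFrame
    pairwise_p: pd.DataFrame
    hull_area: dict[str, float] = field(default_factory=dict)
    weighted_hull_area: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.group_pv):
            rows.append(
                {
                    "group": g,
                    "n": self.n_per_group[g],
                    "procrustes_variance": self.group_pv[g],
                    "share": self.group_share[g],
                    "hull_area": self.hull_area.get(g, np.nan),
                    "weighted_hull_area": self.weighted_hull_area.get(g, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _as_matrix(sample: AlignedSample | np.ndarray) -> np.ndarray:
    if isinstance(sample, AlignedSample):
        return sample.flattened()
    arr = np.asarray(sample, float)
    return arr.reshape(arr.shape[0], -1)


def _group_pv(flat: np.ndarray, ddof: int = 0) -> float:
    dev = flat - flat.mean(axis=0)
    return float((dev**2).sum() / (flat.shape[0] - ddof))


def procrustes_variance(
    sample: AlignedSample | np.ndarray,
    labels: np.ndarray | list | pd.Series | None = None,
    ddof: int = 0,
) -> dict[str, float]:
    """Per-group mean squared Procrustes deviation from the group mean shape.

    With ``labels=None`` the whole sample forms a single group ``"all"``.
    Divisor is ``n - ddof`` with ``ddof=0`` by default (group-wise disparity
    convention). Empty groups are absent from the result.
    """
    flat = _as_matrix(sample)
    if labels is None:
        return {"all": _group_pv(flat, ddof)}
    labels = np.asarray(labels)
    if labels.shape[0] != flat.shape[0]:
        raise ValueError("one label per specimen required")
    out: dict[str, float] = {}
    for g in np.unique(labels):
        members = flat[labels == g]
        if members.shape[0] - ddof < 1:
            logger.info("group %r too small for ddof=%d; omitted", g, ddof)
            continue
        out[str(g)] = _group_pv(members, ddof)
    return out


def disparity_shares(group_pv: dict[str, float]) -> dict[str, float]:
    """Each group's PV as a fraction of the summed group PVs."""
    total = sum(group_pv.values())
    if total == 0:
        return {g: 0.0 for g in group_pv}
    return {g: v / total for g, v in group_pv.items()}


def pairwise_pv_test(
    sample: AlignedSample | np.ndarray,
    labels: np.ndarray | list | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation test of pairwise Procrustes-variance differences.

    The observed statistic for a pair of groups is ``|PV_g1 - PV_g2|``; the
    null distribution is built by randomly permuting the group labels
    ``n_perm`` times, and ``p = (count of permuted statistics >= observed
    + 1) / (n_perm + 1)``. Returns the symmetric absolute-difference and
    p-value matrices (diagonal p = 1). Comparisons involving a group of one
    specimen are reported with the difference but an absent (NaN) p-value.
    """
    if n_perm < 99:
        logger.warning("n_perm=%d gives coarse p-value resolution; 99+ recommended", n_perm)
    flat = _as_matrix(sample)
    labels = np.asarray([str(l) for l in labels])
    groups = sorted(np.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if rng is None:
        rng = np.random.default_rng(seed)

    def pv_by_group(lab: np.ndarray) -> dict[str, float]:
        return {g: _group_pv(flat[lab == g]) for g in groups if (lab == g).sum() >= 1}

    observed = pv_by_group(labels)
    counts = {g: int((labels == g).sum()) for g in groups}

    diff = pd.DataFrame(0.0, index=groups, columns=groups)
    exceed = pd.DataFrame(0, index=groups, columns=groups)
    pairs = list(combinations(groups, 2))
    for g1, g2 in pairs:
        diff.loc[g1, g2] = diff.loc[g2, g1] = abs(observed[g1] - observed[g2])

    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pv = pv_by_group(perm)
        for g1, g2 in pairs:
            if abs(pv[g1] - pv[g2]) >= diff.loc[g1, g2]:
                exceed.loc[g1, g2] += 1

    p = pd.DataFrame(1.0, index=groups, columns=groups)
    for g1, g2 in pairs:
        if counts[g1] < 2 or counts[g2] < 2:
            p.loc[g1, g2] = p.loc[g2, g1] = np.nan
        else:
            val = (exceed.loc[g1, g2] + 1) / (n_perm + 1)
            p.loc[g1, g2] = p.loc[g2, g1] = val
    return diff, p


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices, counter-clockwise, by the monotone-chain algorithm."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from an ordered vertex ring (shoelace formula)."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def convex_hull_area(points2d: np.ndarray) -> float:
    """Area of the convex hull of >= 3 points; collinear input gives 0."""
    pts = np.asarray(points2d, float)
    if pts.shape[0] < 3:
        raise ValueError("convex hull area undefined for fewer than 3 points")
    hull = convex_hull(pts)
    if hull.shape[0] < 3:
        return 0.0
    return shoelace_area(hull)


def hull_areas(
    ord: Ordination,
    labels: np.ndarray | list | pd.Series,
    axes: tuple[int, int] = (0, 1),
) -> dict[str, float]:
    """Per-group convex-hull area on one PC plane; groups with n < 3 are absent."""
    labels = np.asarray([str(l) for l in labels])
    pts = ord.scores[:, list(axes)]
    out: dict[str, float] = {}
    for g in np.unique(labels):
        sub = pts[labels == g]
        if sub.shape[0] >= 3:
            out[str(g)] = convex_hull_area(sub)
    return out


def weighted_hull_area(
    ord: Ordination,
    labels: np.ndarray | list | pd.Series,
    n_pcs: int = 5,
    normalize: bool = False,
) -> dict[str, float]:
    """Variance-weighted hull area over all pairs of the first ``n_pcs`` PCs.

    For each unordered axis pair (i, j) the group's hull area on that plane
    is multiplied by ``prop_variance[i] + prop_variance[j]``, and the
    products are summed. With ``normalize=True`` the sum is divided by the
    total pair weight (an average rather than a raw sum).
    """
    n_pcs = min(n_pcs, ord.n_axes)
    labels = np.asarray([str(l) for l in labels])
    out: dict[str, float] = {}
    pairs = list(combinations(range(n_pcs), 2))
    total_weight = sum(ord.prop_variance[i] + ord.prop_variance[j] for i, j in pairs)
    for g in np.unique(labels):
        mask = labels == g
        if mask.sum() < 3:
            continue
        acc = 0.0
        for i, j in pairs:
            area = convex_hull_area(ord.scores[np.ix_(mask, [i, j])])
            acc += area * (ord.prop_variance[i] + ord.prop_variance[j])
        out[str(g)] = acc / total_weight if normalize else acc
    return out


def sum_of_variances(scores: np.ndarray) -> float:
    """Sum over PC axes of the per-axis score variance (divisor n-1)."""
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 2:
        raise ValueError("sum of variances undefined for fewer than 2 specimens")
    return float(scores.var(axis=0, ddof=1).sum())


def disparity_table(
    sample: AlignedSample,
    ord: Ordination,
    labels: np.ndarray | list | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_pcs_weighted: int = 5,
) -> DisparityTable:
    """Assemble the full per-group disparity summary for one grouping variable."""
    labels = np.asarray([str(l) for l in labels])
    pv = procrustes_variance(sample, labels)
    diff, p = pairwise_pv_test(sample, labels, n_perm=n_perm, seed=seed, rng=rng)
    return DisparityTable(
        group_pv=pv,
        group_share=disparity_shares(pv),
        n_per_group={g: int((labels == g).sum()) for g in np.unique(labels)},
        pairwise_abs_diff=diff,
        pairwise_p=p,
        hull_area=hull_areas(ord, labels),
        weighted_hull_area=weighted_hull_area(ord, labels, n_pcs=n_pcs_weighted),
        n_permutations=n_perm,
        seed=seed,
    )
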