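"""Geological time handling: interval tables, binning, richness and disparity curves.

Ages are in Ma and decrease toward the present; an interval runs from
``start_ma`` (older) to ``end_ma`` (younger). Interval membership follows a
single convention throughout: an interval owns the ages
``[end_ma, start_ma)`` — an age falling exactly on a shared boundary belongs
to the OLDER of the two intervals — and the oldest interval is additionally
closed at its old end so the whole span is covered. This matches
first-appearance ("epoch of appearance") semantics: a taxon appearing
exactly at a boundary is credited to the interval in which its record
begins.

Two interval tables are shipped as package data, covering the Ludfordian
(425.6 Ma) to the end-Gzhelian (298.9 Ma): a 16-stage table and the 7-epoch
table (Ludlow, Pridoli, Lower/Middle/Upper Devonian, Mississippian,
Pennsylvanian). Boundary ages follow the international chronostratigraphic
chart; both tables are user-overridable via :meth:`TimeScale.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ordination import Ordination
from .superimposition import AlignedSample

#: Span of the study interval, Ma.
SPAN_START_MA = 425.6
SPAN_END_MA = 298.9


@dataclass
class TimeScale:
    """Ordered, contiguous set of geological intervals (old to young)."""

    intervals: list[tuple[str, float, float]]
    level: str = "custom"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("empty time scale")
        self.intervals = [(str(n), float(s), float(e)) for n, s, e in self.intervals]
        prev_end = None
        for name, start, end in self.intervals:
            if start <= end:
                raise ValueError(f"interval {name!r}: start_ma must exceed end_ma")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError(f"interval {name!r} does not abut the previous interval")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.intervals]

    @property
    def start_ma(self) -> float:
        return self.intervals[0][1]

    @property
    def end_ma(self) -> float:
        return self.intervals[-1][2]

    def contains(self, age_ma: float) -> bool:
        return self.end_ma <= age_ma <= self.start_ma

    def index_of(self, age_ma: float) -> int:
        """Index of the interval owning ``age_ma`` (boundary ages to the older interval)."""
        if not self.contains(age_ma):
            raise ValueError(f"age {age_ma} Ma outside time scale [{self.end_ma}, {self.start_ma}]")
        for i, (_, start, end) in enumerate(self.intervals):
            if end <= age_ma < start or (i == 0 and age_ma == start):
                return i
        raise AssertionError("unreachable: contiguous scale must own every in-span age")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["name", "start_ma", "end_ma"])

    @classmethod
    def from_csv(cls, path: str | Path, level: str = "custom") -> "TimeScale":
        df = pd.read_csv(path)
        return cls([(r.name, r.start_ma, r.end_ma) for r in df.itertuples(index=False)], level=level)


def _load_builtin(name: str, level: str) -> TimeScale:
    with resources.files("morphodisp.data").joinpath(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    return TimeScale([(r.name, r.start_ma, r.end_ma) for r in df.itertuples(index=False)], level=level)


def default_stages() -> TimeScale:
    """The 16-stage Ludfordian-to-Gzhelian table shipped with the package."""
    return _load_builtin("stages.csv", "stage")


def default_epochs() -> TimeScale:
    """The 7-epoch Ludfordian-to-Gzhelian table shipped with the package."""
    return _load_builtin("epochs.csv", "epoch")


def equal_bins(start_ma: float, end_ma: float, n_bins: int) -> TimeScale:
    """Divide [start_ma, end_ma] into ``n_bins`` contiguous bins of equal width.

    The default study span (425.6 to 298.9 Ma) with 7 bins gives a width of
    18.1 My. Bins tile the span exactly; the last bin's young edge is set to
    ``end_ma`` verbatim to avoid rounding drift.
    """
    if start_ma <= end_ma:
        raise ValueError("start_ma must exceed end_ma")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    edges = np.linspace(start_ma, end_ma, n_bins + 1)
    edges[-1] = end_ma
    intervals = [
        (f"bin_{i + 1}", float(edges[i]), float(edges[i + 1])) for i in range(n_bins)
    ]
    return TimeScale(intervals, level="equal_bin")


def assign_interval(species, scale: TimeScale) -> str:
    """Interval of first appearance for a species (FAD-based assignment).

    ``species`` may be a metadata row (anything with a ``fad_ma`` attribute
    or key) or a bare age in Ma. A taxon spanning several intervals is
    assigned by its FAD only — the interval of its appearance.
    """
    if hasattr(species, "fad_ma"):
        fad = float(species.fad_ma)
        name = getattr(species, "species", repr(species))
    elif isinstance(species, dict) or hasattr(species, "keys"):
        fad = float(species["fad_ma"])
        name = species.get("species", "<row>") if isinstance(species, dict) else species["species"]
    else:
        fad = float(species)
        name = f"{fad} Ma"
    try:
        return scale.names[scale.index_of(fad)]
    except ValueError as exc:
        raise ValueError(f"species {name}: {exc}") from exc


def assign_intervals(meta: pd.DataFrame, scale: TimeScale) -> pd.Series:
    """Vectorised :func:`assign_interval` over a metadata table (indexed like it)."""
    return pd.Series(
        [assign_interval(row, scale) for row in meta.itertuples(index=False)],
        index=meta.index,
        name="interval",
    )


def range_through_richness(meta: pd.DataFrame, scale: TimeScale) -> pd.DataFrame:
    """Taxon count per interval assuming presence throughout each FAD-LAD range.

    A species is counted in every interval its ``[lad_ma, fad_ma]`` range
    intersects, under the same ownership convention as
    :meth:`TimeScale.index_of`: an age exactly on a boundary is present in
    the older interval only.
    """
    richness = np.zeros(len(scale.intervals), dtype=int)
    for row in meta.itertuples(index=False):
        fad, lad = float(row.fad_ma), float(row.lad_ma)
        for i, (_, start, end) in enumerate(scale.intervals):
            # owned ages of interval i: [end_ma, start_ma), oldest also owns its start
            hi = start if i > 0 else np.nextafter(start, np.inf)
            if fad >= end and lad < hi:
                richness[i] += 1
    return pd.DataFrame({"interval": scale.names, "richness": richness})


def disparity_through_time(
    sample: AlignedSample,
    ord: Ordination,
    meta: pd.DataFrame,
    scale: TimeScale,
    metric: str = "procrustes_variance",
) -> pd.DataFrame:
    """Disparity per time interval, species binned by their interval of appearance.

    ``metric`` is ``"procrustes_variance"`` (mean squared deviation from the
    interval mean shape, divisor n, on flattened Procrustes coordinates) or
    ``"sum_of_variances"`` (summed per-axis variance of PC scores, divisor
    n-1). Intervals with fewer than two species have no defined dispersion
    and are reported with NaN, not zero.
    """
    from .disparity import _group_pv, sum_of_variances

    if metric not in ("procrustes_variance", "sum_of_variances"):
        raise ValueError(f"unknown metric {metric!r}")
    meta_by_species = meta.set_index("species")
    missing = [sid for sid in sample.specimen_ids if sid not in meta_by_species.index]
    if missing:
        raise ValueError(f"specimens lacking metadata: {missing}")
    sub = meta_by_species.loc[sample.specimen_ids].reset_index()
    intervals = assign_intervals(sub, scale)

    rows = []
    flat = sample.flattened()
    for i, name in enumerate(scale.names):
        mask = (intervals == name).to_numpy()
        n = int(mask.sum())
        if n < 2:
            value = np.nan
        elif metric == "procrustes_variance":
            value = _group_pv(flat[mask])
        else:
            value = sum_of_variances(ord.scores[mask])
        rows.append({"interval": name, "n": n, "metric": metric, "disparity": value})
    return pd.DataFrame(rows)
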