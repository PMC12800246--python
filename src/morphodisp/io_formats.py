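"""Readers and writers for TPS landmark files, slider definitions and species metadata.

The TPS dialect handled here is the flat 2D one produced by landmark
digitising tools: an ``LM=k`` count line, ``k`` whitespace-separated
coordinate rows, then optional ``ID=``, ``IMAGE=`` and ``SCALE=`` key lines.
``SCALE`` is a units-per-coordinate factor and is applied on read, so
in-memory coordinates are always in physical units. Slider definitions are a
three-column CSV of ``before,slider,after`` point indices (0-based by
default; pass ``one_based=True`` for tables exported from R workflows, which
index from 1). Species metadata is a CSV with a fixed header; group and
habitat vocabularies are closed and validated on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight clades of early sarcopterygians used as grouping vocabulary.
GROUPS = (
    "Onychodontida",
    "Actinistia",
    "Porolepiformes",
    "Dipnoi",
    "Rhizodontida",
    "Osteolepiformes",
    "Elpistostegalia",
    "Tetrapoda",
)

#: Broad aquatic habitat categories along the salinity gradient.
HABITATS = ("marine", "estuarine", "freshwater")

#: Fine palaeoenvironment categories; may be absent for a species.
PALAEOENVIRONMENTS = (
    "reef",
    "coastal marine",
    "bay",
    "estuary",
    "lagoon",
    "fluvial delta",
    "alluvial plain",
    "oxbow lake and meandering river",
    "calm freshwater lake",
    "dynamic freshwater lake",
)

METADATA_COLUMNS = (
    "species",
    "group",
    "habitat",
    "palaeoenvironment",
    "locality",
    "fad_ma",
    "lad_ma",
    "ontogeny",
)


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed into landmark configurations."""


class MetadataValidationError(ValueError):
    """Raised when a species metadata table violates the schema."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2D landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Identifier taken from the ``ID=`` (preferred) or ``IMAGE=`` line.
    points : (k, 2) ndarray
        Landmark coordinates, scale already applied. y increases upward.
    scale : float, optional
        Units-per-coordinate factor recorded in the source file, if any.
    semilandmark_flags : (k,) bool ndarray, optional
        True where a point is a sliding semi-landmark. Defaults to all fixed.
    """

    specimen_id: str
    points: np.ndarray
    scale: float | None = None
    semilandmark_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id!r}: points must be (k, 2), got {self.points.shape}"
            )
        if self.k < 3:
            raise ValueError(f"{self.specimen_id!r}: need at least 3 landmarks, got {self.k}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id!r}: non-finite coordinate (missing landmarks are unsupported)")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"{self.specimen_id!r}: SCALE must be positive")
        if self.semilandmark_flags is None:
            self.semilandmark_flags = np.zeros(self.k, dtype=bool)
        else:
            self.semilandmark_flags = np.asarray(self.semilandmark_flags, dtype=bool)
            if self.semilandmark_flags.shape != (self.k,):
                raise ValueError(f"{self.specimen_id!r}: semilandmark_flags length mismatch")

    @property
    def k(self) -> int:
        """Total number of landmarks (fixed + semi)."""
        return self.points.shape[0]

    @property
    def k_fixed(self) -> int:
        """Number of fixed (non-sliding) landmarks."""
        return int((~self.semilandmark_flags).sum())

    @property
    def k_semi(self) -> int:
        return int(self.semilandmark_flags.sum())


@dataclass
class SliderDefinition:
    """Curve topology for sliding semi-landmarks.

    Each triple ``(before, slider, after)`` names the point that slides and
    its two neighbours along the outline curve. A terminal semi-landmark with
    a single neighbour is encoded with ``-1`` in the missing slot.
    """

    triples: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.triples = [(int(b), int(s), int(a)) for b, s, a in self.triples]
        for b, s, a in self.triples:
            if s in (b, a):
                raise ValueError(f"slider {s} listed as its own neighbour")
            if b < 0 and a < 0:
                raise ValueError(f"slider {s} has no neighbours")

    @property
    def slider_indices(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.triples], dtype=int)

    def validate_against(self, config: LandmarkConfiguration) -> None:
        """Check indices fit the configuration and sliders are flagged semi."""
        k = config.k
        for b, s, a in self.triples:
            for idx in (b, s, a):
                if idx >= k:
                    raise ValueError(
                        f"slider triple ({b},{s},{a}) references point {idx} but k={k}"
                    )
            if not config.semilandmark_flags[s]:
                raise ValueError(
                    f"point {s} appears as a slider but is not flagged as a semi-landmark"
                )


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    ``SCALE=`` is applied (coordinates multiplied) when present. The
    identifier is taken from ``ID=`` when present, else ``IMAGE=``, else the
    record's ordinal position. Unknown key lines are ignored with a warning.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text(encoding="utf-8").splitlines()

    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path}: line {i + 1}: expected 'LM=' record start, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}: line {i + 1}: bad LM count {line!r}") from exc
        record_no += 1
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row and not _looks_numeric(row):
                break  # key line reached before k rows: count mismatch
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(f"{path}: line {i + 1}: expected two coordinates, got {row!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"{path}: line {i + 1}: non-numeric coordinate in {row!r}") from exc
            i += 1
        if len(coords) != k:
            raise TPSParseError(
                f"{path}: record {record_no}: LM={k} but found {len(coords)} coordinate rows"
            )
        # trailing key lines of this record
        spec_id: str | None = None
        image: str | None = None
        scale: float | None = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise TPSParseError(f"{path}: line {i + 1}: unexpected row {row!r}")
            key, value = row.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "IMAGE":
                image = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(f"{path}: line {i + 1}: bad SCALE {value!r}") from exc
            else:
                logger.warning("%s: ignoring unknown TPS key line %r", path, row)
            i += 1
        points = np.asarray(coords, dtype=float)
        if scale is not None:
            points = points * scale
        identifier = spec_id if spec_id is not None else (image if image is not None else str(record_no))
        configs.append(LandmarkConfiguration(identifier, points, scale=scale))
    return configs


def _looks_numeric(row: str) -> bool:
    parts = row.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> Path:
    """Write configurations to a TPS file, losslessly round-trippable by :func:`read_tps`.

    Coordinates are divided by the recorded scale before writing (with the
    ``SCALE=`` line restored) so a read immediately recovers the stored
    physical coordinates. All configurations must share the same number of
    landmarks.
    """
    path = Path(path)
    ks = {c.k for c in configs}
    if len(ks) > 1:
        offenders = ", ".join(f"{c.specimen_id}(k={c.k})" for c in configs)
        raise ValueError(f"heterogeneous landmark counts: {offenders}")
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        pts = c.points if c.scale is None else c.points / c.scale
        for x, y in pts:
            out.append(f"{x:.17g} {y:.17g}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.17g}")
    path.write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")
    return path


def read_sliders(path: str | Path, one_based: bool = False) -> SliderDefinition:
    """Read a slider-definition CSV with columns ``before,slider,after``.

    Indices are 0-based unless ``one_based`` is set (R morphometrics tools
    export 1-based tables), in which case 1 is subtracted from every index.
    A missing terminal neighbour is encoded as ``-1`` (or ``0`` in 1-based files).
    """
    df = pd.read_csv(path)
    expected = ["before", "slider", "after"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: slider file must have columns {expected}, got {list(df.columns)}")
    arr = df[expected].to_numpy(dtype=int)
    if one_based:
        arr = arr - 1  # maps the 0 "absent" sentinel to -1
    return SliderDefinition([tuple(row) for row in arr])


def write_sliders(sliders: SliderDefinition, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(sliders.triples, columns=["before", "slider", "after"]).to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a species metadata CSV.

    Returns a DataFrame with columns ``species, group, habitat,
    palaeoenvironment, locality, fad_ma, lad_ma, ontogeny``. Validation is
    all-or-nothing: every invalid row is reported (no silent drops).
    """
    df = pd.read_csv(path, dtype={"species": str, "locality": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataValidationError(f"{path}: missing metadata columns {missing}")
    return validate_metadata(df, source=str(path))


def validate_metadata(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate vocabularies and age ordering; raise listing every bad row."""
    errors: list[str] = []
    df = df.copy()
    df["fad_ma"] = pd.to_numeric(df["fad_ma"], errors="coerce")
    df["lad_ma"] = pd.to_numeric(df["lad_ma"], errors="coerce")
    for _, row in df.iterrows():
        sp = row["species"]
        if row["group"] not in GROUPS:
            errors.append(f"{sp}: unknown group {row['group']!r}")
        if row["habitat"] not in HABITATS:
            errors.append(f"{sp}: unknown habitat {row['habitat']!r}")
        env = row["palaeoenvironment"]
        if not (pd.isna(env) or env == "" or env in PALAEOENVIRONMENTS):
            errors.append(f"{sp}: unknown palaeoenvironment {env!r}")
        if pd.isna(row["fad_ma"]) or pd.isna(row["lad_ma"]):
            errors.append(f"{sp}: non-numeric occurrence age")
        elif row["fad_ma"] < row["lad_ma"]:
            errors.append(
                f"{sp}: fad_ma ({row['fad_ma']}) < lad_ma ({row['lad_ma']}); ages must decrease toward present"
            )
    if errors:
        raise MetadataValidationError(
            f"{source}: {len(errors)} invalid metadata row(s):\n  " + "\n  ".join(errors)
        )
    df["palaeoenvironment"] = df["palaeoenvironment"].replace("", np.nan)
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=list(METADATA_COLUMNS))
    return path


def validate_bundle(
    configs: Sequence[LandmarkConfiguration],
    sliders: SliderDefinition | None,
    metadata: pd.DataFrame,
) -> None:
    """Cross-file consistency: shared k, slider indices valid, ids covered by metadata."""
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"landmark configurations disagree on k: {sorted(ks)}")
    if sliders is not None and configs:
        for c in configs:
            c.semilandmark_flags[sliders.slider_indices] = True
        sliders.validate_against(configs[0])
    ids = {c.specimen_id for c in configs}
    known = set(metadata["species"])
    orphans = sorted(ids - known)
    if orphans:
        raise ValueError(f"specimens without metadata: {orphans}")
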