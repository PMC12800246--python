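"""Synthetic landmark datasets with known ground truth.

Generates samples that mimic the statistical structure of a 2D
geometric-morphometric study of Palaeozoic fishes: a fish-like outline
template of fixed landmarks plus sliding semi-landmarks, group-specific
mean-shape offsets, isotropic digitisation noise, stratigraphic ranges
inside the 425.6-298.9 Ma study window, locality labels including a planted
fossil-Lagerstaette, and a random similarity transform (rotation,
translation, scaling) per specimen so that superimposition is actually
exercised. Because the truth (offsets, noise levels, ranges) is known,
every downstream statistic has a recovery target.

Noise is applied to the shape BEFORE the similarity transform, so
digitisation error lives in shape units and superimposition is expected to
remove the transform, not the noise. Group offsets are centred (no net
translation) and size-neutral (orthogonal to the uniform-scaling direction)
so the planted effects survive superimposition.

The default census mirrors the study conditions: 36 species in 8 clades
(including one single-species and one two-species group), three aquatic
habitats, ten palaeoenvironment categories, and one Lagerstaette locality
concentrated in a narrow late time slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GROUPS,
    HABITATS,
    PALAEOENVIRONMENTS,
    LandmarkConfiguration,
    SliderDefinition,
    write_metadata,
    write_sliders,
    write_tps,
)
from .superimposition import centroid_size

#: Default number of species per clade (sums to 36, includes n=1 and n=2 groups).
DEFAULT_CENSUS: dict[str, int] = {
    "Onychodontida": 1,
    "Actinistia": 6,
    "Porolepiformes": 4,
    "Dipnoi": 6,
    "Rhizodontida": 2,
    "Osteolepiformes": 12,
    "Elpistostegalia": 1,
    "Tetrapoda": 4,
}

#: Study window, Ma.
WINDOW = (425.6, 298.9)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    ``group_offsets`` maps group to a flattened (2k,) deformation vector;
    ``noise_sd`` to the isotropic per-coordinate digitisation noise sd (in
    shape units of the unit-centroid-size template). Offsets are centred and
    size-neutral by construction.
    """

    mean_shape: np.ndarray
    group_offsets: dict[str, np.ndarray]
    noise_sd: dict[str, float]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    locality: dict[str, str] = field(default_factory=dict)
    species_noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "mean_shape": self.mean_shape.tolist(),
            "group_offsets": {g: v.tolist() for g, v in self.group_offsets.items()},
            "noise_sd": self.noise_sd,
            "ranges": {s: list(r) for s, r in self.ranges.items()},
            "locality": self.locality,
            "species_noise_sd": self.species_noise_sd,
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path


def fish_outline(t: np.ndarray) -> np.ndarray:
    """Closed fusiform outline with a caudal notch, parameterised on [0, 1).

    A deliberately simple body plan: an ellipse elongated along x, depth
    modulated to thin toward the tail, with a notch at the caudal end. Not
    an anatomical model — just a smooth, asymmetric closed curve on which
    outline semi-landmarks make sense.
    """
    theta = 2 * np.pi * t
    x = np.cos(theta)
    depth = 0.35 * (1 - 0.45 * np.cos(theta))
    y = depth * np.sin(theta)
    # caudal notch near theta = pi (the tail end)
    notch = 0.12 * np.exp(-((np.mod(theta, 2 * np.pi) - np.pi) ** 2) / 0.08)
    x = x + notch
    return np.column_stack([x, y])


def make_outline_scheme(
    k_fixed: int, k_semi: int
) -> tuple[LandmarkConfiguration, SliderDefinition]:
    """Outline template plus slider topology.

    Fixed landmarks sit at ``k_fixed`` equally spaced positions along the
    outline (anatomical extremes: snout, fin insertions, caudal notch);
    ``k_semi`` semi-landmarks fill the arcs between them. Every
    semi-landmark's slider triple references its two adjacent outline
    points (fixed or semi), so sliding follows the curve. The template is
    scaled to unit centroid size.
    """
    if k_fixed < 3:
        raise ValueError("need at least 3 fixed landmarks")
    if k_semi < 0:
        raise ValueError("k_semi must be nonnegative")
    k = k_fixed + k_semi
    t = np.arange(k) / k
    pts = fish_outline(t)
    pts = pts - pts.mean(axis=0)
    pts /= centroid_size(pts)

    # mark k_fixed approximately equally spaced outline positions as fixed
    fixed_pos = np.unique(np.round(np.linspace(0, k, k_fixed, endpoint=False)).astype(int) % k)
    # rounding collisions are possible only when k_semi is tiny; spread them out
    while len(fixed_pos) < k_fixed:
        candidates = np.setdiff1d(np.arange(k), fixed_pos)
        fixed_pos = np.sort(np.append(fixed_pos, candidates[0]))
    flags = np.ones(k, dtype=bool)
    flags[fixed_pos] = False

    triples = [
        (int((i - 1) % k), int(i), int((i + 1) % k)) for i in range(k) if flags[i]
    ]
    template = LandmarkConfiguration("template", pts, semilandmark_flags=flags)
    return template, SliderDefinition(triples)


def _neutralize_offset(offset: np.ndarray, mean_flat: np.ndarray, k: int) -> np.ndarray:
    """Remove net translation and the uniform-scaling component from an offset."""
    v = offset.reshape(k, 2)
    v = v - v.mean(axis=0)
    v = v.ravel()
    scale_dir = mean_flat / np.linalg.norm(mean_flat)
    v = v - (v @ scale_dir) * scale_dir
    return v


def default_truth(
    template: LandmarkConfiguration | None = None,
    census: dict[str, int] | None = None,
    offset_magnitude: float = 0.08,
    noise_sd: float | dict[str, float] = 0.02,
    seed: int = 0,
    lagerstatte_locality: str = "Varved Gulch",
    lagerstatte_window: tuple[float, float] = (330.9, 323.2),
) -> tuple[SimulationTruth, dict[str, int]]:
    """Build the default study-shaped simulation truth.

    Each clade receives a random centred, size-neutral mean-shape offset of
    norm ``offset_magnitude`` (shape units) and an isotropic digitisation
    noise sd (0.02 shape units by default, roughly 2% of configuration
    size — a realistic digitisation error). Stratigraphic ranges are drawn
    inside the study window; species of the Lagerstaette locality get FADs
    inside ``lagerstatte_window`` (a Serpukhovian-like slice by default).
    """
    rng = np.random.default_rng(seed)
    if template is None:
        template, _ = make_outline_scheme(11, 25)
    census = dict(census or DEFAULT_CENSUS)
    k = template.k
    mean_flat = template.points.ravel()

    offsets: dict[str, np.ndarray] = {}
    sds: dict[str, float] = {}
    for g in census:
        raw = rng.standard_normal(2 * k)
        v = _neutralize_offset(raw, mean_flat, k)
        offsets[g] = v / np.linalg.norm(v) * offset_magnitude
        sds[g] = noise_sd[g] if isinstance(noise_sd, dict) else float(noise_sd)

    ranges: dict[str, tuple[float, float]] = {}
    locality: dict[str, str] = {}
    localities = ["Redbed Creek", "Old Quarry", "Shale Point", lagerstatte_locality]
    i_species = 0
    for g, n_g in census.items():
        for _ in range(n_g):
            name = f"sp{i_species:03d}_{g[:4]}"
            loc = localities[i_species % 3]
            if i_species % 7 == 3:
                loc = lagerstatte_locality
            if loc == lagerstatte_locality:
                fad = rng.uniform(lagerstatte_window[1], lagerstatte_window[0])
            else:
                fad = rng.uniform(WINDOW[1] + 5.0, WINDOW[0])
            duration = rng.uniform(0.5, 15.0)
            lad = max(fad - duration, WINDOW[1])
            ranges[name] = (float(fad), float(lad))
            locality[name] = loc
            i_species += 1
    truth = SimulationTruth(
        mean_shape=template.points.copy(),
        group_offsets=offsets,
        noise_sd=sds,
        ranges=ranges,
        locality=locality,
        seed=seed,
    )
    return truth, census


def simulate_dataset(
    truth: SimulationTruth,
    n_per_group: dict[str, int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Draw one landmark dataset from a simulation truth.

    Each species' shape is ``mean + group offset + isotropic noise``, then
    randomly rotated, translated and scaled. Returns the configurations and
    a metadata table (group, habitat, palaeoenvironment, locality, FAD/LAD).
    Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    k = truth.k
    mean_flat = truth.mean_shape.ravel()

    configs: list[LandmarkConfiguration] = []
    meta_rows: list[dict] = []
    species_names = list(truth.ranges)
    i_species = 0
    for g, n_g in n_per_group.items():
        if n_g < 1:
            raise ValueError(f"group {g!r} is empty")
        for _ in range(n_g):
            name = (
                species_names[i_species]
                if i_species < len(species_names)
                else f"sp{i_species:03d}_{g[:4]}"
            )
            sd = truth.species_noise_sd.get(name, truth.noise_sd[g])
            flat = mean_flat + truth.group_offsets[g] + rng.normal(0, sd, 2 * k)
            shape = flat.reshape(k, 2)
            # random similarity transform: digitised position/size/orientation
            angle = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
            scale = rng.uniform(0.5, 3.0)
            shift = rng.uniform(-5, 5, size=2)
            observed = shape @ R.T * scale + shift
            configs.append(LandmarkConfiguration(name, observed))

            fad, lad = truth.ranges.get(name, (WINDOW[0], WINDOW[1]))
            habitat = HABITATS[i_species % 3]
            env = PALAEOENVIRONMENTS[i_species % len(PALAEOENVIRONMENTS)] if i_species % 4 else None
            meta_rows.append(
                {
                    "species": name,
                    "group": g,
                    "habitat": habitat,
                    "palaeoenvironment": env,
                    "locality": truth.locality.get(name, "Redbed Creek"),
                    "fad_ma": fad,
                    "lad_ma": lad,
                    "ontogeny": "adult",
                }
            )
            i_species += 1
    return configs, pd.DataFrame(meta_rows)


def write_bundle(
    configs: list[LandmarkConfiguration],
    sliders: SliderDefinition,
    meta: pd.DataFrame,
    outdir: str | Path,
    truth: SimulationTruth | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": write_tps(configs, outdir / "landmarks.tps"),
        "sliders": write_sliders(sliders, outdir / "sliders.csv"),
        "metadata": write_metadata(meta, outdir / "metadata.csv"),
    }
    if truth is not None:
        paths["truth"] = truth.to_json(outdir / "truth.json")
    return paths


def planted_lagerstatte_truth(
    seed: int = 0,
    boost: float = 4.0,
    lagerstatte_locality: str = "Varved Gulch",
    lagerstatte_window: tuple[float, float] = (330.9, 323.2),
    n_lagerstatte: int = 5,
    n_background_in_window: int = 3,
    **kwargs,
) -> tuple[SimulationTruth, dict[str, int]]:
    """Truth where one locality contributes all the extreme shapes of one bin.

    Species at the Lagerstaette receive digitisation/shape noise ``boost``
    times the background sd and FADs concentrated inside the Lagerstaette
    window; ``n_background_in_window`` ordinary species share that window so
    the bin still has a defined disparity after exclusion. Used to study the
    bias that exceptional-preservation deposits impose on disparity curves.
    """
    truth, census = default_truth(
        seed=seed,
        lagerstatte_locality=lagerstatte_locality,
        lagerstatte_window=lagerstatte_window,
        **kwargs,
    )
    rng = np.random.default_rng(seed + 1)
    names = list(truth.ranges)
    # reassign localities/ranges deterministically: first n_lagerstatte species
    # become the Lagerstaette sample, the next few are background in-window
    in_window = lambda: float(rng.uniform(lagerstatte_window[1], lagerstatte_window[0]))
    out_window = lambda: float(rng.uniform(WINDOW[1] + 5.0, lagerstatte_window[0] + 10.0))
    base_sd = max(truth.noise_sd.values())
    for i, name in enumerate(names):
        if i < n_lagerstatte:
            truth.locality[name] = lagerstatte_locality
            fad = in_window()
            truth.species_noise_sd[name] = base_sd * boost
        elif i < n_lagerstatte + n_background_in_window:
            truth.locality[name] = "Redbed Creek"
            fad = in_window()
        else:
            truth.locality[name] = ["Redbed Creek", "Old Quarry", "Shale Point"][i % 3]
            fad = out_window()
            while lagerstatte_window[1] <= fad <= lagerstatte_window[0]:
                fad = out_window()
        truth.ranges[name] = (fad, max(fad - float(rng.uniform(0.5, 6.0)), WINDOW[1]))
    return truth, census


def expected_pv(truth: SimulationTruth, group: str) -> float:
    """Analytic within-group Procrustes variance for isotropic noise.

    Superimposition removes 4 of the 2k coordinate degrees of freedom
    (2 translation, 1 rotation, 1 scale), so isotropic per-coordinate noise
    of sd s on a unit-centroid-size template yields a Procrustes variance of
    approximately ``(s / CS)^2 * (2k - 4)`` where CS is the template
    centroid size. An approximation for small noise; recovery tests use a
    10-15% tolerance.
    """
    if group not in truth.noise_sd:
        raise KeyError(f"unknown group {group!r}")
    s = truth.noise_sd[group] / centroid_size(truth.mean_shape)
    return s**2 * (2 * truth.k - 4)
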