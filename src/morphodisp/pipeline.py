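"""Orchestration of the full disparity analysis.

One call runs, for a dataset: superimposition (with sliding
semi-landmarks), PCA ordination, per-group disparity tables for each
requested grouping variable (clade, epoch of appearance, habitat,
palaeoenvironment), disparity-through-time curves on both the epoch scale
and an equal-width binning, and range-through richness. A locality
jackknife re-runs the whole analysis from scratch without the species of
one locality (superimposition depends on the sample, so excluded species
must not influence the consensus) and reports the paired curves.

All randomness flows from the single configured seed through named
per-stage substreams, so any stage is individually reproducible. The run
log records the seed, input file hashes and package versions needed to
reproduce every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronology import (
    SPAN_END_MA,
    SPAN_START_MA,
    TimeScale,
    assign_intervals,
    default_epochs,
    default_stages,
    disparity_through_time,
    equal_bins,
    range_through_richness,
)
from .disparity import DisparityTable, disparity_table
from .io_formats import (
    read_metadata,
    read_sliders,
    read_tps,
    validate_bundle,
)
from .ordination import Ordination, pca
from .superimposition import AlignedSample, gpa

logger = logging.getLogger(__name__)

GROUPING_VARIABLES = ("group", "epoch", "habitat", "palaeoenvironment")


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    tps: str | Path
    sliders: str | Path | None
    metadata: str | Path
    timescale: str | Path | None = None
    groupings: tuple[str, ...] = GROUPING_VARIABLES
    n_permutations: int = 999
    seed: int = 0
    n_pcs_weighted: int = 5
    tangent_projection: bool = False
    sliders_one_based: bool = False
    jackknife_localities: tuple[str, ...] = ()
    n_bins: int = 7
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        bad = [g for g in self.groupings if g not in GROUPING_VARIABLES]
        if bad:
            raise ValueError(f"unknown grouping variables {bad}; choose from {GROUPING_VARIABLES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("groupings", "jackknife_localities"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisResult:
    """In-memory bundle of everything one run computed."""

    sample: AlignedSample
    ordination: Ordination
    disparity: dict[str, DisparityTable]
    dtt_epochs: pd.DataFrame
    dtt_bins: pd.DataFrame
    richness: pd.DataFrame
    metadata: pd.DataFrame
    run_log: dict


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent, reproducible generator per pipeline stage."""
    digest = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(digest,)))


def _subset_ordination(ord: Ordination, mask: np.ndarray) -> Ordination:
    """Row subset of one joint ordination (axes and variance shares unchanged)."""
    return Ordination(
        scores=ord.scores[mask],
        eigenvalues=ord.eigenvalues,
        prop_variance=ord.prop_variance,
        loadings=ord.loadings,
        mean_vector=ord.mean_vector,
        specimen_ids=[sid for sid, m in zip(ord.specimen_ids, mask) if m],
    )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _analyse(
    configs,
    sliders,
    meta: pd.DataFrame,
    config: RunConfig,
    epochs: TimeScale,
) -> AnalysisResult:
    sample = gpa(configs, sliders=sliders)
    ordination = pca(sample, tangent_projection=config.tangent_projection)

    meta_by_species = meta.set_index("species").loc[sample.specimen_ids].reset_index()
    epoch_labels = assign_intervals(meta_by_species, epochs)

    disparity: dict[str, DisparityTable] = {}
    for var in config.groupings:
        if var == "epoch":
            labels = epoch_labels
        else:
            labels = meta_by_species[var]
        mask = labels.notna().to_numpy()
        if mask.sum() < 3 or pd.Series(labels[mask]).nunique() < 2:
            logger.warning("grouping %r has too few labelled species; skipped", var)
            continue
        sub_sample = sample.subset(mask)
        sub_ord = _subset_ordination(ordination, mask) if mask.sum() < sample.n else ordination
        disparity[var] = disparity_table(
            sub_sample,
            sub_ord,
            np.asarray(labels[mask]),
            n_perm=config.n_permutations,
            rng=_substream(config.seed, f"permutation:{var}"),
            n_pcs_weighted=config.n_pcs_weighted,
        )

    bins = equal_bins(SPAN_START_MA, SPAN_END_MA, config.n_bins)
    dtt_epochs = disparity_through_time(sample, ordination, meta, epochs, "procrustes_variance")
    dtt_bins = disparity_through_time(sample, ordination, meta, bins, "sum_of_variances")
    richness = range_through_richness(meta, default_stages())

    run_log = {
        "package": "morphodisp",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "n_specimens": sample.n,
        "converged": bool(sample.converged),
    }
    return AnalysisResult(sample, ordination, disparity, dtt_epochs, dtt_bins, richness, meta, run_log)


def run_analysis(config: RunConfig, write: bool = True) -> AnalysisResult:
    """Run the full pipeline described by ``config``.

    Reads and cross-validates the inputs, then aligns, ordinates, computes
    every requested disparity table and both disparity-through-time curves,
    and the range-through richness curve. With ``write=True`` (and an
    ``outdir`` set) all artifacts are written as CSV plus a JSON run log.
    """
    configs = read_tps(config.tps)
    sliders = (
        read_sliders(config.sliders, one_based=config.sliders_one_based)
        if config.sliders
        else None
    )
    meta = read_metadata(config.metadata)
    validate_bundle(configs, sliders, meta)
    epochs = (
        TimeScale.from_csv(config.timescale, level="epoch")
        if config.timescale
        else default_epochs()
    )
    result = _analyse(configs, sliders, meta, config, epochs)
    result.run_log["inputs"] = {
        "tps": _sha256(config.tps),
        "metadata": _sha256(config.metadata),
        **({"sliders": _sha256(config.sliders)} if config.sliders else {}),
    }
    if write and config.outdir is not None:
        write_results(result, config.outdir)
    return result


def write_results(result: AnalysisResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, k = result.sample.n, result.sample.k
    aligned = pd.DataFrame(
        {
            "specimen": np.repeat(result.sample.specimen_ids, k),
            "point": np.tile(np.arange(k), n),
            "x": result.sample.coords[:, :, 0].ravel(),
            "y": result.sample.coords[:, :, 1].ravel(),
        }
    )
    aligned.to_csv(outdir / "aligned.csv", index=False)
    pd.DataFrame(result.sample.consensus, columns=["x", "y"]).to_csv(
        outdir / "consensus.csv", index_label="point"
    )
    result.ordination.scores_frame().to_csv(outdir / "scores.csv", index_label="specimen")
    pd.DataFrame(
        {
            "eigenvalue": result.ordination.eigenvalues,
            "prop_variance": result.ordination.prop_variance,
        }
    ).to_csv(outdir / "eigenvalues.csv", index_label="axis")
    for var, table in result.disparity.items():
        table.to_frame().to_csv(outdir / f"disparity_{var}.csv", index=False)
        table.pairwise_abs_diff.to_csv(outdir / f"pairwise_diff_{var}.csv")
        table.pairwise_p.to_csv(outdir / f"pairwise_p_{var}.csv")
    result.dtt_epochs.to_csv(outdir / "dtt_epochs.csv", index=False)
    result.dtt_bins.to_csv(outdir / "dtt_bins.csv", index=False)
    result.richness.to_csv(outdir / "richness.csv", index=False)
    (outdir / "run_log.json").write_text(json.dumps(result.run_log, indent=1), encoding="utf-8")


def jackknife_locality(
    config: RunConfig, locality: str, write: bool = True
) -> tuple[AnalysisResult, AnalysisResult | None, pd.DataFrame]:
    """Re-run the full analysis with and without one locality's species.

    Superimposition is repeated from scratch on the reduced sample (the
    consensus, and with it every aligned coordinate, depends on sample
    composition). Returns (baseline, jackknifed, difference table of the
    epoch disparity curves); the jackknifed result is None when the
    locality matches no species, in which case the difference is zero.
    """
    base_outdir = Path(config.outdir) if config.outdir else None
    baseline = run_analysis(
        RunConfig(**{**config.__dict__, "outdir": base_outdir / "baseline" if base_outdir and write else None})
    )
    meta = baseline.metadata
    excluded_mask = meta["locality"] == locality
    if not excluded_mask.any():
        logger.warning("locality %r matches no species; jackknife is a no-op", locality)
        diff = baseline.dtt_epochs.assign(disparity_excluded=baseline.dtt_epochs["disparity"], difference=0.0)
        return baseline, None, diff

    keep_species = set(meta.loc[~excluded_mask, "species"])
    configs = [c for c in read_tps(config.tps) if c.specimen_id in keep_species]
    if len(configs) < 3:
        raise ValueError(
            f"excluding locality {locality!r} leaves {len(configs)} species (< 3); dataset aborted"
        )
    sliders = (
        read_sliders(config.sliders, one_based=config.sliders_one_based)
        if config.sliders
        else None
    )
    sub_meta = meta.loc[~excluded_mask].reset_index(drop=True)
    epochs = (
        TimeScale.from_csv(config.timescale, level="epoch")
        if config.timescale
        else default_epochs()
    )
    jack = _analyse(configs, sliders, sub_meta, config, epochs)

    diff = baseline.dtt_epochs.merge(
        jack.dtt_epochs[["interval", "n", "disparity"]],
        on="interval",
        suffixes=("", "_excluded"),
    )
    diff["difference"] = diff["disparity"] - diff["disparity_excluded"]
    if write and base_outdir is not None:
        write_results(jack, base_outdir / f"jackknife_{locality.replace(' ', '_')}")
        diff.to_csv(base_outdir / f"jackknife_{locality.replace(' ', '_')}_difference.csv", index=False)
    return baseline, jack, diff
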