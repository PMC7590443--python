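"""End-to-end orchestration of the two analyses.

``run_signal`` chains filtering -> species means -> relative amounts ->
(optional class aggregation) -> Bray-Curtis -> PCoA -> Kmult with a
permutation test, writing every intermediate as plain delimited text or
Newick so downstream R users can pick the pipeline apart.  ``run_devcorr``
chains pairing -> per-class Spearman -> weighted mean.  Each dataset (site)
is analysed separately; there is deliberately no pooling command.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from fruitscent import devcorr as _devcorr
from fruitscent import ordination as _ord
from fruitscent import physignal as _sig
from fruitscent import voctable as _voc

__all__ = ["RunConfig", "run_signal", "run_devcorr",
           "analyze_signal", "analyze_devcorr"]

LEVELS = ("compound", "class")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (one dataset, one level)."""

    scent_table: str
    tree: str | None = None
    class_map: str | None = None
    unripe_table: str | None = None
    dataset: str = "dataset"
    level: str = "compound"
    control_samples: tuple[str, ...] = ()
    apply_filter: bool = False
    ubiquity_threshold: float = 0.9
    rare_sample_fraction: float = 0.25
    max_share_threshold: float = 0.01
    normalize_per_sample: bool = False
    n_perm: int = 1000
    seed: int = 0
    linkage: str = "UPGMA"
    eigen_tolerance: float = 1e-8
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")


def _species_profile(
    table: _voc.ScentTable,
    classmap: _voc.ClassMap | None,
    level: str,
    normalize_per_sample: bool,
) -> _voc.SpeciesProfile:
    """Mean-then-normalise species profile (or normalise-then-mean variant)."""
    if normalize_per_sample:
        rel = _voc.relative_amounts(table.amounts, level="compound")
        means = rel.values.groupby(table.species_of, observed=True).mean().sort_index()
        totals = means.sum(axis=1)
        means = means.divide(totals.where(totals > 0, 1.0), axis=0)
        profile = _voc.SpeciesProfile(means, level="compound")
    else:
        means = _voc.species_means(table)
        profile = _voc.relative_amounts(means, level="compound")
    if level == "class":
        if classmap is None:
            raise ValueError("class-level analysis needs a class map")
        profile = _voc.aggregate_classes(profile, classmap)
    return profile


@dataclass
class SignalRun:
    """In-memory result bundle of a phylogenetic-signal analysis."""

    result: _sig.SignalResult
    profile: _voc.SpeciesProfile
    distances: _ord.DistanceMatrix
    scores: _ord.OrdinationScores
    dendrogram: _ord.Dendrogram
    pruned_tree: dendropy.Tree
    match_report: _sig.MatchReport
    removal_log: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_signal(
    table: _voc.ScentTable,
    tree: dendropy.Tree,
    classmap: _voc.ClassMap | None = None,
    level: str = "compound",
    n_perm: int = 1000,
    seed: int = 0,
    linkage: str = "UPGMA",
    eigen_tolerance: float = 1e-8,
    normalize_per_sample: bool = False,
    removal_log: pd.DataFrame | None = None,
) -> SignalRun:
    """Phylogenetic-signal analysis on in-memory objects (library surface)."""
    profile = _species_profile(table, classmap, level, normalize_per_sample)
    pruned, report = _sig.prune_and_match(tree, profile.species)
    matched = sorted(report.matched)
    profile = _voc.SpeciesProfile(
        profile.values.loc[matched], level=profile.level,
        zero_rows=[s for s in profile.zero_rows if s in matched])
    dist = _ord.bray_curtis(profile)
    scores = _ord.pcoa(dist, eigen_tolerance=eigen_tolerance)
    if scores.scores.shape[1] == 0:
        raise ValueError(
            f"degenerate scent variation at {level} level: all species "
            "profiles are identical, no ordination axes to test"
        )
    cov = _sig.phylo_cov(pruned)
    tip_of = report.matched
    aligned = cov.align([tip_of[sp] for sp in matched])
    result = _sig.permutation_test(scores.scores, aligned, n_perm=n_perm, seed=seed)
    dendro = _ord.hierarchical_cluster(dist, linkage=linkage)
    return SignalRun(result, profile, dist, scores, dendro, pruned, report,
                     removal_log if removal_log is not None else pd.DataFrame())


def run_signal(config: RunConfig) -> SignalRun:
    """File-based phylogenetic-signal pipeline; writes all artifacts."""
    if config.tree is None:
        raise ValueError("signal analysis needs a tree")
    table = _voc.read_scent_table(config.scent_table)
    classmap = _voc.read_class_map(config.class_map) if config.class_map else None
    tree = _sig.read_tree(config.tree)

    removal_log = pd.DataFrame()
    if config.apply_filter or config.control_samples:
        table, removal_log = _voc.filter_compounds(
            table,
            control_samples=set(config.control_samples),
            ubiquity_threshold=config.ubiquity_threshold if config.apply_filter else None,
            rare_sample_fraction=config.rare_sample_fraction if config.apply_filter else None,
            max_share_threshold=config.max_share_threshold if config.apply_filter else None,
        )

    run = analyze_signal(
        table, tree, classmap=classmap, level=config.level,
        n_perm=config.n_perm, seed=config.seed, linkage=config.linkage,
        eigen_tolerance=config.eigen_tolerance,
        normalize_per_sample=config.normalize_per_sample,
        removal_log=removal_log,
    )

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{config.dataset}_{config.level}"
    run.distances.write(out / f"{stem}_braycurtis.tsv")
    run.scores.to_frame().to_csv(out / f"{stem}_pcoa_scores.tsv", sep="\t")
    (out / f"{stem}_dendrogram.nwk").write_text(run.dendrogram.newick() + "\n")
    _sig.write_tree(run.pruned_tree, out / f"{stem}_pruned_tree.nwk")
    (out / f"{stem}_leaf_order.txt").write_text(
        "\n".join(run.dendrogram.leaf_order()) + "\n")
    _voc.write_removal_log(run.removal_log, out / f"{stem}_removed_compounds.tsv")
    report = {
        "analysis": "phylogenetic_signal",
        "dataset": config.dataset,
        "level": config.level,
        "kmult": run.result.statistic,
        "p_value": run.result.p_value,
        "n_permutations": run.result.n_permutations,
        "seed": run.result.seed,
        "n_axes": run.result.n_axes,
        "n_species": len(run.profile.species),
        "unmatched_species": run.match_report.unmatched_species,
        "config": asdict(config),
    }
    (out / f"{stem}_signal.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return run


@dataclass
class DevCorrRun:
    """In-memory result bundle of a developmental-constraint analysis."""

    result: _devcorr.DevCorrResult
    paired: _devcorr.PairedClassProfiles


def analyze_devcorr(
    ripe: _voc.ScentTable,
    unripe: _voc.ScentTable,
    classmap: _voc.ClassMap,
    normalize_per_sample: bool = False,
    method: str = "t-approximation",
) -> DevCorrRun:
    """Ripe/unripe class-correlation analysis on in-memory objects."""
    ripe_prof = _species_profile(ripe, classmap, "class", normalize_per_sample)
    unripe_prof = _species_profile(unripe, classmap, "class", normalize_per_sample)
    paired = _devcorr.pair_ripe_unripe(ripe_prof, unripe_prof)
    result = _devcorr.spearman_by_class(paired, method=method)
    return DevCorrRun(result, paired)


def run_devcorr(config: RunConfig) -> DevCorrRun:
    """File-based developmental-constraint pipeline; writes all artifacts."""
    if config.unripe_table is None:
        raise ValueError("devcorr needs an unripe table")
    if config.class_map is None:
        raise ValueError("devcorr needs a class map")
    ripe = _voc.read_scent_table(config.scent_table)
    unripe = _voc.read_scent_table(config.unripe_table)
    classmap = _voc.read_class_map(config.class_map)
    run = analyze_devcorr(ripe, unripe, classmap,
                          normalize_per_sample=config.normalize_per_sample)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stem = config.dataset
    run.result.to_frame().to_csv(out / f"{stem}_class_correlations.tsv", sep="\t")
    report = {
        "analysis": "developmental_constraints",
        "dataset": config.dataset,
        "weighted_mean_rho": run.result.weighted_mean_rho,
        "n_species": run.result.n_species,
        "dropped_species": run.paired.dropped_species,
        "unknown_mean_share": run.paired.unknown_mean_share,
        "config": asdict(config),
    }
    (out / f"{stem}_devcorr.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return run
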