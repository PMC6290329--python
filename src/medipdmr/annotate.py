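"""Genomic feature annotation, cell-type marker filtering, and permutation
feature enrichment.

A region carries a feature flag iff it overlaps >= 1 bp of that feature's
track.  Regions overlapping both an exon and an intron are labelled
intron/exon boundaries; regions overlapping no gene body are intergenic.
Cell-type filtering removes regions lying within marker genes — genes whose
expression in one cell type is at least ``fold`` times the maximum across
the other types — since methylation changes there could reflect shifts in
cell-type proportions rather than true regulatory change.

Feature enrichment p-values are empirical: the observed per-feature count on
the query set is compared with counts on ``n_perm`` random same-size subsets
of the background region set (drawn without replacement), with the add-one
correction so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import RegionSet

__all__ = [
    "AnnotationDB",
    "FeatureProfile",
    "annotate",
    "derive_markers",
    "filter_celltype",
    "feature_enrichment",
]

FEATURE_TRACKS = ("cgi", "exon", "intron", "promoter_200", "promoter_1500", "utr5", "utr3", "gene")


@dataclass
class AnnotationDB:
    """Named feature tracks; the gene track's region_ids are gene ids.

    ``gene_strand`` maps gene id -> '+'/'-' (promoter placement is
    strand-aware; other feature assignment is not).
    """

    tracks: dict[str, RegionSet]
    gene_strand: "pd.Series | None" = None

    def __post_init__(self) -> None:
        for name, track in self.tracks.items():
            if not isinstance(track, RegionSet):
                self.tracks[name] = RegionSet(track)
        gene = self.tracks.get("gene")
        if gene is not None and gene.df["region_id"].duplicated().any():
            raise ValueError("gene ids must be unique")

    @classmethod
    def from_bed_files(cls, paths: Mapping[str, str]) -> "AnnotationDB":
        from .regions import read_bed

        return cls({name: read_bed(p) for name, p in paths.items()})

    def trees(self, name: str) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for rec in self.tracks[name]:
            out.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec.region_id)
        return out


@dataclass
class FeatureProfile:
    """Per-region boolean feature flags plus derived labels."""

    flags: pd.DataFrame  # region_id x feature (bool), incl. intergenic, intron_exon_boundary
    gene_hits: pd.Series  # region_id -> tuple of overlapping gene ids

    @property
    def counts(self) -> pd.Series:
        return self.flags.sum(axis=0)


def annotate(regions: RegionSet, db: AnnotationDB) -> FeatureProfile:
    """Flag each region with every feature it overlaps by >= 1 bp.

    Chromosomes absent from a track are treated as carrying no feature
    (hence intergenic when the gene track misses them).
    """
    track_names = [t for t in FEATURE_TRACKS if t in db.tracks]
    trees = {t: db.trees(t) for t in track_names}
    rows = {}
    gene_hits = {}
    for rec in regions:
        row = {}
        for t in track_names:
            chrom_tree = trees[t].get(rec.chrom)
            hits = chrom_tree.overlap(rec.start, rec.end) if chrom_tree else set()
            row[t] = bool(hits)
            if t == "gene":
                gene_hits[rec.region_id] = tuple(sorted(h.data for h in hits))
        row["intron_exon_boundary"] = row.get("exon", False) and row.get("intron", False)
        row["intergenic"] = not row.get("gene", False)
        rows[rec.region_id] = row
    flags = pd.DataFrame.from_dict(rows, orient="index").reindex(regions.region_ids)
    return FeatureProfile(flags=flags, gene_hits=pd.Series(gene_hits).reindex(regions.region_ids))


def derive_markers(expression: pd.DataFrame, fold: float = 1.5) -> dict[str, list[str]]:
    """Cell-type marker genes from a gene x cell-type expression table.

    A gene marks type t iff expression(t) >= fold * max(expression over the
    other types); ties at exactly the fold boundary are included (>=).
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    if (expression.to_numpy() <= 0).any():
        raise ValueError("expression values must be > 0")
    markers: dict[str, list[str]] = {t: [] for t in expression.columns}
    vals = expression.to_numpy(float)
    for j, t in enumerate(expression.columns):
        others = np.delete(vals, j, axis=1).max(axis=1)
        hit = vals[:, j] >= fold * others
        markers[t] = list(expression.index[hit])
    return markers


def filter_celltype(
    regions: RegionSet,
    markers: dict[str, list[str]],
    db: AnnotationDB,
) -> tuple[RegionSet, RegionSet]:
    """Split regions into (kept, removed) by overlap with marker gene bodies."""
    marker_ids = {g for genes in markers.values() for g in genes}
    gene_df = db.tracks["gene"].df
    marker_track = gene_df[gene_df["region_id"].isin(marker_ids)]
    trees: dict[str, IntervalTree] = {}
    for rec in marker_track.itertuples(index=False):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end)
    removed_mask = []
    for rec in regions:
        tree = trees.get(rec.chrom)
        removed_mask.append(bool(tree.overlap(rec.start, rec.end)) if tree else False)
    removed_mask = np.array(removed_mask, dtype=bool)
    kept = RegionSet(regions.df[~removed_mask])
    removed = RegionSet(regions.df[removed_mask])
    return kept, removed


def _empirical_p(null: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Add-one one-sided empirical p-values (enrichment, depletion)."""
    n_perm = null.shape[0]
    p_enrich = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    p_deplete = (1.0 + (null <= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return p_enrich, p_deplete


def feature_enrichment(
    dmrs: RegionSet,
    background: RegionSet,
    db: AnnotationDB,
    n_perm: int = 1000,
    seed: int = 0,
    profile: FeatureProfile | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of feature counts in a query set vs background.

    Null per-feature counts come from ``n_perm`` uniform same-size subsets of
    the background (without replacement).  Reports observed count, null mean
    and sd, one-sided enrichment/depletion p, and a two-sided p
    (min(1, 2*min of the one-sided pair)).
    """
    if len(dmrs) == 0:
        raise ValueError("empty query region set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bg_ids = set(background.df["region_id"])
    if not set(dmrs.df["region_id"]).issubset(bg_ids):
        raise ValueError("dmrs must be a subset of background")
    if len(background) < len(dmrs):
        raise ValueError("query set cannot exceed the background")

    if profile is None:
        profile = annotate(background, db)
    flags = profile.flags.astype(bool)
    feature_names = list(flags.columns)
    B = flags.to_numpy()
    bg_index = pd.Index(background.df["region_id"])
    dmr_pos = bg_index.get_indexer(dmrs.df["region_id"])
    obs = B[dmr_pos].sum(axis=0).astype(float)

    rng = np.random.default_rng(seed)
    k = len(dmrs)
    null = np.empty((n_perm, len(feature_names)))
    for i in range(n_perm):
        sub = rng.choice(len(background), size=k, replace=False)
        null[i] = B[sub].sum(axis=0)
    p_enrich, p_deplete = _empirical_p(null, obs)
    return pd.DataFrame(
        {
            "observed": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1),
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
            "p_two_sided": np.minimum(1.0, 2.0 * np.minimum(p_enrich, p_deplete)),
        },
        index=feature_names,
    )
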