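"""Genomic region sets and consensus-peak construction.

Per-sample peak calls (BED-like interval sets) are merged into a consensus
peakset: intervals sharing >= 1 bp across samples are clustered transitively
and each cluster is replaced by its union span.  Clusters supported by fewer
than ``min_samples`` distinct samples are dropped — the occupancy filter used
to build a common region set from individually called peaksets.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "OccupancyMatrix",
    "build_consensus",
    "count_in_regions",
    "read_bed",
]


class ValidationError(ValueError):
    """An interval record violates the coordinate contract."""


@dataclass
class RegionSet:
    """An ordered, validated set of genomic intervals.

    Wraps a DataFrame with columns chrom, start, end, region_id, sorted by
    (chrom, start).  start < end for every record; region_ids are unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = self.df.copy()
        if "region_id" not in df.columns:
            df["region_id"] = [f"region_{i}" for i in range(len(df))]
        df = df[["chrom", "start", "end", "region_id"]].reset_index(drop=True)
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            rec = bad.iloc[0]
            raise ValidationError(
                f"invalid interval {rec.chrom}:{rec.start}-{rec.end} ({rec.region_id}): start >= end"
            )
        if df["region_id"].duplicated().any():
            dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
            raise ValidationError(f"duplicate region_id: {dup}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    @property
    def region_ids(self) -> pd.Index:
        return pd.Index(self.df["region_id"])

    @property
    def lengths(self) -> pd.Series:
        out = (self.df["end"] - self.df["start"]).astype(float)
        out.index = self.df["region_id"]
        return out

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple], prefix: str = "region") -> "RegionSet":
        rows = []
        for i, iv in enumerate(intervals):
            if len(iv) >= 4:
                rows.append(iv[:4])
            else:
                rows.append((*iv[:3], f"{prefix}_{i}"))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3+ file; column 4, when present, becomes the region_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "region_id"][: df.shape[1]]
    return RegionSet(df)


@dataclass
class OccupancyMatrix:
    """Boolean region x sample membership with per-region support counts."""

    matrix: pd.DataFrame  # region_id x sample, bool

    @property
    def support(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def build_consensus(
    peaksets: Mapping[str, RegionSet] | Sequence[RegionSet],
    min_samples: int = 3,
) -> tuple[RegionSet, OccupancyMatrix]:
    """Merge per-sample peaksets into an occupancy-filtered consensus.

    Overlap rule: >= 1 bp shared.  Clusters are connected components of the
    overlap graph (found by a sorted sweep; cluster coverage is contiguous,
    so the sweep is exact); the consensus interval is the union span.  A
    sample supports a region iff one of its peaks belongs to the cluster.
    Regions with support < ``min_samples`` are dropped.
    """
    if not isinstance(peaksets, Mapping):
        peaksets = {f"sample_{i}": ps for i, ps in enumerate(peaksets)}
    sample_names = list(peaksets)
    if len(sample_names) < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} peaksets, got {len(sample_names)}"
        )
    frames = []
    for name, ps in peaksets.items():
        if not isinstance(ps, RegionSet):
            ps = RegionSet(ps)  # validates; raises naming the offending record
        sub = ps.df[["chrom", "start", "end"]].copy()
        sub["sample"] = name
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(["chrom", "start", "end"], kind="mergesort")

    rows = []
    occ_rows = []
    rid = 0
    for chrom, grp in pooled.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        samples = grp["sample"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            c_start, c_end = starts[i], ends[i]
            members = {samples[i]}
            j = i + 1
            while j < n and starts[j] < c_end:
                c_end = max(c_end, ends[j])
                members.add(samples[j])
                j += 1
            if len(members) >= min_samples:
                region_id = f"consensus_{rid}"
                rid += 1
                rows.append((chrom, int(c_start), int(c_end), region_id))
                occ_rows.append((region_id, members))
            i = j

    consensus = RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))
    occ = pd.DataFrame(
        [[s in members for s in sample_names] for _, members in occ_rows],
        index=[region_id for region_id, _ in occ_rows],
        columns=sample_names,
    )
    occ = occ.loc[consensus.df["region_id"]]
    return consensus, OccupancyMatrix(occ)


def count_in_regions(
    consensus: RegionSet,
    fragments: Mapping[str, pd.DataFrame],
) -> "CountMatrix":
    """Count fragments per consensus region per sample.

    A fragment is assigned to the consensus region containing its midpoint
    (regions are disjoint after merging, so the assignment is unique);
    fragments whose midpoint falls outside all regions are discarded and
    tallied.  Per-sample totals-in-peaks are recorded for RPKM denominators.
    """
    from .normalize import CountMatrix

    region_df = consensus.df
    for chrom, g in region_df.groupby("chrom"):
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValidationError(
                f"consensus regions overlap on {chrom}; merge before counting"
            )
    values = pd.DataFrame(
        0, index=region_df["region_id"], columns=list(fragments), dtype=float
    )
    discarded = {}
    by_chrom = {c: g for c, g in region_df.groupby("chrom")}
    for sample, frag in fragments.items():
        lost = 0
        for chrom, g in frag.groupby("chrom"):
            regions = by_chrom.get(chrom)
            if regions is None:
                lost += len(g)
                continue
            mids = ((g["start"].to_numpy() + g["end"].to_numpy()) // 2).astype(np.int64)
            starts = regions["start"].to_numpy()
            ends = regions["end"].to_numpy()
            idx = np.searchsorted(starts, mids, side="right") - 1
            inside = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
            lost += int((~inside).sum())
            hit_ids = regions["region_id"].to_numpy()[idx[inside]]
            vc = pd.Series(hit_ids).value_counts()
            values.loc[vc.index, sample] += vc.to_numpy()
        discarded[sample] = lost
    totals = values.sum(axis=0)
    return CountMatrix(
        values=values,
        lengths=consensus.lengths,
        totals=totals,
        state="raw",
        meta={"discarded_fragments": discarded},
    )
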