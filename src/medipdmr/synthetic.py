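"""Synthetic study generator with a known truth table.

Emulates the structure of an enrichment-based methylation study — grouped
negative-binomial counts over consensus regions with age, tissue, breeding,
batch, and planted treatment effects — so the whole pipeline is testable
without sequencing data.  The default designs mirror the scaled-down study
layout: 3 prenatal groups (PAE, PF, C) x 4 ages x n=4 hypothalamus samples,
and 3 groups x 2 tissues x n=4 at P22.

Every generator is a pure function of its inputs and a seed; each draws from
its own named RNG substream of the master seed, so adding a generator never
perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotationDB
from .normalize import CountMatrix
from .regions import RegionSet

__all__ = [
    "EffectSpec",
    "developmental_design",
    "tissue_design",
    "generate_annotation",
    "generate_consensus_regions",
    "generate_counts",
    "generate_sample_peaks",
    "generate_sequences",
    "generate_pyro_table",
    "substream",
]

GROUPS = ("C", "PAE", "PF")
AGES = ("P1", "P8", "P15", "P22")


class CapacityError(ValueError):
    """Requested features do not fit in the genome."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: independent of every other substream name."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class EffectSpec:
    """Parameters of the planted-effect count generator.

    log-scale effects are natural-log shifts derived from ``log2_effect``;
    ``nb_dispersion`` is the NB2 alpha (variance = mu + alpha * mu^2).
    """

    n_regions: int = 5000
    frac_pae_specific: float = 0.05
    frac_pf_shared: float = 0.0
    log2_effect: float = 1.5
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.0
    tissue_shift: float = 0.5
    nb_dispersion: float = 0.2
    mean_log_baseline: float = np.log(100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_pae_specific + self.frac_pf_shared > 1 + 1e-12:
            raise ValueError("frac_pae_specific + frac_pf_shared must be <= 1")
        if min(self.frac_pae_specific, self.frac_pf_shared) < 0:
            raise ValueError("fractions must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0 (0 = Poisson limit)")


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------

def developmental_design(n_per_group: int = 4, ages: tuple = AGES) -> pd.DataFrame:
    """3 groups x len(ages) x n_per_group hypothalamus samples.

    Breeding cohort (4 levels) cycles over animals within each group/age;
    extraction batch cycles by age pairs and meDIP batch splits the ages —
    crossed with group so treatment stays estimable after batch correction.
    """
    rows = []
    breedings = [f"B{i+1}" for i in range(4)]
    for ai, age in enumerate(ages):
        for g in GROUPS:
            for k in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"hyp_{age}_{g}_{k+1}",
                        "group": g,
                        "age": age,
                        "tissue": "hypothalamus",
                        "breeding": breedings[(k + ai) % 4],
                        "extraction_batch": f"E{(k % 2) + 1}",
                        "medip_batch": f"M{((k + ai) % 2) + 1}",
                    }
                )
    return pd.DataFrame(rows)


def tissue_design(n_per_group: int = 4) -> pd.DataFrame:
    """3 groups x 2 tissues x n_per_group P22 samples (paired animals)."""
    rows = []
    breedings = [f"B{i+1}" for i in range(4)]
    for tissue in ("hypothalamus", "wbc"):
        for g in GROUPS:
            for k in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"{tissue}_P22_{g}_{k+1}",
                        "group": g,
                        "age": "P22",
                        "tissue": tissue,
                        "breeding": breedings[k % 4],
                        "extraction_batch": f"E{(k % 2) + 1}",
                        "medip_batch": "M1",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(seed: int, n_genes: int, genome_length: int) -> AnnotationDB:
    """Random gene models with promoters, UTRs, exon/intron structure, CGIs.

    Genes are non-overlapping on one chromosome; each gene's exons and
    introns partition its body exactly; promoters (TSS-200 and TSS-1500) abut
    the transcription start respecting strand.  Raises CapacityError when the
    genes plus flanks cannot fit.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = substream(seed, "annotation")
    flank = 1600
    max_gene = 6000
    slot = max_gene + 2 * flank
    if n_genes * slot > genome_length:
        raise CapacityError(
            f"{n_genes} genes need {n_genes * slot} bp; genome_length={genome_length}"
        )
    extra = genome_length - n_genes * slot
    gaps = rng.multinomial(extra, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    genes, exons, introns, utr5, utr3, prom200, prom1500, cgis = ([] for _ in range(8))
    strands = {}
    cursor = 0
    chrom = "chr1"
    for gi in range(n_genes):
        cursor += gaps[gi] + flank
        glen = int(rng.integers(2000, max_gene + 1))
        gstart, gend = cursor, cursor + glen
        gid = f"gene_{gi}"
        strand = "+" if rng.random() < 0.5 else "-"
        strands[gid] = strand
        genes.append((chrom, gstart, gend, gid))

        n_exons = int(rng.integers(1, 5))
        # partition the body into 2*n_exons-1 alternating blocks, exon first/last
        n_blocks = 2 * n_exons - 1
        cuts = np.sort(rng.choice(np.arange(1, glen), size=n_blocks - 1, replace=False)) \
            if n_blocks > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [glen]])
        for b in range(n_blocks):
            s, e = gstart + int(bounds[b]), gstart + int(bounds[b + 1])
            if b % 2 == 0:
                exons.append((chrom, s, e, f"{gid}_exon_{b//2}"))
            else:
                introns.append((chrom, s, e, f"{gid}_intron_{b//2}"))

        first_exon = (gstart + int(bounds[0]), gstart + int(bounds[1])) if n_blocks > 1 \
            else (gstart, gend)
        last_exon = (gstart + int(bounds[-2]), gend) if n_blocks > 1 else (gstart, gend)
        if strand == "+":
            tss = gstart
            u5, u3 = first_exon, last_exon
            prom200.append((chrom, tss - 200, tss, f"{gid}_p200"))
            prom1500.append((chrom, tss - 1500, tss, f"{gid}_p1500"))
        else:
            tss = gend
            u5, u3 = last_exon, first_exon
            prom200.append((chrom, tss, tss + 200, f"{gid}_p200"))
            prom1500.append((chrom, tss, tss + 1500, f"{gid}_p1500"))
        u5_len = max(1, min(200, (u5[1] - u5[0]) // 3))
        u3_len = max(1, min(300, (u3[1] - u3[0]) // 3))
        if strand == "+":
            utr5.append((chrom, u5[0], u5[0] + u5_len, f"{gid}_utr5"))
            utr3.append((chrom, u3[1] - u3_len, u3[1], f"{gid}_utr3"))
        else:
            utr5.append((chrom, u5[1] - u5_len, u5[1], f"{gid}_utr5"))
            utr3.append((chrom, u3[0], u3[0] + u3_len, f"{gid}_utr3"))
        if rng.random() < 0.6:  # CGI over the TSS
            cgis.append((chrom, max(0, tss - 300), tss + 300, f"{gid}_cgi"))
        cursor = gend + flank

    # a few intergenic CGIs in the trailing gap
    tail_start = cursor + 100
    for j in range(max(1, n_genes // 3)):
        s = tail_start + j * 900
        if s + 400 < genome_length:
            cgis.append((chrom, s, s + 400, f"intergenic_cgi_{j}"))

    mk = RegionSet.from_intervals
    return AnnotationDB(
        tracks={
            "gene": mk(genes),
            "exon": mk(exons),
            "intron": mk(introns) if introns else RegionSet(
                pd.DataFrame(columns=["chrom", "start", "end", "region_id"])
            ),
            "promoter_200": mk(prom200),
            "promoter_1500": mk(prom1500),
            "utr5": mk(utr5),
            "utr3": mk(utr3),
            "cgi": mk(cgis),
        },
        gene_strand=pd.Series(strands),
    )


def generate_consensus_regions(
    n_regions: int,
    seed: int = 0,
    min_len: int = 316,
    max_len: int = 1027,
    gap: int = 500,
    chrom: str = "chr1",
    start: int = 0,
) -> RegionSet:
    """Non-overlapping regions with lengths in the observed DMR size range."""
    rng = substream(seed, "consensus_regions")
    lengths = rng.integers(min_len, max_len + 1, size=n_regions)
    gaps = rng.integers(gap // 2, gap * 2, size=n_regions)
    rows, cursor = [], start
    for i in range(n_regions):
        cursor += int(gaps[i])
        rows.append((chrom, cursor, cursor + int(lengths[i]), f"region_{i}"))
        cursor += int(lengths[i])
    return RegionSet.from_intervals(rows)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    design: pd.DataFrame,
    spec: EffectSpec,
    regions: RegionSet | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts with planted exposure effects and a truth table.

    mean = exp(baseline + age + tissue + breeding + batch + group effect);
    pae_specific regions shift the PAE group only, pf_shared regions shift
    PAE and PF jointly.  The truth table records status, direction, and the
    true log2 fold change per region.
    """
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise ValueError(f"design missing column {col!r}")
    group_sizes = design["group"].value_counts()
    missing = [g for g in GROUPS if group_sizes.get(g, 0) < 2]
    if missing:
        raise ValueError(f"degenerate design: need >= 2 samples in each group; short: {missing}")

    rng = substream(spec.seed, "counts")
    R = spec.n_regions
    S = len(design)
    region_ids = [f"region_{i}" for i in range(R)]
    if regions is not None:
        if len(regions) != R:
            raise ValueError("regions length must match spec.n_regions")
        region_ids = list(regions.region_ids)
        lengths = regions.lengths
    else:
        lengths = pd.Series(rng.integers(316, 1028, size=R).astype(float), index=region_ids)

    # truth assignment
    n_pae = int(round(spec.frac_pae_specific * R))
    n_pf = int(round(spec.frac_pf_shared * R))
    order = rng.permutation(R)
    status = np.array(["null"] * R, dtype=object)
    status[order[:n_pae]] = "pae_specific"
    status[order[n_pae:n_pae + n_pf]] = "pf_shared"
    direction_sign = np.where(rng.random(R) < 0.5, 1.0, -1.0)
    true_log2fc = np.where(status == "null", 0.0, direction_sign * spec.log2_effect)
    truth = pd.DataFrame(
        {
            "region_id": region_ids,
            "status": status,
            "direction": np.where(
                true_log2fc > 0, "up", np.where(true_log2fc < 0, "down", "none")
            ),
            "true_log2fc": true_log2fc,
        }
    ).set_index("region_id")

    baseline = rng.normal(spec.mean_log_baseline, 0.5, size=R)
    log_mu = np.tile(baseline[:, None], (1, S))

    def factor_shift(col: str, sd: float, per_region: bool) -> None:
        if col not in design.columns or sd == 0:
            return
        for lv in pd.unique(design[col]):
            mask = (design[col] == lv).to_numpy()
            shift = rng.normal(0.0, sd, size=R) if per_region else rng.normal(0.0, sd)
            log_mu[:, mask] += shift[:, None] if per_region else shift

    factor_shift("age", 0.2, per_region=False)
    factor_shift("breeding", 0.1, per_region=False)
    # tissue: per-region signature so tissues cluster apart
    if "tissue" in design.columns and design["tissue"].nunique() > 1 and spec.tissue_shift:
        tissues = pd.unique(design["tissue"])
        for lv in tissues[1:]:
            mask = (design["tissue"] == lv).to_numpy()
            log_mu[:, mask] += rng.normal(0.0, spec.tissue_shift, size=R)[:, None]
    # batch: per-region location shifts + per-batch residual scale
    for col in ("extraction_batch", "medip_batch"):
        if col in design.columns and spec.batch_shift_sd:
            for lv in pd.unique(design[col]):
                mask = (design[col] == lv).to_numpy()
                log_mu[:, mask] += rng.normal(0.0, spec.batch_shift_sd, size=R)[:, None]
        if col in design.columns and spec.batch_scale_sd:
            for lv in pd.unique(design[col]):
                mask = (design[col] == lv).to_numpy()
                sd_b = spec.batch_scale_sd * float(rng.uniform(0.5, 1.5))
                log_mu[:, mask] += rng.normal(0.0, sd_b, size=(R, int(mask.sum())))

    ln_effect = true_log2fc * np.log(2.0)
    pae_mask = (design["group"] == "PAE").to_numpy()
    pf_mask = (design["group"] == "PF").to_numpy()
    log_mu[:, pae_mask] += ln_effect[:, None]
    shared = (status == "pf_shared")[:, None]
    log_mu[:, pf_mask] += np.where(shared, ln_effect[:, None], 0.0)

    mu = np.exp(np.clip(log_mu, -30, 30))
    if spec.nb_dispersion > 0:
        lam = rng.gamma(shape=1.0 / spec.nb_dispersion, scale=spec.nb_dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    values = pd.DataFrame(counts.astype(float), index=region_ids,
                          columns=design["sample_id"].tolist())
    matrix = CountMatrix(
        values=values,
        lengths=lengths,
        totals=values.sum(axis=0),
        state="raw",
        meta={"effect_spec": asdict(spec)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# peaks, sequences, pyro
# ---------------------------------------------------------------------------

def generate_sample_peaks(
    consensus: RegionSet,
    dropout: float,
    jitter: int,
    seed: int,
    sample_ids: list[str] | int = 20,
) -> dict[str, RegionSet]:
    """Per-sample peaksets: consensus with Bernoulli dropout + endpoint jitter."""
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    min_len = int(consensus.lengths.min()) if len(consensus) else 0
    if jitter < 0 or (len(consensus) and 2 * jitter >= min_len):
        raise ValueError(f"jitter={jitter} too large for smallest region ({min_len} bp)")
    if isinstance(sample_ids, int):
        sample_ids = [f"sample_{i}" for i in range(sample_ids)]
    rng = substream(seed, "sample_peaks")
    out = {}
    df = consensus.df
    n = len(df)
    for sid in sample_ids:
        keep = rng.random(n) >= dropout
        sub = df[keep].copy()
        if jitter > 0 and len(sub):
            sub["start"] = sub["start"] + rng.integers(-jitter, jitter + 1, size=len(sub))
            sub["end"] = sub["end"] + rng.integers(-jitter, jitter + 1, size=len(sub))
            sub["start"] = sub["start"].clip(lower=0)
        sub["region_id"] = [f"{sid}_peak_{i}" for i in range(len(sub))]
        out[sid] = RegionSet(sub)
    return out


def generate_sequences(
    regions: RegionSet,
    planted_pwm=None,
    plant_in: set[str] | None = None,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[dict[str, str], dict[str, int]]:
    """i.i.d. background sequences, with the PWM consensus planted on request.

    Returns (region_id -> sequence, region_id -> planted offset).
    """
    plant_in = set(plant_in or ())
    missing = plant_in - set(regions.df["region_id"])
    if missing:
        raise ValueError(f"plant_in ids not in regions: {sorted(missing)[:3]}")
    rng = substream(seed, "sequences")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seqs, offsets = {}, {}
    consensus = planted_pwm.consensus if planted_pwm is not None else ""
    for rec in regions:
        L = rec.end - rec.start
        seq = "".join(bases[rng.choice(4, size=L, p=probs)])
        if rec.region_id in plant_in:
            if L < len(consensus):
                raise ValueError(
                    f"region {rec.region_id} ({L} bp) shorter than motif ({len(consensus)} bp)"
                )
            off = int(rng.integers(0, L - len(consensus) + 1))
            seq = seq[:off] + consensus + seq[off + len(consensus):]
            offsets[rec.region_id] = off
        seqs[rec.region_id] = seq
    return seqs, offsets


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def generate_gene_sets(
    gene_ids: list[str],
    n_sets: int,
    seed: int,
    min_size: int = 2,
    max_size: int = 30,
) -> dict[str, list[str]]:
    """Random gene sets over a gene universe (annotation-style groupings)."""
    if not gene_ids:
        raise ValueError("gene universe is empty")
    rng = substream(seed, "gene_sets")
    out = {}
    for j in range(n_sets):
        k = int(rng.integers(min_size, min(max_size, len(gene_ids)) + 1))
        out[f"set_{j}"] = list(rng.choice(gene_ids, size=k, replace=False))
    return out


def generate_pyro_table(
    truth: pd.DataFrame,
    n_cpgs: int,
    group_offset: float,
    noise_sd: float,
    seed: int,
    region_id: str | None = None,
    n_animals: int = 4,
    ages: tuple = AGES,
    baseline: float | None = None,
    groups: tuple = ("PAE", "C"),
) -> pd.DataFrame:
    """Per-CpG percent-methylation long table for one region.

    Values = CpG baseline + group offset (PAE only, signed by the region's
    true direction) + Gaussian noise, clipped to [0, 100].
    """
    if n_cpgs < 1:
        raise ValueError("empty assay: n_cpgs must be >= 1")
    if group_offset < 0:
        raise ValueError("group_offset must be >= 0")
    rng = substream(seed, "pyro")
    if region_id is None:
        planted = truth[truth["status"] == "pae_specific"]
        region_id = planted.index[0] if len(planted) else truth.index[0]
    sign = {"up": 1.0, "down": -1.0, "none": 0.0}[truth.loc[region_id, "direction"]]
    cpg_base = (
        np.full(n_cpgs, baseline) if baseline is not None
        else rng.uniform(25.0, 65.0, size=n_cpgs)
    )
    rows = []
    for age in ages:
        for g in groups:
            for a in range(n_animals):
                aid = f"{g}_{age}_{a+1}"
                offs = group_offset * sign if g == "PAE" else 0.0
                noise = rng.normal(0.0, noise_sd, size=n_cpgs) if noise_sd > 0 else np.zeros(n_cpgs)
                vals = np.clip(cpg_base + offs + noise, 0.0, 100.0)
                for c in range(n_cpgs):
                    rows.append((aid, g, age, c + 1, float(vals[c])))
    out = pd.DataFrame(rows, columns=["animal_id", "group", "age", "cpg", "percent"])
    out.attrs["region_id"] = region_id
    return out
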