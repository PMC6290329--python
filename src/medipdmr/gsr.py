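"""Gene-score resampling (GSR) ontology enrichment with multifunctionality
correction.

Each gene receives a score of -log10 of the minimum region-level p among its
regions.  A gene set's observed statistic is the mean score of its members;
the null is the mean of same-size uniform random draws (without replacement)
from the gene universe, repeated ``iterations`` times, giving an add-one
one-sided empirical p (high scores = enrichment).

Multifunctional genes — genes annotated to many sets — inflate set scores;
the correction regresses the rank of each gene's score on its rank-normalized
annotation count and re-runs GSR on the residuals, yielding a second p-value
per set.  When all genes are equally annotated the correction is the
identity.  A term is exposure-specific when both p-values clear alpha in the
two PAE contrasts and at least one fails in PF vs C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetDB",
    "gene_scores",
    "gsr",
    "multifunctionality_correct",
    "call_pae_specific_terms",
]


@dataclass
class GeneSetDB:
    """Gene sets filtered to the configured size bounds."""

    sets: dict[str, list[str]]
    names: dict[str, str] = field(default_factory=dict)
    min_size: int = 2
    max_size: int = 2000

    def __post_init__(self) -> None:
        filtered = {}
        for sid, genes in self.sets.items():
            genes = list(dict.fromkeys(genes))  # de-duplicate, keep order
            if self.min_size <= len(genes) <= self.max_size:
                filtered[sid] = genes
        self.sets = filtered

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "GeneSetDB":
        df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene"])
        sets: dict[str, list[str]] = {}
        for sid, grp in df.groupby("set_id", sort=False):
            sets[str(sid)] = list(grp["gene"].astype(str))
        return cls(sets=sets, **kwargs)

    def annotation_counts(self, universe: pd.Index) -> pd.Series:
        counts = pd.Series(0, index=universe, dtype=float)
        for genes in self.sets.values():
            present = counts.index.intersection(genes)
            counts.loc[present] += 1
        return counts


def gene_scores(region_pvals: pd.Series, region_to_gene: pd.Series,
                how: str = "min_p") -> pd.Series:
    """Per-gene score from region-level p-values.

    Default: -log10 of the minimum p among the gene's regions ('min_p');
    'max_score' takes the maximum of per-region -log10 p (equivalent here,
    kept as the documented alternative for other score functions).
    Zero p-values are clamped to the smallest positive float and flagged.
    """
    mapped = region_to_gene.dropna()
    missing = mapped.index.difference(region_pvals.index)
    if len(missing):
        raise ValueError(f"mapped regions without p-values: {list(missing[:3])}...")
    p = region_pvals.loc[mapped.index].astype(float)
    n_zero = int((p == 0).sum())
    p = p.clip(lower=np.finfo(float).tiny)
    df = pd.DataFrame({"gene": mapped.to_numpy(), "p": p.to_numpy()})
    if how == "min_p":
        scores = -np.log10(df.groupby("gene")["p"].min())
    elif how == "max_score":
        scores = df.assign(s=-np.log10(df["p"])).groupby("gene")["s"].max()
    else:
        raise ValueError("how must be 'min_p' or 'max_score'")
    scores.attrs["n_zero_p_clamped"] = n_zero
    return scores


def gsr(
    scores: pd.Series,
    db: GeneSetDB,
    iterations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw GSR p per set: observed mean member score vs same-size random draws.

    Null distributions are shared across sets of equal size (the draws depend
    only on set size), which leaves the per-set p-values unchanged while
    avoiding redundant sampling.  Members missing from the score vector are
    dropped and reported per set.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    values = scores.to_numpy(float)
    index = scores.index
    rng = np.random.default_rng(seed)
    sizes = {}
    rows = []
    for sid, genes in db.sets.items():
        present = [g for g in genes if g in index]
        rows.append((sid, genes, present))
        if present:
            sizes.setdefault(len(present), None)
    null_by_size = {}
    n_genes = len(values)
    for k in sizes:
        draws = np.empty(iterations)
        for i in range(iterations):
            draws[i] = values[rng.choice(n_genes, size=k, replace=False)].mean()
        null_by_size[k] = draws
    out = []
    for sid, genes, present in rows:
        if not present:
            out.append((sid, len(genes), 0, np.nan, np.nan))
            continue
        obs = float(scores.loc[present].mean())
        null = null_by_size[len(present)]
        p = (1.0 + (null >= obs).sum()) / (iterations + 1.0)
        out.append((sid, len(genes), len(present), obs, p))
    return pd.DataFrame(
        out, columns=["set_id", "n_genes", "n_scored", "observed_mean", "p"]
    ).set_index("set_id")


def multifunctionality(db: GeneSetDB, universe: pd.Index) -> pd.Series:
    """Rank-normalized per-gene annotation count in (0, 1)."""
    counts = db.annotation_counts(universe)
    return counts.rank(method="average") / (len(counts) + 1.0)


def multifunctionality_correct(
    raw: pd.DataFrame,
    db: GeneSetDB,
    scores: pd.Series,
    iterations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multifunctionality-corrected GSR p-values.

    Score ranks are regressed on rank-normalized annotation counts; GSR is
    re-run on the residuals with the same iteration count and seed.  With
    uniform annotation counts the regressor is constant and the correction
    is the identity (raw p returned, noted in attrs).
    """
    mf = multifunctionality(db, scores.index)
    out = raw.copy()
    out["multifunctionality"] = [
        float(mf.loc[[g for g in db.sets[sid] if g in mf.index]].mean())
        if any(g in mf.index for g in db.sets[sid]) else np.nan
        for sid in raw.index
    ]
    if mf.nunique() <= 1:
        out["mf_p"] = raw["p"]
        out.attrs["mf_identity"] = True
        return out
    r_score = scores.rank(method="average").to_numpy(float)
    r_mf = mf.loc[scores.index].to_numpy(float)
    X = np.column_stack([np.ones_like(r_mf), r_mf])
    coef, *_ = np.linalg.lstsq(X, r_score, rcond=None)
    resid = pd.Series(r_score - X @ coef, index=scores.index)
    corrected = gsr(resid, db, iterations=iterations, seed=seed)
    out["mf_p"] = corrected["p"]
    out.attrs["mf_identity"] = False
    return out


def call_pae_specific_terms(
    results: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exposure-specific term calls across the three contrasts.

    ``results`` maps contrast name (PAEvC, PAEvPF, PFvC) to a GSR table with
    columns p and mf_p.  A set is flagged iff p < alpha and mf_p < alpha in
    both PAE contrasts, and (p >= alpha or mf_p >= alpha) in PFvC.  Output
    sorted by PAEvC p ascending.
    """
    needed = {"PAEvC", "PAEvPF", "PFvC"}
    if set(results) != needed:
        raise ValueError(f"results must have exactly the contrasts {sorted(needed)}")
    base = results["PAEvC"]
    idx = base.index
    for c, tbl in results.items():
        if not idx.equals(tbl.index):
            raise ValueError(f"set ids misaligned between PAEvC and {c}")
    out = pd.DataFrame(index=idx)
    if "n_genes" in base.columns:
        out["n_genes"] = base["n_genes"]
    if "multifunctionality" in base.columns:
        out["multifunctionality"] = base["multifunctionality"]
    for c in ("PAEvC", "PAEvPF", "PFvC"):
        out[f"p_{c}"] = results[c]["p"]
        out[f"mf_p_{c}"] = results[c]["mf_p"]
    sig = lambda c: (out[f"p_{c}"] < alpha) & (out[f"mf_p_{c}"] < alpha)  # noqa: E731
    out["pae_specific"] = sig("PAEvC") & sig("PAEvPF") & ~sig("PFvC")
    return out.sort_values("p_PAEvC", kind="mergesort")
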