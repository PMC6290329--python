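"""Count normalization and sample-level quality control.

Raw per-region read counts are scaled to reads/kb (count divided by region
length in kb) and then to RPKM by dividing by each sample's total reads in
predicted peaks (in millions) — the depth denominator is reads *in peaks*,
not total library size.  QC computes pairwise Pearson correlations on
log(RPKM + 1), flags samples whose nearest correlation neighbour carries a
different tissue label (the mislabeled-sample rule) or whose best correlation
falls below a floor, and scans principal components for covariate-associated
variance by one-way ANOVA on PC scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "QCReport",
    "to_reads_per_kb",
    "to_rpkm",
    "rpkm_to_reads_per_kb",
    "correlation_qc",
    "pc_covariate_scan",
]

STATES = ("raw", "reads_per_kb", "rpkm", "batch_adjusted")


class NormalizationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Region x sample value matrix carrying its normalization state.

    values: DataFrame indexed by region_id, columns = sample ids.
    lengths: region lengths in bp.  totals: per-sample total reads in peaks.
    """

    values: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series
    state: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise NormalizationError(f"unknown state {self.state!r}")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise NormalizationError("region lengths must be > 0 for all regions")
        self.totals = self.totals.reindex(self.values.columns)
        if (self.values.to_numpy() < 0).any() and self.state == "raw":
            raise NormalizationError("raw counts must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def region_ids(self) -> pd.Index:
        return self.values.index

    def copy_with(self, values: pd.DataFrame, state: str, **meta) -> "CountMatrix":
        return CountMatrix(
            values=values,
            lengths=self.lengths,
            totals=self.totals,
            state=state,
            meta={**self.meta, **meta},
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# state={self.state}\n")
            self.values.to_csv(fh, sep="\t")


def _require_state(m: CountMatrix, state: str, op: str) -> None:
    if m.state != state:
        raise NormalizationError(f"{op} requires state={state!r}, got {m.state!r}")


def to_reads_per_kb(counts: CountMatrix) -> CountMatrix:
    """reads/kb: r_ij / (L_j / 1000)."""
    _require_state(counts, "raw", "to_reads_per_kb")
    vals = counts.values.div(counts.lengths / 1000.0, axis=0)
    return counts.copy_with(vals, "reads_per_kb")


def to_rpkm(counts: CountMatrix) -> CountMatrix:
    """RPKM: reads/kb divided by total reads in predicted peaks, in millions."""
    if counts.state == "raw":
        counts = to_reads_per_kb(counts)
    _require_state(counts, "reads_per_kb", "to_rpkm")
    if counts.totals.isna().any() or (counts.totals <= 0).any():
        raise NormalizationError("per-sample totals-in-peaks must be > 0 for RPKM")
    vals = counts.values.div(counts.totals / 1e6, axis=1)
    return counts.copy_with(vals, "rpkm")


def rpkm_to_reads_per_kb(m: CountMatrix, clip_negative: bool = False) -> CountMatrix:
    """Exact inverse of the depth scaling: multiply by N_i / 1e6.

    Used to return adjusted RPKM values to the reads/kb scale for count-model
    testing; negatives (possible after adjustment) are clipped when requested
    and counted in meta['clipped_negative'].
    """
    if m.state not in ("rpkm", "batch_adjusted"):
        raise NormalizationError("rpkm_to_reads_per_kb requires rpkm or batch_adjusted state")
    if m.totals.isna().any():
        raise NormalizationError("totals-in-peaks missing; cannot back-convert")
    vals = m.values.mul(m.totals / 1e6, axis=1)
    n_neg = int((vals.to_numpy() < 0).sum())
    if clip_negative:
        vals = vals.clip(lower=0.0)
    return m.copy_with(vals, "reads_per_kb", clipped_negative=n_neg)


@dataclass
class QCReport:
    correlations: pd.DataFrame
    nearest_neighbor: pd.Series
    nn_tissue: pd.Series
    flagged: list
    reasons: dict
    pc_table: Optional[pd.DataFrame] = None

    def to_tsv(self, path) -> None:
        flags = pd.DataFrame(
            {"flagged": [s in self.flagged for s in self.correlations.index],
             "reason": [self.reasons.get(s, "") for s in self.correlations.index],
             "nearest_neighbor": self.nearest_neighbor,
             "nn_tissue": self.nn_tissue}
        )
        flags.to_csv(path, sep="\t")


def correlation_qc(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    min_r: float = 0.95,
) -> QCReport:
    """Pearson-correlation QC on log(RPKM + 1).

    A sample is flagged when its nearest neighbour (highest correlation)
    carries a different tissue label, or when its maximum correlation with
    any other sample is below ``min_r``.  Constant sample vectors have
    undefined correlations and are flagged explicitly.
    """
    if matrix.state in ("raw", "reads_per_kb"):
        matrix = to_rpkm(matrix)
    samples = list(matrix.samples)
    if len(samples) < 3:
        raise ValueError("correlation QC needs at least 3 samples")
    logv = np.log(matrix.values.to_numpy(dtype=float) + 1.0)
    sd = logv.std(axis=0)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(logv.mean(axis=0)))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(logv, rowvar=False)
    corr_df = pd.DataFrame(corr, index=samples, columns=samples)

    tissue = metadata.set_index("sample_id")["tissue"] if "tissue" in metadata.columns else None
    flagged, reasons = [], {}
    nn, nn_tis = {}, {}
    for k, s in enumerate(samples):
        if constant[k]:
            flagged.append(s)
            reasons[s] = "constant sample vector (undefined correlation)"
            nn[s], nn_tis[s] = "", ""
            continue
        others = corr_df[s].drop(index=s).dropna()
        best = others.idxmax()
        nn[s] = best
        nn_tis[s] = tissue.get(best, "") if tissue is not None else ""
        if others.max() < min_r:
            flagged.append(s)
            reasons[s] = f"max correlation {others.max():.3f} < {min_r}"
        elif tissue is not None and tissue.get(s) is not None and tissue.get(best) != tissue.get(s):
            flagged.append(s)
            reasons[s] = f"nearest neighbor {best} has tissue {tissue.get(best)!r} != {tissue.get(s)!r}"
    return QCReport(
        correlations=corr_df,
        nearest_neighbor=pd.Series(nn),
        nn_tissue=pd.Series(nn_tis),
        flagged=flagged,
        reasons=reasons,
    )


def pc_covariate_scan(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    n_pcs: int = 5,
    covariates: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Associate principal components of log(RPKM+1) with sample covariates.

    PCA treats samples as observations (SVD of the centered sample x region
    matrix).  For each PC x categorical covariate the table reports the PC's
    variance fraction and a one-way ANOVA F statistic with p-value.
    Single-level covariates are skipped with a warning row (F, p = NaN).
    """
    X = np.log(matrix.values.to_numpy(dtype=float).T + 1.0)  # samples x regions
    n_samples = X.shape[0]
    max_pcs = min(X.shape) - 1
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(regions, samples)-1 = {max_pcs}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var_frac = S**2 / (S**2).sum()
    scores = U * S

    meta = metadata.set_index("sample_id").loc[list(matrix.samples)]
    if covariates is None:
        covariates = [c for c in meta.columns]
    rows = []
    for pc in range(n_pcs):
        for cov in covariates:
            levels = meta[cov].astype(str)
            uniq = levels.unique()
            if len(uniq) < 2:
                rows.append((pc + 1, cov, var_frac[pc], np.nan, np.nan, "single-level covariate; skipped"))
                continue
            groups = [scores[levels.to_numpy() == lv, pc] for lv in uniq]
            F, p = stats.f_oneway(*groups)
            rows.append((pc + 1, cov, var_frac[pc], F, p, ""))
    return pd.DataFrame(
        rows, columns=["pc", "covariate", "variance_fraction", "F", "p", "note"]
    ).sort_values(["pc", "covariate"], kind="mergesort").reset_index(drop=True)
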