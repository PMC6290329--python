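"""PWM scanning and permutation motif enrichment.

Sequences are scored against position weight matrices by log2-odds
(motif probability over background composition, pseudocount-regularized) at
every offset on both strands; a region registers a hit when its best score
reaches a fraction (default 0.8) of the motif's maximum attainable score.
Enrichment compares the fraction of query regions with >= 1 hit to the same
statistic on random same-size subsets of the background region set, with
add-one empirical p-values and BH correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import bh_adjust

__all__ = ["PWM", "scan", "hit_matrix", "motif_enrichment", "read_jaspar"]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
NEG_INF = float("-inf")


@dataclass
class PWM:
    """Position weight matrix with background and pseudocount.

    ``matrix`` rows are motif positions, columns A, C, G, T probabilities.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4 (A, C, G, T)")
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log2-odds; column 4 scores ambiguity codes as background (0)."""
        lo = np.log2(self.matrix / self.background[None, :])
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices; anything outside ACGT becomes 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _strand_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[0]
    n = idx.shape[0] - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lo[np.arange(L), windows].sum(axis=1) if n > 0 else np.empty(0)


def scan(sequence: str, pwm: PWM, threshold: float | None = None) -> dict:
    """Score a sequence at all offsets on both strands.

    Returns best score, its (offset, strand), and all positions reaching the
    threshold (default: 0.8 * max attainable score).  Sequences shorter than
    the motif yield a -inf sentinel, not an exception.
    """
    L = len(pwm)
    if threshold is None:
        threshold = 0.8 * pwm.max_score
    idx = encode(sequence)
    if idx.shape[0] < L:
        return {"best_score": NEG_INF, "best_position": None, "hits": [], "threshold": threshold}
    lo = pwm.log_odds
    fwd = _strand_scores(idx, lo)
    # reverse complement: reverse positions, complement columns (A<->T, C<->G)
    lo_rc = lo[::-1][:, [3, 2, 1, 0, 4]]
    rev = _strand_scores(idx, lo_rc)
    hits = [(int(i), "+", float(s)) for i, s in enumerate(fwd) if s >= threshold]
    hits += [(int(i), "-", float(s)) for i, s in enumerate(rev) if s >= threshold]
    if fwd.max() >= rev.max():
        best, pos, strand = float(fwd.max()), int(fwd.argmax()), "+"
    else:
        best, pos, strand = float(rev.max()), int(rev.argmax()), "-"
    return {"best_score": best, "best_position": (pos, strand), "hits": hits,
            "threshold": threshold}


def hit_matrix(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Region x motif table of best score, hit flag, and hit count."""
    records = {}
    for rid, seq in sequences.items():
        row = {}
        for pwm in pwms:
            res = scan(seq, pwm, threshold=threshold_fraction * pwm.max_score)
            row[(pwm.motif_id, "best_score")] = res["best_score"]
            row[(pwm.motif_id, "hit")] = len(res["hits"]) > 0
            row[(pwm.motif_id, "n_hits")] = len(res["hits"])
        records[rid] = row
    out = pd.DataFrame.from_dict(records, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["motif", "stat"])
    return out


def motif_enrichment(
    dmr_ids: Sequence[str],
    background_hits: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of motif hit fractions in a query subset.

    ``background_hits`` is the :func:`hit_matrix` of the full background
    (queries must be a subset).  Observed statistic per motif: fraction of
    query regions with >= 1 hit.  Null: the same fraction on ``n_perm``
    random same-size subsets.  BH q across motifs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dmr_ids = list(dmr_ids)
    if not set(dmr_ids).issubset(background_hits.index):
        raise ValueError("query regions missing from background hit matrix")
    hits = background_hits.xs("hit", axis=1, level="stat").astype(bool)
    motifs = list(hits.columns)
    H = hits.to_numpy()
    pos = hits.index.get_indexer(dmr_ids)
    k = len(dmr_ids)
    obs = H[pos].mean(axis=0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(motifs)))
    n_bg = H.shape[0]
    for i in range(n_perm):
        null[i] = H[rng.choice(n_bg, size=k, replace=False)].mean(axis=0)
    p_enrich = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    p_deplete = (1.0 + (null <= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    out = pd.DataFrame(
        {
            "observed_fraction": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1),
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
        },
        index=pd.Index(motifs, name="motif"),
    )
    out["uninformative"] = ~H.any(axis=0)
    out.loc[out["uninformative"], ["p_enrich", "p_deplete"]] = 1.0
    out["q_enrich"] = bh_adjust(out["p_enrich"])
    return out


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-style plain-text matrices (>id then 4 rows A/C/G/T)."""
    pwms = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line: {lines[i]!r}")
        motif_id = lines[i][1:].split()[0]
        rows = []
        for j in range(4):
            row = lines[i + 1 + j].replace("[", " ").replace("]", " ")
            fields = [x for x in row.split() if x not in "ACGT"]
            rows.append([float(x) for x in fields])
        mat = np.array(rows, dtype=float).T  # positions x ACGT
        counts = mat / np.maximum(mat.sum(axis=1, keepdims=True), 1e-12)
        pwms.append(PWM(motif_id=motif_id, matrix=counts))
        i += 5
    return pwms
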