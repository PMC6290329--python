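"""End-to-end orchestration of the two analyses and the validation harness.

The statistical chain mirrors the published order of operations: raw counts
-> reads/kb -> RPKM -> correlation QC and sample exclusion -> empirical-Bayes
batch adjustment -> back-conversion to reads/kb -> per-region NB testing with
BH-FDR -> the exposure-specific intersection call, followed by feature /
motif / gene-set enrichment and pyrosequencing-style summaries.

``dmr_pipeline`` is the reusable statistical core; ``run`` adds file I/O,
configuration, and a YAML manifest; ``simulate_and_evaluate`` scores pipeline
calls against the synthetic truth table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import combat, dmr, gsr, motifs, normalize, pyro, synthetic
from .normalize import CountMatrix

logger = logging.getLogger("medipdmr")

__all__ = ["PipelineConfig", "dmr_pipeline", "run", "simulate_and_evaluate"]

_CONFIG_SCHEMA: dict[str, type] = {
    "mode": str,                 # developmental | tissue_concordant | both
    "outdir": str,
    "seed": int,
    "alpha": float,
    "min_samples": int,
    "n_perm": int,
    "gsr_iterations": int,
    "set_min_size": int,
    "set_max_size": int,
    "fold_thresholds": list,
    "pyro_threshold": float,
    "batch_factors": list,
    "keep_covariates": list,
    "n_regions": int,
    "n_per_group": int,
    "frac_pae_specific": float,
    "frac_pf_shared": float,
    "log2_effect": float,
    "nb_dispersion": float,
    "batch_shift_sd": float,
    "batch_scale_sd": float,
    "shrink": bool,
    "rounding": str,
    "run_enrichment": bool,
    "run_motifs": bool,
    "run_gsr": bool,
    "run_pyro": bool,
    "min_r": float,
}


@dataclass
class PipelineConfig:
    mode: str = "developmental"
    outdir: str = "medipdmr_out"
    seed: int = 0
    alpha: float = 0.05
    min_samples: int = 3
    n_perm: int = 1000
    gsr_iterations: int = 10000
    set_min_size: int = 2
    set_max_size: int = 2000
    fold_thresholds: list = field(default_factory=lambda: [1.5, 2.0])
    pyro_threshold: float = 5.0
    batch_factors: list = field(default_factory=lambda: ["medip_batch", "extraction_batch"])
    keep_covariates: list = field(default_factory=lambda: ["group"])
    n_regions: int = 2000
    n_per_group: int = 4
    frac_pae_specific: float = 0.05
    frac_pf_shared: float = 0.0
    log2_effect: float = 1.5
    nb_dispersion: float = 0.2
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.0
    shrink: bool = True
    rounding: str = "round"
    run_enrichment: bool = True
    run_motifs: bool = False
    run_gsr: bool = False
    run_pyro: bool = True
    min_r: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("developmental", "tissue_concordant", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            want = _CONFIG_SCHEMA[key]
            if want is float and isinstance(val, int):
                continue
            if not isinstance(val, want):
                raise ValueError(f"config key {key!r} must be {want.__name__}")
        return cls(**raw)

    def effect_spec(self) -> synthetic.EffectSpec:
        return synthetic.EffectSpec(
            n_regions=self.n_regions,
            frac_pae_specific=self.frac_pae_specific,
            frac_pf_shared=self.frac_pf_shared,
            log2_effect=self.log2_effect,
            nb_dispersion=self.nb_dispersion,
            batch_shift_sd=self.batch_shift_sd,
            batch_scale_sd=self.batch_scale_sd,
            seed=self.seed,
        )


def dmr_pipeline(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "breeding"),
    batch_factors: list[str] | None = None,
    keep_covariates: list[str] | None = None,
    alpha: float = 0.05,
    shrink: bool = True,
    rounding: str = "round",
    qc_min_r: float = 0.0,
) -> dict:
    """Normalize -> QC exclude -> batch-adjust -> back-convert -> test -> call.

    Returns a dict with the QC report, adjusted matrix, test table, and the
    called :class:`~medipdmr.dmr.DMRTable`.
    """
    rpkm = normalize.to_rpkm(matrix)
    qc = normalize.correlation_qc(rpkm, metadata.reset_index()
                                  if "sample_id" not in metadata.columns else metadata,
                                  min_r=qc_min_r)
    keep = [s for s in rpkm.samples if s not in qc.flagged]
    if len(keep) < len(rpkm.samples):
        logger.info("excluding %d flagged sample(s): %s",
                    len(rpkm.samples) - len(keep), qc.flagged)
        rpkm = rpkm.copy_with(rpkm.values[keep], rpkm.state)
        rpkm.totals = rpkm.totals[keep]
    meta = metadata if "sample_id" in metadata.columns else metadata.reset_index()
    meta = meta[meta["sample_id"].isin(keep)]

    models = []
    if batch_factors:
        adjusted, models = combat.fit_and_adjust(
            rpkm, meta, batch_factors,
            keep_covariates=keep_covariates or ["group"], shrink=shrink,
        )
        testable = combat.back_to_reads_per_kb(adjusted)
    else:
        adjusted = rpkm
        testable = normalize.rpkm_to_reads_per_kb(rpkm)

    design = dmr.DesignSpec(metadata=meta, covariates=covariates)
    dispersion = dmr.estimate_dispersion(
        testable, design, adjusted_factors=tuple(batch_factors or ())
    )
    # the LRT uses the common dispersion: per-region moment estimates correlate
    # with contrast noise and measurably distort type-I calibration (methods note)
    tests = dmr.fit_and_test(
        testable, design, dispersion.attrs["common"], rounding=rounding
    )
    calls = dmr.call_pae_specific(tests, alpha=alpha)
    return {
        "qc": qc,
        "metadata": meta,
        "adjusted": adjusted,
        "testable": testable,
        "batch_models": models,
        "dispersion": dispersion,
        "tests": tests,
        "calls": calls,
    }


def _group_means(testable: CountMatrix, meta: pd.DataFrame) -> dict[str, pd.Series]:
    out = {}
    for g in ("PAE", "PF", "C"):
        cols = meta.loc[meta["group"] == g, "sample_id"]
        out[g] = testable.values[list(cols)].mean(axis=1)
    return out


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()
    ).hexdigest()[:16]


def run(config: PipelineConfig) -> dict:
    """Run the configured synthetic analysis end to end, writing artifacts.

    Counts are generated at the region level (the statistical chain consumes
    region counts); per-sample peak calling and consensus construction are
    exercised through their own CLI verbs on BED input.  Identical config and
    seed reproduce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    results: dict = {}

    modes = ["developmental", "tissue_concordant"] if config.mode == "both" else [config.mode]
    for mode in modes:
        design = (
            synthetic.developmental_design(config.n_per_group)
            if mode == "developmental"
            else synthetic.tissue_design(config.n_per_group)
        )
        spec = config.effect_spec()
        matrix, truth = synthetic.generate_counts(design, spec)
        manifest["stages"].append({"stage": f"{mode}:generate",
                                   "n_regions": len(matrix.region_ids),
                                   "n_samples": len(matrix.samples)})

        covariates = ("age", "breeding") if mode == "developmental" else ("tissue", "breeding")
        res = dmr_pipeline(
            matrix, design,
            covariates=covariates,
            batch_factors=config.batch_factors,
            keep_covariates=config.keep_covariates,
            alpha=config.alpha,
            shrink=config.shrink,
            rounding=config.rounding,
        )
        res["truth"] = truth
        calls = res["calls"]
        means = _group_means(res["testable"], res["metadata"])
        fc = dmr.fold_change_class(means["PAE"], means["C"], means["PF"], eps=0.5)
        table = calls.table.join(fc)

        if mode == "tissue_concordant":
            per_tissue_fc = {}
            for tissue in ("hypothalamus", "wbc"):
                sub_meta = res["metadata"][res["metadata"]["tissue"] == tissue]
                sub = res["testable"]
                subm = sub.copy_with(sub.values[list(sub_meta["sample_id"])], sub.state)
                subm.totals = subm.totals[list(sub_meta["sample_id"])]
                d = dmr.DesignSpec(metadata=sub_meta, covariates=("breeding",))
                t = dmr.fit_and_test(subm, d, res["dispersion"], rounding=config.rounding)
                per_tissue_fc[tissue] = t["log2fc_PAEvC"]
            conc = dmr.tissue_concordance(
                per_tissue_fc["hypothalamus"], per_tissue_fc["wbc"], table["pae_specific"]
            )
            res["concordance"] = conc
            table["tissue_concordant"] = (
                conc["concordant"].reindex(table.index).astype("boolean").fillna(False)
            )

        dmr_tsv = outdir / f"{mode}_dmr_table.tsv"
        table.to_csv(dmr_tsv, sep="\t")
        partition = calls.direction_partition()
        logger.info("%s: called %d regions (up=%d down=%d none=%d)", mode,
                    partition["total"], partition["up"], partition["down"],
                    partition["direction_uncalled"])
        manifest["stages"].append({
            "stage": f"{mode}:test", "n_called": partition["total"],
            "direction_partition": partition, "checksum": _checksum(table),
            "n_nonconverged": res["tests"].attrs.get("n_nonconverged", 0),
        })
        res["qc"].to_tsv(outdir / f"{mode}_qc_flags.tsv")

        regions = synthetic.generate_consensus_regions(config.n_regions, seed=config.seed)
        db = synthetic.generate_annotation(
            config.seed, n_genes=max(10, config.n_regions // 50),
            genome_length=int(regions.df["end"].max()) + 20000,
        )
        called_ids = list(calls.called.index)

        if config.run_enrichment and partition["total"] > 0:
            sub = ann.RegionSet(regions.df[regions.df["region_id"].isin(called_ids)])
            if 0 < len(sub) < len(regions):
                enrich = ann.feature_enrichment(
                    sub, regions, db, n_perm=config.n_perm, seed=config.seed
                )
                enrich.to_csv(outdir / f"{mode}_feature_enrichment.tsv", sep="\t")
                manifest["stages"].append({"stage": f"{mode}:feature_enrichment",
                                           "n_perm": config.n_perm})
                res["feature_enrichment"] = enrich

        if config.run_motifs and partition["total"] > 0:
            pwm = motifs.PWM("demo_motif", np.array([[0.85, 0.05, 0.05, 0.05],
                                                     [0.05, 0.85, 0.05, 0.05],
                                                     [0.05, 0.05, 0.85, 0.05],
                                                     [0.05, 0.05, 0.05, 0.85],
                                                     [0.85, 0.05, 0.05, 0.05]]))
            plant = set(called_ids[: max(1, len(called_ids) // 2)])
            seqs, _ = synthetic.generate_sequences(regions, pwm, plant, seed=config.seed)
            hits = motifs.hit_matrix(seqs, [pwm])
            menr = motifs.motif_enrichment(called_ids, hits, n_perm=config.n_perm,
                                           seed=config.seed)
            menr.to_csv(outdir / f"{mode}_motif_enrichment.tsv", sep="\t")
            manifest["stages"].append({"stage": f"{mode}:motif_enrichment"})
            res["motif_enrichment"] = menr

        if config.run_gsr:
            profile = ann.annotate(regions, db)
            gene_map = profile.gene_hits.map(lambda g: g[0] if g else np.nan)
            gene_map = gene_map[gene_map.index.isin(res["tests"].index)]
            genes = list(db.tracks["gene"].region_ids)
            sets = synthetic.generate_gene_sets(genes, n_sets=20, seed=config.seed)
            setdb = gsr.GeneSetDB(sets=sets, min_size=config.set_min_size,
                                  max_size=config.set_max_size)
            gsr_results = {}
            for contrast in ("PAEvC", "PAEvPF", "PFvC"):
                pv = res["tests"][f"p_{contrast}"].dropna()
                scores = gsr.gene_scores(pv, gene_map[gene_map.index.isin(pv.index)])
                raw = gsr.gsr(scores, setdb, iterations=config.gsr_iterations,
                              seed=config.seed)
                gsr_results[contrast] = gsr.multifunctionality_correct(
                    raw, setdb, scores, iterations=config.gsr_iterations,
                    seed=config.seed)
            terms = gsr.call_pae_specific_terms(gsr_results, alpha=config.alpha)
            terms.to_csv(outdir / f"{mode}_gsr_terms.tsv", sep="\t")
            manifest["stages"].append({"stage": f"{mode}:gsr",
                                       "iterations": config.gsr_iterations})
            res["gsr_terms"] = terms

        if config.run_pyro:
            pt = synthetic.generate_pyro_table(
                truth if (truth["status"] != "null").any() else truth,
                n_cpgs=16, group_offset=5.0, noise_sd=3.0, seed=config.seed,
            )
            stats_by_age = pyro.group_stats(pt, by="age")["dmr"]
            summary = []
            for age, row in stats_by_age.iterrows():
                change = row["PAE"] - row["C"]
                summary.append((age, row["PAE"], row["C"], change,
                                pyro.flag_significant_change(change, config.pyro_threshold)))
            pd.DataFrame(summary, columns=["age", "PAE", "C", "change", "gt_threshold"]) \
                .to_csv(outdir / f"{mode}_pyro_summary.tsv", sep="\t", index=False)
            manifest["stages"].append({"stage": f"{mode}:pyro"})

        results[mode] = res

    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    results["manifest"] = manifest
    return results


def simulate_and_evaluate(config: PipelineConfig) -> dict:
    """Generate -> run -> score calls against the truth table.

    Reports sensitivity on planted exposure-specific regions, the realized
    false discovery proportion among calls, and direction accuracy.
    """
    mode = "developmental" if config.mode == "both" else config.mode
    design = (
        synthetic.developmental_design(config.n_per_group)
        if mode == "developmental"
        else synthetic.tissue_design(config.n_per_group)
    )
    spec = config.effect_spec()
    matrix, truth = synthetic.generate_counts(design, spec)
    covariates = ("age", "breeding") if mode == "developmental" else ("tissue", "breeding")
    res = dmr_pipeline(
        matrix, design, covariates=covariates,
        batch_factors=config.batch_factors, keep_covariates=config.keep_covariates,
        alpha=config.alpha, shrink=config.shrink, rounding=config.rounding,
    )
    return evaluate_calls(res["calls"], truth) | {"result": res, "truth": truth}


def evaluate_calls(calls: dmr.DMRTable, truth: pd.DataFrame) -> dict:
    t = calls.table.join(truth, how="left", rsuffix="_true")
    called = t["pae_specific"]
    planted = t["status"] == "pae_specific"
    n_called = int(called.sum())
    tp = int((called & planted).sum())
    fp = n_called - tp
    sens = tp / planted.sum() if planted.sum() else np.nan
    fdr = fp / n_called if n_called else 0.0
    hit = called & planted
    dir_ok = (t.loc[hit, "direction"] == t.loc[hit, "direction_true"]) if tp else pd.Series(dtype=bool)
    return {
        "n_called": n_called,
        "n_planted": int(planted.sum()),
        "sensitivity": float(sens) if planted.sum() else float("nan"),
        "realized_fdr": float(fdr),
        "direction_accuracy": float(dir_ok.mean()) if tp else float("nan"),
        "pf_shared_called": int((called & (t["status"] == "pf_shared")).sum()),
        "n_pf_shared": int((t["status"] == "pf_shared").sum()),
    }
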