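"""Generator contracts: determinism, generative moments, planted structure."""

import numpy as np
import pandas as pd
import pytest

from medipdmr import synthetic
from medipdmr.motifs import PWM
from medipdmr.synthetic import (
    CapacityError,
    EffectSpec,
    developmental_design,
    generate_annotation,
    generate_consensus_regions,
    generate_counts,
    generate_pyro_table,
    generate_sample_peaks,
    generate_sequences,
    tissue_design,
)


class TestEffectSpec:
    def test_fraction_invariant(self):
        with pytest.raises(ValueError):
            EffectSpec(frac_pae_specific=0.7, frac_pf_shared=0.5)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec(nb_dispersion=-0.1)


class TestAnnotation:
    def test_single_gene_exons_introns_tile_body(self):
        db = generate_annotation(seed=1, n_genes=1, genome_length=50_000)
        gene = db.tracks["gene"].df.iloc[0]
        blocks = pd.concat([db.tracks["exon"].df, db.tracks["intron"].df])
        blocks = blocks.sort_values("start")
        assert blocks["start"].iloc[0] == gene["start"]
        assert blocks["end"].iloc[-1] == gene["end"]
        # contiguous, non-overlapping
        assert (blocks["start"].to_numpy()[1:] == blocks["end"].to_numpy()[:-1]).all()

    def test_minus_strand_promoter_at_right_end(self):
        for seed in range(10):
            db = generate_annotation(seed=seed, n_genes=3, genome_length=100_000)
            for _, g in db.tracks["gene"].df.iterrows():
                strand = db.gene_strand[g["region_id"]]
                p200 = db.tracks["promoter_200"].df
                p = p200[p200["region_id"] == f"{g['region_id']}_p200"].iloc[0]
                if strand == "-":
                    assert p["start"] == g["end"]
                else:
                    assert p["end"] == g["start"]

    def test_seed_reproducible_bed_output(self, tmp_path):
        for i, path in enumerate([tmp_path / "a.bed", tmp_path / "b.bed"]):
            db = generate_annotation(seed=7, n_genes=4, genome_length=120_000)
            db.tracks["gene"].to_bed(path)
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_annotation(seed=0, n_genes=100, genome_length=10_000)


class TestCounts:
    def test_no_planted_effects_all_null(self):
        m, truth = generate_counts(
            developmental_design(), EffectSpec(n_regions=50, frac_pae_specific=0,
                                               frac_pf_shared=0, seed=1))
        assert (truth["status"] == "null").all()
        assert (truth["true_log2fc"] == 0).all()

    def test_seed_determinism(self):
        spec = EffectSpec(n_regions=30, seed=11)
        m1, t1 = generate_counts(developmental_design(), spec)
        m2, t2 = generate_counts(developmental_design(), spec)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_monte_carlo_mean_ratio(self):
        # one region, thousands of replicate animals: PAE/C mean ratio -> 2
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(30_000)],
            "group": ["PAE", "C", "PF"] * 10_000,
        })
        spec = EffectSpec(n_regions=1, frac_pae_specific=1.0, log2_effect=1.0,
                          batch_shift_sd=0.0, seed=13)
        m, truth = generate_counts(design, spec)
        vals = m.values.iloc[0]
        groups = design.set_index("sample_id")["group"]
        ratio = vals[groups == "PAE"].mean() / vals[groups == "C"].mean()
        if truth["direction"].iloc[0] == "down":
            ratio = 1.0 / ratio
        assert abs(ratio - 2.0) / 2.0 <= 0.05

    def test_poisson_limit_variance_equals_mean(self):
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12_000)],
            "group": ["PAE", "C", "PF"] * 4_000,
        })
        spec = EffectSpec(n_regions=1, frac_pae_specific=0, nb_dispersion=0.0,
                          batch_shift_sd=0.0, seed=14)
        m, _ = generate_counts(design, spec)
        vals = m.values.iloc[0].to_numpy()
        assert abs(vals.var() / vals.mean() - 1.0) <= 0.1

    def test_nb_variance_matches_parameterization(self):
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12_000)],
            "group": ["PAE", "C", "PF"] * 4_000,
        })
        spec = EffectSpec(n_regions=1, frac_pae_specific=0, nb_dispersion=0.3,
                          batch_shift_sd=0.0, seed=15)
        m, _ = generate_counts(design, spec)
        vals = m.values.iloc[0].to_numpy()
        mu = vals.mean()
        expect = mu + 0.3 * mu**2
        assert abs(vals.var() / expect - 1.0) <= 0.1

    def test_degenerate_design_rejected(self):
        design = pd.DataFrame({"sample_id": ["a", "b"], "group": ["PAE", "C"]})
        with pytest.raises(ValueError, match="degenerate"):
            generate_counts(design, EffectSpec(n_regions=5))


class TestSamplePeaks:
    def test_no_dropout_keeps_everything(self):
        cons = generate_consensus_regions(20, seed=3)
        peaks = generate_sample_peaks(cons, dropout=0.0, jitter=0, seed=1, sample_ids=5)
        assert all(len(ps) == 20 for ps in peaks.values())

    def test_zero_jitter_identical_intervals(self):
        cons = generate_consensus_regions(10, seed=4)
        peaks = generate_sample_peaks(cons, dropout=0.0, jitter=0, seed=2, sample_ids=2)
        for ps in peaks.values():
            assert ps.df[["start", "end"]].equals(cons.df[["start", "end"]])

    def test_dropout_occupancy_matches_binomial(self):
        cons = generate_consensus_regions(1, seed=5, min_len=400, max_len=500)
        occ = []
        for seed in range(1000):
            peaks = generate_sample_peaks(cons, dropout=0.5, jitter=0, seed=seed,
                                          sample_ids=20)
            occ.append(sum(len(ps) for ps in peaks.values()))
        mean_occ = np.mean(occ)
        se = np.sqrt(20 * 0.25 / 1000)
        assert abs(mean_occ - 10.0) <= 3 * se

    def test_oversized_jitter_rejected(self):
        cons = generate_consensus_regions(5, seed=6, min_len=100, max_len=120)
        with pytest.raises(ValueError, match="jitter"):
            generate_sample_peaks(cons, dropout=0.0, jitter=60, seed=0)


class TestSequences:
    def _pwm(self):
        return PWM("toy", np.array([[0.9, 0.03, 0.03, 0.04]] * 5), pseudocount=0.0)

    def test_background_consensus_frequency(self):
        regions = generate_consensus_regions(10, seed=7, min_len=900, max_len=1100)
        seqs, _ = generate_sequences(regions, None, None, seed=7, gc=0.5)
        text = "".join(seqs.values())
        # AAAAA occurrence rate ~ (1/4)^5 per offset under uniform composition
        count = sum(1 for i in range(len(text) - 4) if text[i:i + 5] == "AAAAA")
        n = len(text) - 4
        expect = n * 0.25**5
        assert abs(count - expect) <= 4 * np.sqrt(expect)

    def test_planted_consensus_at_recorded_offset(self):
        regions = generate_consensus_regions(5, seed=8, min_len=200, max_len=300)
        pwm = self._pwm()
        ids = set(list(regions.region_ids)[:2])
        seqs, offsets = generate_sequences(regions, pwm, ids, seed=8)
        for rid in ids:
            off = offsets[rid]
            assert seqs[rid][off:off + 5] == pwm.consensus

    def test_gc_fraction_within_three_sigma(self):
        regions = generate_consensus_regions(20, seed=9, min_len=400, max_len=600)
        seqs, _ = generate_sequences(regions, None, None, seed=9, gc=0.5)
        text = "".join(seqs.values())
        gc = sum(1 for b in text if b in "GC") / len(text)
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / len(text))

    def test_region_shorter_than_motif_rejected(self):
        regions = generate_consensus_regions(1, seed=10, min_len=3, max_len=4, gap=10)
        with pytest.raises(ValueError, match="shorter"):
            generate_sequences(regions, self._pwm(), set(regions.region_ids), seed=0)


class TestPyroTable:
    def _truth(self, direction="up"):
        return pd.DataFrame(
            {"status": ["pae_specific"], "direction": [direction],
             "true_log2fc": [1.0 if direction == "up" else -1.0]},
            index=["region_0"],
        )

    def test_zero_offset_groups_equal_in_expectation(self):
        t = generate_pyro_table(self._truth(), n_cpgs=8, group_offset=0.0,
                                noise_sd=2.0, seed=1, n_animals=30)
        means = t.groupby("group")["percent"].mean()
        n = (t["group"] == "PAE").sum()
        assert abs(means["PAE"] - means["C"]) < 3 * 2.0 / np.sqrt(n)

    def test_noiseless_offset_exact(self):
        t = generate_pyro_table(self._truth(), n_cpgs=4, group_offset=5.0,
                                noise_sd=0.0, seed=2)
        wide = t.groupby(["age", "cpg", "group"])["percent"].mean().unstack("group")
        assert ((wide["PAE"] - wide["C"]) == 5.0).all()

    def test_clipped_at_hundred(self):
        t = generate_pyro_table(self._truth(), n_cpgs=4, group_offset=5.0,
                                noise_sd=0.0, seed=3, baseline=98.0)
        assert (t.loc[t["group"] == "PAE", "percent"] == 100.0).all()

    def test_empty_assay_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_pyro_table(self._truth(), n_cpgs=0, group_offset=1.0,
                                noise_sd=1.0, seed=4)


def test_fasta_output_wrapped_and_readable(tmp_path):
    from Bio import SeqIO

    regions = generate_consensus_regions(3, seed=12, min_len=150, max_len=200)
    seqs, _ = generate_sequences(regions, None, None, seed=12)
    path = tmp_path / "r.fasta"
    synthetic.write_fasta(seqs, path)
    lines = path.read_text().splitlines()
    assert all(len(ln) <= 60 for ln in lines if not ln.startswith(">"))
    back = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    assert back == seqs


def test_gene_sets_respect_size_bounds():
    sets = synthetic.generate_gene_sets([f"g{i}" for i in range(50)], n_sets=10,
                                        seed=3, min_size=2, max_size=8)
    assert len(sets) == 10
    assert all(2 <= len(v) <= 8 for v in sets.values())
    assert all(len(set(v)) == len(v) for v in sets.values())


def test_named_substreams_are_independent():
    a1 = synthetic.substream(5, "counts").normal(size=4)
    a2 = synthetic.substream(5, "counts").normal(size=4)
    b = synthetic.substream(5, "sequences").normal(size=4)
    np.testing.assert_array_equal(a1, a2)
    assert not np.allclose(a1, b)


def test_designs_have_expected_shape():
    dev = developmental_design()
    assert len(dev) == 48 and dev["breeding"].nunique() == 4
    tis = tissue_design()
    assert len(tis) == 24 and set(tis["tissue"]) == {"hypothalamus", "wbc"}
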