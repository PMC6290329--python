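"""NB GLM testing, BH adjustment, and the exposure-specific call rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from medipdmr import dmr, synthetic
from medipdmr.dmr import (
    DesignSpec,
    bh_adjust,
    call_pae_specific,
    estimate_dispersion,
    fit_and_test,
    fold_change_class,
    tissue_concordance,
)
from medipdmr.normalize import CountMatrix


def count_matrix(vals, samples):
    vals = pd.DataFrame(np.asarray(vals, float))
    vals.index = [f"r{i}" for i in range(len(vals))]
    vals.columns = samples
    return CountMatrix(values=vals, lengths=pd.Series(500.0, index=vals.index),
                       totals=vals.sum(axis=0) + 1, state="raw")


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self):
        design = synthetic.developmental_design(ages=("P1", "P8"))  # 24 samples
        spec = synthetic.EffectSpec(n_regions=5000, frac_pae_specific=0,
                                    nb_dispersion=0.0, batch_shift_sd=0.0, seed=21)
        m, _ = synthetic.generate_counts(design, spec)
        d = DesignSpec(metadata=design)
        disp = estimate_dispersion(m, d)
        assert disp.attrs["common"] <= 0.01

    def test_nb_dispersion_recovered(self):
        design = synthetic.developmental_design(ages=("P1", "P8"))
        spec = synthetic.EffectSpec(n_regions=5000, frac_pae_specific=0,
                                    nb_dispersion=0.2, batch_shift_sd=0.0, seed=22)
        m, _ = synthetic.generate_counts(design, spec)
        disp = estimate_dispersion(m, DesignSpec(metadata=design))
        assert abs(disp.attrs["common"] - 0.2) / 0.2 <= 0.15

    def test_single_region_equals_common(self):
        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=1, frac_pae_specific=0,
                                    batch_shift_sd=0.0, seed=23)
        m, _ = synthetic.generate_counts(design, spec)
        disp = estimate_dispersion(m, DesignSpec(metadata=design, covariates=()))
        assert disp.iloc[0] == pytest.approx(disp.attrs["common"])

    def test_all_zero_region_flagged(self):
        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=50, frac_pae_specific=0,
                                    batch_shift_sd=0.0, seed=24)
        m, _ = synthetic.generate_counts(design, spec)
        m.values.iloc[0] = 0.0
        disp = estimate_dispersion(m, DesignSpec(metadata=design, covariates=()))
        assert "region_0" in disp.attrs["all_zero_regions"]
        assert (disp > 0).all()


class TestFitAndTest:
    def test_planted_effect_recovered(self):
        design = synthetic.developmental_design()
        spec = synthetic.EffectSpec(n_regions=1000, frac_pae_specific=0.5,
                                    log2_effect=1.0, batch_shift_sd=0.0, seed=31)
        m, truth = synthetic.generate_counts(design, spec)
        d = DesignSpec(metadata=design)
        t = fit_and_test(m, d, estimate_dispersion(m, d).attrs["common"])
        planted = truth["status"] == "pae_specific"
        est = t.loc[planted.index[planted], "log2fc_PAEvC"]
        signed = est * np.sign(truth.loc[planted, "true_log2fc"])
        assert abs(signed.median() - 1.0) <= 0.15

    def test_null_p_uniform(self):
        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=3000, frac_pae_specific=0,
                                    batch_shift_sd=0.0, seed=32)
        m, _ = synthetic.generate_counts(design, spec)
        d = DesignSpec(metadata=design, covariates=("breeding",))
        t = fit_and_test(m, d, estimate_dispersion(m, d).attrs["common"])
        p = t[["p_PAEvC", "p_PAEvPF", "p_PFvC"]].to_numpy().ravel()
        p = p[~np.isnan(p)]
        frac = (p < 0.05).mean()
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_offset_shift_invariance(self):
        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=100, batch_shift_sd=0.0, seed=33)
        m, _ = synthetic.generate_counts(design, spec)
        d1 = DesignSpec(metadata=design, covariates=("breeding",))
        t1 = fit_and_test(m, d1, 0.2)
        d2 = DesignSpec(metadata=design, covariates=("breeding",),
                        offset=m.totals * 2.0)
        t2 = fit_and_test(m, d2, 0.2)
        np.testing.assert_allclose(
            t1[["log2fc_PAEvC", "p_PAEvC"]], t2[["log2fc_PAEvC", "p_PAEvC"]],
            rtol=1e-6, atol=1e-10,
        )

    def test_doubling_counts_and_offset_keeps_log2fc(self):
        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=100, batch_shift_sd=0.0, seed=34)
        m, _ = synthetic.generate_counts(design, spec)
        # exact for the Poisson member of the family (score equation scales)
        d = DesignSpec(metadata=design, covariates=("breeding",))
        t1 = fit_and_test(m, d, 0.0)
        doubled = m.copy_with(m.values * 2, "raw")
        doubled.totals = m.totals * 2
        t2 = fit_and_test(doubled, DesignSpec(metadata=design, covariates=("breeding",)), 0.0)
        np.testing.assert_allclose(t1["log2fc_PAEvC"], t2["log2fc_PAEvC"], atol=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        design = synthetic.developmental_design(ages=("P1",))
        spec = synthetic.EffectSpec(n_regions=5, batch_shift_sd=0.0, seed=35)
        m, _ = synthetic.generate_counts(design, spec)
        d = DesignSpec(metadata=design, covariates=("breeding",))
        alpha = 0.2
        t = fit_and_test(m, d, alpha)
        X = d.design_matrices(m.samples)
        off = d.offset_vector(m)
        for i in range(5):
            y = np.round(m.values.iloc[i].to_numpy())
            full = sm.GLM(y, X["full"], offset=off,
                          family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            red = sm.GLM(y, X["PAEvC"], offset=off,
                         family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            lrt = 2 * (full.llf - red.llf)
            p_sm = stats.chi2.sf(max(lrt, 0.0), 1)
            assert t["p_PAEvC"].iloc[i] == pytest.approx(p_sm, abs=1e-4)
            assert t["log2fc_PAEvC"].iloc[i] == pytest.approx(
                full.params[-2] / np.log(2), abs=1e-4
            )

    def test_degenerate_design_rejected(self):
        design = synthetic.developmental_design(ages=("P1",))
        design = design[design["group"] != "PF"]
        with pytest.raises(ValueError, match="PF"):
            DesignSpec(metadata=design)


class TestBH:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (bh_adjust(np.ones(5)) == 1.0).all()

    def test_empty(self):
        assert bh_adjust(np.array([])).size == 0

    def test_nan_passthrough_not_counted(self):
        p = np.array([0.01, np.nan, 0.02, 0.03])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2, 3]], bh_adjust(np.array([0.01, 0.02, 0.03])))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_definition_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        # brute-force step-up with cumulative minimum
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        expect = np.minimum(1, np.minimum.accumulate(ranked[::-1])[::-1])
        brute = np.empty(m)
        brute[order] = expect
        np.testing.assert_allclose(q, brute)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_qvalues_dominate_p_and_stay_in_unit_interval(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-12)).all()


class TestCallRule:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["p_PAEvC", "p_PAEvPF", "p_PFvC",
                           "log2fc_PAEvC", "log2fc_PAEvPF", "log2fc_PFvC"],
        )
        df.index = [f"r{i}" for i in range(len(df))]
        return df

    def test_called_when_pf_contrast_null(self):
        t = self._table([[0.01, 0.01, 0.50, 1.0, 0.9, 0.0]])
        out = call_pae_specific(t, alpha=0.05)
        assert out.table["pae_specific"].iloc[0]
        assert out.table["direction"].iloc[0] == "up"

    def test_not_called_when_pf_significant(self):
        t = self._table([[0.001, 0.001, 0.001, 1.0, 0.9, 1.0]])
        out = call_pae_specific(t, alpha=0.05)
        assert not out.table["pae_specific"].iloc[0]

    def test_direction_requires_sign_agreement(self):
        t = self._table([[0.001, 0.001, 0.9, 1.0, -0.5, 0.0]])
        out = call_pae_specific(t, alpha=0.05)
        assert out.table["direction"].iloc[0] == "none"
        assert out.counts["n_direction_discordant"] == int(out.table["pae_specific"].iloc[0])

    def test_truth_table_confusion(self):
        design = synthetic.developmental_design()
        spec = synthetic.EffectSpec(n_regions=2000, frac_pae_specific=0.05,
                                    frac_pf_shared=0.05, log2_effect=1.5, seed=41)
        m, truth = synthetic.generate_counts(design, spec)
        d = DesignSpec(metadata=design)
        t = fit_and_test(m, d, estimate_dispersion(m, d).attrs["common"])
        out = call_pae_specific(t, alpha=0.05)
        joined = out.table.join(truth, rsuffix="_t")
        shared_rate = joined.loc[joined["status"] == "pf_shared", "pae_specific"].mean()
        assert shared_rate <= 0.05
        sens = joined.loc[joined["status"] == "pae_specific", "pae_specific"].mean()
        assert sens > 0.5  # reported; planted effect is strong at this size


class TestConcordanceAndFoldChange:
    def test_concordance_rules(self):
        calls = pd.Series([True, True, True], index=["a", "b", "c"])
        h = pd.Series([0.4, 0.4, 0.0], index=calls.index)
        w = pd.Series([0.2, -0.2, 0.4], index=calls.index)
        out = tissue_concordance(h, w, calls)
        assert out.loc["a", "concordant"] and not out.loc["b", "concordant"]
        assert out.loc["c", "indeterminate"] and out.attrs["n_zero_excluded"] == 1

    def test_random_signs_retain_half(self, rng):
        n = 4000
        calls = pd.Series(True, index=range(n))
        h = pd.Series(rng.normal(size=n))
        w = pd.Series(rng.normal(size=n))
        out = tissue_concordance(h, w, calls)
        assert abs(out["concordant"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_fold_change_examples(self):
        fc = fold_change_class(pd.Series([30.0, 10.0]), pd.Series([20.0, 10.0]))
        assert fc["fold_change"].iloc[0] == pytest.approx(1.5)
        assert fc["fc_class"].iloc[0] == ">=1.5"
        assert fc["fold_change"].iloc[1] == pytest.approx(1.0)
        assert fc["fc_class"].iloc[1] == "<1.5"

    def test_fold_change_matches_ratio_oracle(self, rng):
        a = pd.Series(rng.uniform(1, 100, 50))
        b = pd.Series(rng.uniform(1, 100, 50))
        fc = fold_change_class(a, b)["fold_change"].to_numpy()
        expect = np.maximum(a / b, b / a).to_numpy()
        np.testing.assert_allclose(fc, expect)

    def test_zero_means_require_eps(self):
        with pytest.raises(ValueError, match="eps"):
            fold_change_class(pd.Series([0.0]), pd.Series([5.0]))
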