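"""Line-panel and expression statistics: genotype classes, exact binomial CIs,
the epistasis ANOVA, dosage r2, and the NB interaction test."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from introscan.pheno import (
    genotype_class,
    genotype_r2,
    interaction_test,
    line_binom_ci,
    nb_interaction_test,
    survival_anova,
)
from introscan.synth import PanelScenario, gen_expression_counts, gen_line_panel


class TestGenotypeClass:
    @pytest.mark.parametrize(
        "a2r, ax, expected",
        [
            ("C", "T", "tropical_tropical"),
            ("A", "A", "temperate_temperate"),
            ("C", "A", "tropical_temperate"),
            ("A", "T", "temperate_tropical"),
        ],
    )
    def test_mapping(self, a2r, ax, expected):
        assert genotype_class(a2r, ax) == expected

    def test_bijective_over_combinations(self):
        classes = {genotype_class(a, x) for a in "CA" for x in "TA"}
        assert len(classes) == 4

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError):
            genotype_class("G", "T")
        with pytest.raises(ValueError):
            genotype_class("C", "C")


class TestLineBinomCi:
    def test_boundary_cases(self):
        assert line_binom_ci(0, 20)[0] == 0.0
        assert line_binom_ci(20, 20)[1] == 1.0

    def test_beta_quantile_example(self):
        lo, hi = line_binom_ci(5, 20)
        assert (round(lo, 4), round(hi, 4)) == (0.0866, 0.4910)

    def test_matches_reference_implementation(self):
        for s, n in [(3, 17), (0, 9), (12, 12), (30, 100)]:
            lo, hi = line_binom_ci(s, n)
            ref_lo, ref_hi = proportion_confint(s, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(np.nan_to_num(ref_lo), abs=1e-10)
            assert hi == pytest.approx(np.nan_to_num(ref_hi, nan=1.0), abs=1e-10)

    def test_coverage_at_nominal_level(self):
        # exact intervals are conservative: simulated coverage >= 95% - margin
        rng = np.random.default_rng(0)
        for p in (0.1, 0.3, 0.5):
            surv = rng.binomial(30, p, size=2000)
            cover = np.mean([line_binom_ci(s, 30)[0] <= p <= line_binom_ci(s, 30)[1] for s in surv])
            assert cover >= 0.94

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            line_binom_ci(1, 0)
        with pytest.raises(ValueError):
            line_binom_ci(5, 4)


class TestSurvivalAnova:
    def test_interaction_detected_in_epistatic_panel(self):
        panel = gen_line_panel(PanelScenario(epistatic_effect=1.5), seed=1)
        f, p, (dfn, _) = interaction_test(panel)
        assert dfn == 1
        assert p < 0.05 and f > 4

    def test_locus_order_invariance(self):
        panel = gen_line_panel(PanelScenario(epistatic_effect=1.0), seed=2)
        swapped = panel.rename(columns={"allele_2R": "allele_X", "allele_X": "allele_2R"})
        # swapping creates invalid allele codes; recode to each locus alphabet
        swapped["allele_2R"] = swapped["allele_2R"].map({"T": "C", "A": "A"})
        swapped["allele_X"] = swapped["allele_X"].map({"C": "T", "A": "A"})
        f1, _, _ = interaction_test(panel)
        f2, _, _ = interaction_test(swapped)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_covariates_in_table(self):
        panel = gen_line_panel(PanelScenario(), seed=3)
        table = survival_anova(panel, include_covariates=True)
        assert any("wolbachia" in str(i) for i in table.index)

    def test_monomorphic_locus_rejected(self):
        panel = gen_line_panel(PanelScenario(), seed=4)
        panel["allele_2R"] = "C"
        with pytest.raises(ValueError):
            survival_anova(panel)

    def test_weighted_variant_runs(self):
        panel = gen_line_panel(PanelScenario(epistatic_effect=1.5), seed=5)
        f, p, _ = interaction_test(panel, weight_by_assayed=True)
        assert np.isfinite(f) and 0 <= p <= 1


class TestGenotypeR2:
    def test_identical_and_complementary(self):
        a = np.array([0, 1, 1, 0, 1, 0], float)
        assert genotype_r2(a, a) == pytest.approx(1.0)
        assert genotype_r2(a, 1 - a) == pytest.approx(1.0)

    def test_symmetry_and_label_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 2, 100).astype(float), rng.integers(0, 2, 100).astype(float)
        assert genotype_r2(a, b) == pytest.approx(genotype_r2(b, a))
        assert genotype_r2(a, b) == pytest.approx(genotype_r2(1 - a, b))

    def test_null_expectation_one_over_n(self):
        rng = np.random.default_rng(1)
        n = 1000
        vals = [
            genotype_r2(rng.integers(0, 2, n).astype(float), rng.integers(0, 2, n).astype(float))
            for _ in range(500)
        ]
        # E[r2] = 1/n under independence; SE of the mean ~ sqrt(2)/n/sqrt(500)
        assert np.mean(vals) == pytest.approx(1 / n, abs=4 * np.sqrt(2) / n / np.sqrt(500))

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            genotype_r2(np.zeros(10), np.arange(10.0))


class TestNbInteraction:
    def test_offset_invariance_under_joint_scaling(self):
        """Doubling every count and every normalization factor jointly leaves
        the interaction estimates unchanged (the offset absorbs the scale).
        Rescaling a single sample is only approximately neutral, since the
        ML variance weights of that sample change."""
        counts, sheet, _ = gen_expression_counts(
            10, backgrounds=["VT", "SK"], n_replicates=3, interaction_effect=1.0, seed=1
        )
        res1 = nb_interaction_test(
            counts, sheet["background"], sheet["temperature"], sheet["norm_factor"],
            reference_background="VT",
        )
        res2 = nb_interaction_test(
            counts * 2, sheet["background"], sheet["temperature"],
            sheet["norm_factor"] * 2, reference_background="VT",
        )
        assert np.allclose(res1["estimate"], res2["estimate"], atol=0.02)

        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 10
        nf = sheet["norm_factor"].copy()
        nf.iloc[0] *= 10
        res3 = nb_interaction_test(
            scaled, sheet["background"], sheet["temperature"], nf,
            reference_background="VT",
        )
        assert np.allclose(res1["estimate"], res3["estimate"], atol=0.05)

    def test_effect_recovered_on_log_scale(self):
        counts, sheet, carriers = gen_expression_counts(
            40, backgrounds=["VT", "SK"], n_replicates=6,
            interaction_effect=2.0, dispersion=0.05, seed=2,
        )
        res = nb_interaction_test(
            counts, sheet["background"], sheet["temperature"], sheet["norm_factor"],
            reference_background="VT",
        )
        assert res["estimate"].mean() == pytest.approx(2.0 * np.log(2), abs=0.15)

    def test_all_zero_gene_skipped(self):
        counts, sheet, _ = gen_expression_counts(
            5, backgrounds=["VT", "SK"], n_replicates=3, seed=3
        )
        counts.iloc[0] = 0
        res = nb_interaction_test(
            counts, sheet["background"], sheet["temperature"], sheet["norm_factor"]
        )
        assert "gene_1" not in set(res["gene"])

    def test_poisson_limit_agreement(self):
        import statsmodels.api as sm

        counts, sheet, _ = gen_expression_counts(
            20, backgrounds=["VT", "SK"], n_replicates=6,
            interaction_effect=1.0, dispersion=1e-4, seed=4,
        )
        res = nb_interaction_test(
            counts, sheet["background"], sheet["temperature"], sheet["norm_factor"],
            reference_background="VT",
        ).set_index("gene")
        bg = (sheet["background"] != "VT").to_numpy(float)
        hot = (sheet["temperature"] == "34C").to_numpy(float)
        exog = np.column_stack([np.ones(len(sheet)), bg, hot, bg * hot])
        offset = np.log(sheet["norm_factor"].to_numpy())
        for gene in counts.index:
            pois = sm.GLM(
                counts.loc[gene].to_numpy(float), exog, offset=offset,
                family=sm.families.Poisson(),
            ).fit()
            assert res.loc[gene, "estimate"] == pytest.approx(pois.params[3], rel=0.01)

    def test_rejects_bad_design(self):
        counts, sheet, _ = gen_expression_counts(
            3, backgrounds=["VT", "SK"], n_replicates=3, seed=5
        )
        with pytest.raises(ValueError):
            nb_interaction_test(
                counts, np.repeat("VT", len(sheet)), sheet["temperature"], sheet["norm_factor"]
            )
        with pytest.raises(ValueError):
            nb_interaction_test(
                counts, sheet["background"], sheet["temperature"],
                np.zeros(len(sheet)),
            )
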