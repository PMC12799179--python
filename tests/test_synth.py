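"""Synthetic-data generators: truth emission, noise structure, selection
wiring, reproducibility."""

import numpy as np
import pytest

from introscan.simulate import SimParams, expected_backcross_frequency
from introscan.synth import (
    FocalLocus,
    PanelScenario,
    ParentalScenario,
    SeasonalScenario,
    demo_scan_scenario,
    gen_expression_counts,
    gen_f16_pools,
    gen_line_panel,
    gen_parental_pools,
    gen_seasonal_series,
)
from introscan.windows import build_window_map


@pytest.fixture(scope="module")
def tiny_map():
    return build_window_map(
        {"2R": 2}, {"2R": 300_000}, n_sites_per_window=10, seed=1
    )


class TestParentalScenario:
    def test_focal_override_and_validation(self, tiny_map):
        wid = tiny_map[0].id
        scen = ParentalScenario.random(
            tiny_map, focal_loci=[FocalLocus(wid, 3, 0.598, 1.0, 0.0)], seed=0
        )
        assert scen.vt_freqs[3] == 0.598 and scen.sk_freqs[3] == 1.0

    def test_focal_outside_map_rejected(self, tiny_map):
        with pytest.raises(ValueError):
            ParentalScenario.random(
                tiny_map, focal_loci=[FocalLocus("3L:1-10", 0, 0.5, 1.0)], seed=0
            )
        with pytest.raises(ValueError):
            ParentalScenario.random(
                tiny_map, focal_loci=[FocalLocus(tiny_map[0].id, 99, 0.5, 1.0)], seed=0
            )

    def test_background_spectrum_intermediate(self, tiny_map):
        scen = ParentalScenario.random(tiny_map, seed=3)
        for v in (scen.vt_freqs, scen.sk_freqs):
            assert np.all((v >= 0.05) & (v <= 0.95))


class TestParentalPools:
    def test_fixed_allele_constant_depth(self, tiny_map):
        wid = tiny_map[0].id
        scen = ParentalScenario.random(
            tiny_map, focal_loci=[FocalLocus(wid, 0, 0.598, 1.0, 0.0)], seed=1
        )
        _, sk, _ = gen_parental_pools(scen, seed=1, constant_depth=True)
        assert sk.alt[0] == 85 and sk.total[0] == 85

    def test_read_frequency_unbiased_at_focal_value(self):
        # long-run mean of simulated alt/depth over ~10^4 sites at p = 0.598
        wmap = build_window_map({"2R": 1}, {"2R": 10**7}, n_sites_per_window=10_000, seed=2)
        scen = ParentalScenario.random(wmap, seed=2)
        scen.vt_freqs[:] = 0.598
        vt, _, _ = gen_parental_pools(scen, seed=2)
        freq = vt.alt / vt.total
        se = freq.std() / np.sqrt(freq.size)
        assert abs(freq.mean() - 0.598) < 3 * se

    def test_deterministic_under_seed(self, tiny_map):
        scen = ParentalScenario.random(tiny_map, seed=4)
        a = gen_parental_pools(scen, seed=9)[0]
        b = gen_parental_pools(scen, seed=9)[0]
        assert np.array_equal(a.alt, b.alt) and np.array_equal(a.total, b.total)

    def test_rejects_degenerate(self, tiny_map):
        scen = ParentalScenario.random(tiny_map, seed=5)
        scen.mean_depth = 0.0
        with pytest.raises(ValueError):
            gen_parental_pools(scen, seed=0)


class TestF16Pools:
    def test_neutral_means_match_recurrence(self, tiny_map, design):
        scen = ParentalScenario.random(tiny_map, seed=6)
        pools, truth = gen_f16_pools(scen, design, n_replicates=60, seed=6)
        freqs = np.array([p.alt / p.total for p in pools])
        expected = expected_backcross_frequency(scen.vt_freqs, scen.sk_freqs, 8)
        # per-site MC standard error of the mean read frequency
        mean = freqs.mean(axis=0)
        se = freqs.std(axis=0) / np.sqrt(len(pools))
        frac_ok = np.mean(np.abs(mean - expected) < 3 * se)
        assert frac_ok >= 0.9
        assert not truth["true_positive"].any()

    def test_selection_exceeds_neutral_expectation(self, tiny_map, design):
        wid = tiny_map[0].id
        focal = [FocalLocus(wid, 5, 0.05, 1.0, 50.0)]
        scen = ParentalScenario.random(tiny_map, focal_loci=focal, seed=7)
        pools, truth = gen_f16_pools(scen, design, n_replicates=8, seed=7)
        neutral = expected_backcross_frequency(0.05, 1.0, 8)
        gi = scen.window_offsets()[wid] + 5
        for p in pools:
            assert p.alt[gi] / p.total[gi] > neutral
        assert truth.set_index("window").loc[wid, "true_positive"]

    def test_replicates_distinct_but_reproducible(self, tiny_map, design):
        scen = ParentalScenario.random(tiny_map, seed=8)
        pools, _ = gen_f16_pools(scen, design, n_replicates=6, seed=8)
        tables = {tuple(p.alt.tolist()) for p in pools}
        assert len(tables) == 6
        again, _ = gen_f16_pools(scen, design, n_replicates=6, seed=8)
        assert all(np.array_equal(a.alt, b.alt) for a, b in zip(pools, again))

    def test_rejects_zero_replicates(self, tiny_map, design):
        scen = ParentalScenario.random(tiny_map, seed=9)
        with pytest.raises(ValueError):
            gen_f16_pools(scen, design, n_replicates=0, seed=0)


class TestSeasonalSeries:
    def test_null_has_no_env_slope(self):
        scen = SeasonalScenario(beta_seasonal=0.0, collections_per_year=20, years=[2016, 2017, 2018])
        samples, _ = gen_seasonal_series(scen, seed=10)
        z = samples["true_z"].to_numpy()
        y = samples["true_freq"].to_numpy()
        slope = np.polyfit(z, y, 1)[0]
        resid_se = y.std() / np.sqrt(len(y))
        assert abs(slope) < 3 * max(resid_se, 1e-12) + 1e-9

    def test_truth_follows_logit_model(self):
        from scipy.special import logit

        scen = SeasonalScenario(beta_seasonal=-0.089)
        samples, _ = gen_seasonal_series(scen, seed=11)
        lo = logit(samples["true_freq"].to_numpy())
        fit = np.polyfit(samples["true_z"], lo, 1)
        assert fit[0] == pytest.approx(-0.089, abs=1e-9)
        assert fit[1] == pytest.approx(logit(scen.baseline_freq), abs=1e-9)

    def test_env_table_covers_all_lag_windows(self):
        samples, env = gen_seasonal_series(SeasonalScenario(), seed=12)
        env_dates = set(env["date"])
        for d in samples["date"]:
            for back in range(90):
                assert (d - np.timedelta64(back, "D")).strftime("%Y-%m-%d") in env_dates

    def test_constant_env_flagged_degenerate(self):
        scen = SeasonalScenario(env_amplitude=0.0, ar_sd=0.0, statistic="mean")
        with pytest.raises(ValueError, match="degenerate"):
            gen_seasonal_series(scen, seed=13)


class TestLinePanel:
    def test_epistatic_shift_only_on_double_tropical(self):
        panel = gen_line_panel(PanelScenario(epistatic_effect=1.5), seed=14)
        tt = panel[panel["genotype_class"] == "tropical_tropical"]
        others = panel[panel["genotype_class"] != "tropical_tropical"]
        assert tt["true_p"].nunique() == 1
        assert others["true_p"].nunique() == 1
        assert tt["true_p"].iloc[0] > others["true_p"].iloc[0]

    def test_all_classes_represented(self):
        panel = gen_line_panel(PanelScenario(n_lines=12), seed=15)
        assert panel["genotype_class"].nunique() == 4

    def test_rejects_invalid_scenarios(self):
        with pytest.raises(ValueError):
            PanelScenario(embryos_per_line=0)
        with pytest.raises(ValueError):
            PanelScenario(class_probs=(0.001, 0.333, 0.333, 0.333))
        with pytest.raises(ValueError):
            PanelScenario(n_lines=4)


class TestExpressionCounts:
    def test_truth_and_shapes(self):
        counts, sheet, carriers = gen_expression_counts(
            25, interaction_effect=2.0, carrier_fraction=0.4, seed=16
        )
        assert counts.shape == (25, len(sheet))
        assert 0 < carriers.sum() < 25

    def test_deterministic_under_seed(self):
        a = gen_expression_counts(10, seed=17)[0]
        b = gen_expression_counts(10, seed=17)[0]
        assert a.equals(b)

    def test_rejects_bad_dispersion_and_design(self):
        with pytest.raises(ValueError):
            gen_expression_counts(5, dispersion=0.0, seed=0)
        with pytest.raises(ValueError):
            gen_expression_counts(5, backgrounds=["VT"], seed=0)


class TestDemoScenario:
    def test_planted_window_labelled(self):
        scen, wid = demo_scan_scenario(seed=18)
        sel = [l for l in scen.focal_loci if l.selection_strength > 0]
        assert sel and all(l.window_id == wid for l in sel)

    def test_neutral_variant_unlabelled(self):
        scen, _ = demo_scan_scenario(seed=18, selected=False)
        assert all(l.selection_strength == 0 for l in scen.focal_loci)
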