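import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import phycofit as pf
from phycofit.simulate import SimulationConfig, simulate_experiment, simulate_library


class TestSimulateLibrary:
    def test_total_sites_near_expectation(self):
        config = SimulationConfig(n_genes=100, mean_sites_per_gene=15, seed=3)
        lib = simulate_library(config)
        in_gene = (lib.site_gene != "").sum()
        assert 1300 <= in_gene <= 1700  # Poisson(1500) within ~5 sd

    def test_zero_mean_sites_empty_library(self):
        config = SimulationConfig(
            n_genes=20, mean_sites_per_gene=0, intergenic_site_fraction=0, seed=3
        )
        lib = simulate_library(config)
        assert len(lib.positions) == 0

    def test_deterministic_under_seed(self):
        config = SimulationConfig(n_genes=30, seed=9)
        a, b = simulate_library(config), simulate_library(config)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.site_gene, b.site_gene)

    def test_sites_fall_inside_their_gene(self):
        config = SimulationConfig(n_genes=25, seed=5)
        lib = simulate_library(config)
        spans = {g.gene_id: (g.start, g.end) for g in lib.genes}
        for pos, gene_id in zip(lib.positions, lib.site_gene):
            if gene_id:
                start, end = spans[gene_id]
                assert start <= pos <= end

    def test_positions_unique(self):
        lib = simulate_library(SimulationConfig(n_genes=40, seed=1))
        assert len(np.unique(lib.positions)) == len(lib.positions)


class TestSimulateExperiment:
    def test_deterministic_under_seed(self, small_experiment):
        config, exp = small_experiment
        again = simulate_experiment(config, simulate_library(config))
        assert exp.truth.equals(again.truth)
        sample = exp.samples[0].sample_id
        assert exp.tracks[sample] == again.tracks[sample]

    def test_truth_frequencies_conserved(self, small_experiment):
        """Per-treatment gene frequencies plus the intergenic remainder
        account for the whole pool."""
        config, exp = small_experiment
        intergenic = (exp.library.site_gene == "").mean()
        for treatment, group in exp.truth.groupby("treatment"):
            assert group["true_N_t2"].sum() <= 1.0 + 1e-9
            assert group["true_N_t1"].sum() == pytest.approx(
                1.0 - config.intergenic_site_fraction, abs=0.1
            )

    def test_neutral_truth_is_unit_fitness(self, small_experiment):
        """In treatments without planted effects every mutant grows with the
        pool, so true W is exactly 1. (In treatments carrying effect genes,
        neutral mutants' pool-relative W legitimately departs from 1.)"""
        _, exp = small_experiment
        clean = exp.truth[exp.truth["treatment"].isin(["Rp", "Rp+M"])]
        neutral = clean[clean["multiplier"] == 1.0]
        assert np.allclose(neutral["true_W"], 1.0, atol=1e-9)

    def test_knockout_collapses_only_in_its_treatment(self, small_result):
        """A gene with growth multiplier 0 in one treatment: frequency decays
        ~1/d, so W falls to the persisting-nongrower value ln(2)/ln(d+1),
        and stays neutral elsewhere; the estimate tracks the closed form."""
        result, truth = small_result
        w = result.mean_fitness.set_index(["gene_id", "treatment"])["W_mean"]
        tru = truth.set_index(["gene_id", "treatment"])["true_W"]
        assert tru.loc[("SYN01", "Rp+V")] < 0.25
        assert w.loc[("SYN01", "Rp+V")] == pytest.approx(
            tru.loc[("SYN01", "Rp+V")], abs=0.05
        )
        assert w.loc[("SYN01", "Rp")] == pytest.approx(1.0, abs=0.05)

    def test_inconsistent_effect_table_rejected(self):
        config = SimulationConfig(
            n_genes=5, seed=1, effect_table={("NOPE", "Rp+V"): 0.5}
        )
        lib = simulate_library(config)
        with pytest.raises(ValueError, match="NOPE"):
            simulate_experiment(config, lib)

    def test_cell_records_match_configured_expansion(self, small_result):
        result, truth = small_result
        d_by_treatment = truth.groupby("treatment")["d"].first()
        for row in result.expansion.itertuples():
            assert row.d == pytest.approx(d_by_treatment[row.treatment])


class TestRecovery:
    def test_estimated_w_monotone_in_multiplier(self):
        """Across the multiplier grid the pipeline's W estimates are monotone
        and rank-correlate with truth above 0.9."""
        grid = [0.25, 0.5, 1.0, 1.5]
        effect = {}
        gene_ids = [f"SYN{i + 1:03d}" for i in range(120)]
        for i, m in enumerate(grid * 5):  # 20 effect genes
            effect[(gene_ids[i], "Rp+V")] = m
        config = SimulationConfig(
            n_genes=120, read_depth=500_000, seed=21, effect_table=effect
        )
        result, truth = pf.run_simulated(config, seed=21)
        est = result.mean_fitness.query("treatment == 'Rp+V'").set_index(
            "gene_id"
        )["W_mean"]
        by_multiplier = {
            m: np.mean([est[g] for (g, t), mm in effect.items() if mm == m])
            for m in grid
        }
        values = [by_multiplier[m] for m in grid]
        assert values == sorted(values)
        tru = truth.query("treatment == 'Rp+V'").set_index("gene_id")["true_W"]
        graded = [g for (g, _t) in effect]  # genes spanning the grid
        rho = spearmanr(tru[graded], est[graded]).statistic
        assert rho > 0.9

    def test_high_depth_limit_approaches_truth(self):
        """With deep sequencing the pipeline W converges to the closed-form
        truth for a mid-strength effect gene."""
        config = SimulationConfig(
            n_genes=40,
            read_depth=10_000_000,
            seed=8,
            effect_table={("SYN05", "Rp+M"): 0.6},
        )
        result, truth = pf.run_simulated(config, seed=8)
        est = result.mean_fitness.set_index(["gene_id", "treatment"])["W_mean"]
        tru = truth.set_index(["gene_id", "treatment"])["true_W"]
        key = ("SYN05", "Rp+M")
        assert est.loc[key] == pytest.approx(tru.loc[key], abs=0.01)
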