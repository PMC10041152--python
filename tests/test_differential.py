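import math

import numpy as np
import pandas as pd
import pytest

from phycofit.differential import (
    bh_adjust,
    call_significance,
    contrast_table,
    log2_fold_change,
    randomization_test,
)


def brute_force_bh(p_values):
    """Independent step-up implementation straight from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "w_multi,w_rp,expected",
        [
            (1.0, 1.0, 0.0),
            (0.0, 0.0, 0.0),               # psi / psi
            (1.99, 0.99, 1.0),             # log2(2.0 / 1.0)
        ],
    )
    def test_examples(self, w_multi, w_rp, expected):
        assert log2_fold_change(w_multi, w_rp, 0.01) == pytest.approx(expected)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-0.1, 1.0)

    def test_nonpositive_psi_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(1.0, 1.0, psi=0.0)


class TestRandomizationTest:
    def test_degenerate_identical_groups(self):
        assert randomization_test([1, 1, 1, 1], [1, 1, 1, 1]) == 1.0

    def test_full_enumeration_oracle(self):
        """Two constant groups {1,1} vs {2,2}: of the C(4,2)=6 assignments
        only the observed split and its mirror reach the observed statistic."""
        assert randomization_test([1.0, 1.0], [2.0, 2.0]) == pytest.approx(2 / 6)

    def test_label_invariance_under_same_seed(self):
        a, b = [1.0, 1.4, 0.9, 1.1], [2.0, 1.8, 2.2, 2.1]
        p1 = randomization_test(a, b, rng_seed=5)
        p2 = randomization_test(list(reversed(a)), list(reversed(b)), rng_seed=5)
        assert p1 == p2

    def test_too_few_replicates_untestable(self):
        assert math.isnan(randomization_test([1.0], [1.0, 2.0]))
        assert math.isnan(
            randomization_test([1.0, np.nan], [1.0, 2.0])
        )

    def test_exact_p_never_zero(self, rng):
        for _ in range(20):
            p = randomization_test(rng.normal(10, 1, 4), rng.normal(0.1, 0.01, 4))
            assert p >= 2 / 70 - 1e-12

    @pytest.mark.parametrize("sizes", [(2, 2), (3, 3), (4, 4)])
    def test_sampling_agrees_with_enumeration(self, sizes, rng):
        """Sampled randomization p tracks the exact enumeration p within
        binomial Monte-Carlo error."""
        n1, n2 = sizes
        for trial in range(3):
            g1 = rng.normal(1.0, 0.3, n1)
            g2 = rng.normal(1.3, 0.3, n2)
            exact = randomization_test(g1, g2, rng_seed=trial)
            sampled = randomization_test(
                g1, g2, n_perm=10_000, rng_seed=trial, force_sampling=True
            )
            mc_sd = math.sqrt(exact * (1 - exact) / 10_000)
            assert abs(sampled - exact) < 4 * mc_sd + 2e-4


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestCallSignificance:
    def _frame(self, p_adj_values):
        n = len(p_adj_values)
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "contrast": ["Rp+V vs Rp"] * n,
                "log2fc": [0.5] * n,
                "p_raw": p_adj_values,
            }
        )

    def test_strict_alpha_boundary(self):
        # single-contrast, sorted p: BH leaves a monotone vector unchanged here
        frame = self._frame([0.049])
        out = call_significance(frame, alpha=0.05)
        assert out["significant"].tolist() == [True]
        out = call_significance(self._frame([0.05]), alpha=0.05)
        assert out["significant"].tolist() == [False]

    def test_empty_input(self):
        out = call_significance(self._frame([]))
        assert len(out) == 0

    def test_adjustment_within_contrast(self):
        frame = pd.DataFrame(
            {
                "gene_id": ["A", "B", "A", "B"],
                "contrast": ["c1", "c1", "c2", "c2"],
                "log2fc": [1.0] * 4,
                "p_raw": [0.01, 0.04, 0.5, 1.0],
            }
        )
        out = call_significance(frame).set_index(["contrast", "gene_id"])
        assert out.loc[("c1", "A"), "p_adj"] == pytest.approx(0.02)
        assert out.loc[("c1", "B"), "p_adj"] == pytest.approx(0.04)
        assert out.loc[("c2", "A"), "p_adj"] == pytest.approx(1.0)


class TestContrastTable:
    def _fitness(self):
        rows = []
        w = {
            ("A", "Rp"): [1.0, 1.05, 0.95, 1.0],
            ("A", "Rp+V"): [2.0, 2.1, 1.9, 2.0],
            ("B", "Rp"): [1.0, 1.1, 0.9, 1.0],
            ("B", "Rp+V"): [1.0, 0.9, 1.1, 1.0],
        }
        for (gene, treatment), values in w.items():
            for rep, val in enumerate(values, start=1):
                rows.append(
                    {"gene_id": gene, "treatment": treatment,
                     "replicate": rep, "W": val}
                )
        return pd.DataFrame(rows)

    def test_log2fc_and_flags(self):
        out = contrast_table(
            self._fitness(), contrasts=(("Rp+V", "Rp"),), seed=0
        ).set_index("gene_id")
        assert out.loc["A", "log2fc"] == pytest.approx(
            math.log2(2.01 / 1.01), abs=1e-9
        )
        assert out.loc["B", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert not out.loc["B", "significant"]

    def test_null_models_share_fold_changes(self):
        fit = self._fitness()
        pooled = contrast_table(fit, contrasts=(("Rp+V", "Rp"),), null="pooled")
        per_gene = contrast_table(fit, contrasts=(("Rp+V", "Rp"),), null="per_gene")
        assert np.allclose(pooled["log2fc"], per_gene["log2fc"])
        assert ((pooled["p_raw"] > 0) & (pooled["p_raw"] <= 1)).all()

    def test_per_gene_null_floor(self):
        out = contrast_table(
            self._fitness(), contrasts=(("Rp+V", "Rp"),), null="per_gene"
        ).set_index("gene_id")
        assert out.loc["A", "p_raw"] == pytest.approx(2 / 70)

    def test_unknown_null_rejected(self):
        with pytest.raises(ValueError):
            contrast_table(self._fitness(), null="bootstrap")
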