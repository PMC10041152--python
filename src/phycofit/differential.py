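"""Treatment contrasts: fold-changes, randomization tests, FDR control.

For each gene, fitness in a multispecies treatment is contrasted against the
single-bacterium treatment as a pseudocounted log2 fold-change,

    log2FC = log2( (W_multi + psi) / (W_Rp + psi) ),    psi = 0.01,

whose two-sided significance is assessed by a randomization test: replicate
W values are reassigned between the two treatment groups and the absolute
fold-change of group means is recomputed for every reassignment. When the
number of distinct reassignments is small (C(8, 4) = 70 for 4 vs 4
replicates) the null is enumerated exactly; otherwise 10,000 random
reassignments are sampled and p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1).

Null models
-----------
With four replicates per group a single gene's permutation distribution has
only 35 distinct absolute statistics, so the smallest attainable per-gene p
is 2/70 ~ 0.029 — too coarse for FDR control across thousands of genes (the
Benjamini-Hochberg threshold for a handful of hits sits far below it). The
pipeline therefore defaults to a pooled null ("pooled"): each gene's
exactly-enumerated permutation statistics are pooled across genes within a
contrast, and every gene's observed statistic is ranked against that common
null. This assumes neutral genes share a statistic distribution — reasonable
here because replicate scatter is dominated by sequencing sampling noise —
and restores a near-continuous p-value. The strict per-gene test is
available as null="per_gene".

P-values are Benjamini-Hochberg adjusted within each contrast and genes with
adjusted p below alpha (default 0.05) are flagged significant.
"""

from __future__ import annotations

import math
import zlib
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_PSI = 0.01
DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05

#: Multispecies-vs-single contrasts of the four-treatment design.
DEFAULT_CONTRASTS = (("Rp+V", "Rp"), ("Rp+M", "Rp"), ("Rp+V+M", "Rp"))


def log2_fold_change(w_multi: float, w_rp: float, psi: float = DEFAULT_PSI) -> float:
    """Pseudocounted log2 ratio of mean fitness values."""
    if psi <= 0:
        raise ValueError("psi must be > 0")
    if w_multi < 0 or w_rp < 0:
        raise ValueError("fitness values must be >= 0")
    return math.log2((w_multi + psi) / (w_rp + psi))


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Deterministic per-gene substream, independent of gene order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(gene_id).encode())])
    )


def _assignment_masks(
    n1: int,
    n2: int,
    n_perm: int,
    rng: np.random.Generator | None,
    force_sampling: bool = False,
) -> tuple[np.ndarray, bool]:
    """Boolean masks (one row per reassignment) selecting group 1.

    Exact enumeration of all C(n1+n2, n1) assignments when that count does
    not exceed n_perm; otherwise n_perm random assignments. Second element
    reports whether enumeration was used.
    """
    n = n1 + n2
    n_exact = math.comb(n, n1)
    if n_exact <= n_perm and not force_sampling:
        masks = np.zeros((n_exact, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks, True
    if rng is None:
        raise ValueError("sampling requested but no RNG provided")
    masks = np.zeros((n_perm, n), dtype=bool)
    base = np.zeros(n, dtype=bool)
    base[:n1] = True
    for i in range(n_perm):
        masks[i] = rng.permutation(base)
    return masks, False


def _perm_abs_stats(
    pooled: np.ndarray, masks: np.ndarray, psi: float
) -> np.ndarray:
    """|log2FC| of group means for each reassignment mask."""
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    sum1 = masks @ pooled
    mean1 = sum1 / n1
    mean2 = (pooled.sum() - sum1) / n2
    return np.abs(np.log2((mean1 + psi) / (mean2 + psi)))


def randomization_test(
    w_group_multi: Sequence[float],
    w_group_rp: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    psi: float = DEFAULT_PSI,
    rng_seed: int | np.random.Generator = 0,
    force_sampling: bool = False,
) -> float:
    """Per-gene two-sided randomization p for the log2 fold-change of means.

    Pools the replicate W values, reassigns them to two groups of the
    original sizes, and compares |log2FC|. Exact enumeration replaces
    sampling whenever the number of distinct reassignments is at most
    ``n_perm`` (then p = #{|stat*| >= |stat|} / n_assignments, the identity
    assignment included, so p is never 0). Returns NaN when either group has
    fewer than two defined values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g1, g2 = _clean(w_group_multi), _clean(w_group_rp)
    if len(g1) < 2 or len(g2) < 2:
        return float("nan")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    observed = abs(log2_fold_change(float(g1.mean()), float(g2.mean()), psi))
    pooled = np.concatenate([g1, g2])
    masks, exact = _assignment_masks(
        len(g1), len(g2), n_perm, rng, force_sampling
    )
    stats = _perm_abs_stats(pooled, masks, psi)
    hits = int((stats >= observed - 1e-12).sum())
    if exact:
        return hits / len(stats)
    return (1 + hits) / (len(stats) + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    arr = np.asarray(list(p_values), dtype=float)
    if len(arr) == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_significance(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Flag rows with adjusted p strictly below alpha (BH within contrast)."""
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        testable = out.loc[idx, "p_raw"].notna()
        sub = idx[testable]
        if len(sub):
            out.loc[sub, "p_adj"] = bh_adjust(out.loc[sub, "p_raw"])
    out["significant"] = out["p_adj"] < alpha
    return out


def contrast_table(
    fitness: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    n_perm: int = DEFAULT_N_PERM,
    psi: float = DEFAULT_PSI,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    null: str = "pooled",
) -> pd.DataFrame:
    """Full differential analysis over a tidy per-replicate fitness table.

    ``fitness`` needs columns gene_id, treatment, replicate, W. For each
    (multi, reference) contrast, genes present in both treatments are tested;
    p-values come from the pooled or per-gene null (see module docstring),
    are BH-adjusted within the contrast, and flagged at ``alpha``.
    """
    if null not in ("pooled", "per_gene"):
        raise ValueError(f"unknown null model {null!r}")
    records = []
    for multi, ref in contrasts:
        contrast_name = f"{multi} vs {ref}"
        wide = {
            treatment: fitness[fitness["treatment"] == treatment]
            .pivot(index="gene_id", columns="replicate", values="W")
            for treatment in (multi, ref)
        }
        genes = wide[multi].index.intersection(wide[ref].index)

        per_gene = []
        for gene_id in genes:
            g1 = _clean(wide[multi].loc[gene_id])
            g2 = _clean(wide[ref].loc[gene_id])
            if len(g1) < 2 or len(g2) < 2:
                per_gene.append((gene_id, g1, g2, np.nan, None))
                continue
            obs = abs(log2_fold_change(float(g1.mean()), float(g2.mean()), psi))
            per_gene.append((gene_id, g1, g2, obs, None))

        if null == "pooled":
            null_stats = []
            for gene_id, g1, g2, obs, _ in per_gene:
                if obs is np.nan or math.isnan(obs):
                    continue
                rng = _gene_rng(seed, gene_id)
                masks, _ = _assignment_masks(len(g1), len(g2), n_perm, rng)
                null_stats.append(
                    _perm_abs_stats(np.concatenate([g1, g2]), masks, psi)
                )
            pooled_null = (
                np.sort(np.concatenate(null_stats)) if null_stats else np.array([])
            )

        for gene_id, g1, g2, obs, _ in per_gene:
            if math.isnan(obs):
                p_raw = float("nan")
                log2fc = (
                    log2_fold_change(float(g1.mean()), float(g2.mean()), psi)
                    if len(g1) and len(g2)
                    else float("nan")
                )
            else:
                log2fc = log2_fold_change(float(g1.mean()), float(g2.mean()), psi)
                if null == "per_gene":
                    p_raw = randomization_test(
                        g1, g2, n_perm=n_perm, psi=psi,
                        rng_seed=_gene_rng(seed, gene_id),
                    )
                else:
                    n_null = len(pooled_null)
                    hits = n_null - np.searchsorted(
                        pooled_null, obs - 1e-12, side="left"
                    )
                    p_raw = (1 + hits) / (n_null + 1)
            records.append(
                {
                    "gene_id": gene_id,
                    "contrast": contrast_name,
                    "log2fc": log2fc,
                    "p_raw": p_raw,
                    "n_multi": len(g1),
                    "n_ref": len(g2),
                    "psi": psi,
                }
            )
    table = pd.DataFrame(records)
    if len(table):
        table = call_significance(table, alpha)
    return table
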