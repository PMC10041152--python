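"""Depth normalization and the gene-level count filters preceding fitness.

Sequencing depth differs between samples, so site counts are rescaled to the
grand mean of the per-sample totals before any frequency is computed. Reads
are then summed within genes, and genes whose mean read support across the
initial and final timepoints falls below a floor (default 10 reads) are
excluded from fitness analysis — with so few reads the frequency ratio is
dominated by sampling noise.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .curation import CuratedLibrary


def grand_mean_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so its total equals the grand mean of sample totals.

    Returns (normalized matrix, per-sample scale factors). Normalized counts
    stay fractional: frequencies are ratios, re-rounding would only add error.
    """
    if matrix.shape[1] == 0:
        raise ValueError("need at least one sample")
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    scales = totals.mean() / totals
    return matrix * scales, scales


def aggregate_by_gene(sites: pd.DataFrame, lib: CuratedLibrary) -> pd.DataFrame:
    """Sum (normalized) site counts within each gene.

    Genes with no assigned sites get all-zero rows, so the gene universe is
    stable across samples and treatments.
    """
    rows = {}
    for gene_id, keys in lib.gene_sites.items():
        if keys:
            rows[gene_id] = sites.loc[keys].sum(axis=0)
        else:
            rows[gene_id] = pd.Series(0.0, index=sites.columns)
    gene_matrix = pd.DataFrame(rows).T
    gene_matrix.index.name = "gene_id"
    return gene_matrix.loc[sorted(rows)]


def low_count_filter(
    genes: pd.DataFrame,
    initial_samples: Sequence[str],
    final_samples: Sequence[str],
    threshold: float = 10.0,
) -> tuple[pd.Index, pd.DataFrame]:
    """Drop genes averaging fewer than ``threshold`` reads across timepoints.

    The criterion is the mean of the two timepoint means: a gene is removed
    when (mean over initial samples + mean over final samples) / 2 <
    threshold (strict). Returns (retained gene index, removal log with the
    per-gene means).
    """
    if len(initial_samples) == 0 or len(final_samples) == 0:
        raise ValueError("initial and final sample sets must be non-empty")
    if set(initial_samples) & set(final_samples):
        raise ValueError("initial and final sample sets must be disjoint")
    mean_initial = genes[list(initial_samples)].mean(axis=1)
    mean_final = genes[list(final_samples)].mean(axis=1)
    avg = (mean_initial + mean_final) / 2
    removed = avg < threshold
    log = pd.DataFrame(
        {
            "mean_initial": mean_initial,
            "mean_final": mean_final,
            "mean_overall": avg,
            "removed": removed,
        }
    )
    return genes.index[~removed], log
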