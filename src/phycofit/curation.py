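"""Central-window curation of the transposon mutant library.

Insertions near the ends of a coding region often leave a functional (or
nearly functional) protein, so only insertions within the central portion of
a gene (default: the central 90%) are treated as knockouts. Sites are
assigned to genes by position; a site falling in the central window of two
overlapping genes is counted for both (fitness is computed per gene
independently) and flagged. Strand is ignored — the transposon disrupts
either strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel


@dataclass
class CuratedLibrary:
    """Result of assigning insertion sites to gene central windows.

    ``gene_sites`` maps gene_id to the (replicon, position) keys assigned to
    it; ``n_unique_mutants`` counts all sites in the input matrix,
    ``n_curated_mutants`` the distinct sites assigned to at least one gene.
    """

    gene_sites: dict[str, list[tuple[str, int]]]
    n_unique_mutants: int
    n_curated_mutants: int
    n_genes_total: int
    multiply_assigned: list[tuple[str, int]] = field(default_factory=list)

    @property
    def mean_mutants_per_gene(self) -> float:
        if self.n_genes_total == 0:
            return float("nan")
        return self.n_curated_mutants / self.n_genes_total


def central_window(gene: GeneModel, fraction: float = 0.9) -> tuple[int, int]:
    """Coordinates (low, high), 1-based inclusive, of the gene's central window.

    Trims ceil(L*(1-fraction)/2) positions from each end, so at most
    fraction*L positions qualify.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    length = gene.end - gene.start + 1
    trim = math.ceil(length * (1 - fraction) / 2)
    return gene.start + trim, gene.end - trim


def assign_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    fraction: float = 0.9,
) -> CuratedLibrary:
    """Assign each insertion site to the gene(s) whose central window holds it.

    ``sites`` is a site-by-sample matrix indexed by (replicon, position).
    Sites outside every window stay in the matrix (pool totals use all reads)
    but are not credited to any gene. Returns the curated library.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")

    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        low, high = central_window(gene, fraction)
        if high < low:  # degenerate short gene: empty window
            continue
        # IntervalTree is half-open; +1 makes [low, high] inclusive
        trees.setdefault(gene.replicon_id, IntervalTree()).addi(
            low, high + 1, gene.gene_id
        )

    gene_sites: dict[str, list[tuple[str, int]]] = {g.gene_id: [] for g in genes}
    multiply_assigned = []
    n_curated = 0
    for chrom, pos in sites.index:
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else set()
        if hits:
            n_curated += 1
            if len(hits) > 1:
                multiply_assigned.append((chrom, int(pos)))
        for hit in hits:
            gene_sites[hit.data].append((chrom, int(pos)))

    return CuratedLibrary(
        gene_sites=gene_sites,
        n_unique_mutants=len(sites),
        n_curated_mutants=n_curated,
        n_genes_total=len(genes),
        multiply_assigned=multiply_assigned,
    )


def library_summary(lib: CuratedLibrary) -> dict[str, float]:
    """Library coverage statistics: genes hit, fraction hit, mean sites/gene."""
    genes_hit = sum(1 for sites in lib.gene_sites.values() if sites)
    return {
        "n_genes_total": lib.n_genes_total,
        "genes_hit": genes_hit,
        "fraction_hit": genes_hit / lib.n_genes_total if lib.n_genes_total else 0.0,
        "n_unique_mutants": lib.n_unique_mutants,
        "n_curated_mutants": lib.n_curated_mutants,
        "mean_mutants_per_gene": lib.mean_mutants_per_gene,
    }
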