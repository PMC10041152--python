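"""Synthetic phycosphere TnSeq experiments with known ground truth.

The generator emulates the study design the pipeline targets: a pooled
transposon mutant library of one focal species grown for ~8 days in four
treatments (alone or with one or two additional bacterial species) with four
replicate flasks each, plus four sequenced inoculum aliquots. The pool
expands by a treatment-specific factor (defaults 2^6.4 alone, 2^4.4 with both
competitors, 2^5.4 in between); most mutants are neutral, while selected
genes carry per-treatment growth-rate multipliers (mutant exponential rate =
multiplier x pool rate). Growth is deterministic-exponential — noise enters
only through lognormal jitter on initial mutant abundances and through
multinomial (optionally Dirichlet-multinomial) read sampling at a configured
depth — the simplest generative model consistent with the fitness
statistic's assumptions.

Ground truth (closed-form W per gene and treatment, and the implied log2
fold-changes) is emitted alongside the data so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import relative_fitness
from .differential import log2_fold_change, DEFAULT_PSI
from .io_formats import (
    CellAbundanceRecord,
    GeneModel,
    SampleMetadata,
    write_annotation,
    write_cell_abundance,
    write_sample_metadata,
    write_wig,
)

REPLICON = "synthetic_chr1"
TREATMENTS = ("Rp", "Rp+V", "Rp+M", "Rp+V+M")

#: Pool expansion factors per treatment: 6.4 generations alone, 4.4 with both
#: competitors, intermediate treatments interpolated to 5.4.
DEFAULT_D = {
    "Rp": 2 ** 6.4,
    "Rp+V": 2 ** 5.4,
    "Rp+M": 2 ** 5.4,
    "Rp+V+M": 2 ** 4.4,
}

_SPECIES_IN_TREATMENT = {
    "Rp": ("Rp",),
    "Rp+V": ("Rp", "V"),
    "Rp+M": ("Rp", "M"),
    "Rp+V+M": ("Rp", "V", "M"),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults mirror the study design."""

    n_genes: int = 500
    mean_sites_per_gene: float = 15.0
    gene_length: int = 900
    intergenic_length: int = 100
    n_replicates: int = 4
    n_inoculum: int = 4
    treatments: tuple[str, ...] = TREATMENTS
    d_per_treatment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_D)
    )
    #: (gene_id, treatment) -> growth-rate multiplier; absent pairs are 1.
    effect_table: dict[tuple[str, str], float] = field(default_factory=dict)
    read_depth: int = 2_000_000
    dispersion: float = 0.0
    #: sd of the lognormal jitter on initial per-mutant abundances.
    init_jitter_sigma: float = 0.5
    #: fraction of insertion sites landing between genes.
    intergenic_site_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.read_depth <= 0:
            raise ValueError("counts must be positive")
        if any(m < 0 for m in self.effect_table.values()):
            raise ValueError("effect multipliers must be >= 0")


@dataclass
class SyntheticLibrary:
    genes: list[GeneModel]
    positions: np.ndarray          # 1-based site coordinates, sorted unique
    site_gene: np.ndarray          # gene_id per site, "" for intergenic


@dataclass
class SyntheticExperiment:
    config: SimulationConfig
    library: SyntheticLibrary
    tracks: dict[str, list[tuple[str, int, float]]]
    samples: list[SampleMetadata]
    cell_records: list[CellAbundanceRecord]
    truth: pd.DataFrame


def simulate_library(config: SimulationConfig) -> SyntheticLibrary:
    """Tile genes along a synthetic replicon and scatter insertion sites.

    Per-gene site counts are Poisson around ``mean_sites_per_gene`` with
    positions uniform within the gene; an additional
    ``intergenic_site_fraction`` of all sites falls uniformly into the
    intergenic gaps. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    period = config.gene_length + config.intergenic_length
    genes = []
    gene_positions: list[np.ndarray] = []
    gene_of_position: list[str] = []
    width = len(str(max(config.n_genes, 1)))
    for i in range(config.n_genes):
        start = 1 + i * period
        end = start + config.gene_length - 1
        gene_id = f"SYN{i + 1:0{width}d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                replicon_id=REPLICON,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                product="synthetic coding region",
            )
        )
        n_sites = rng.poisson(config.mean_sites_per_gene)
        n_sites = min(n_sites, config.gene_length)
        pos = rng.choice(
            np.arange(start, end + 1), size=n_sites, replace=False
        )
        gene_positions.append(np.sort(pos))
        gene_of_position.extend([gene_id] * n_sites)

    in_gene = (
        np.concatenate(gene_positions) if gene_positions else np.array([], int)
    )
    frac = config.intergenic_site_fraction
    n_intergenic = (
        int(round(len(in_gene) * frac / (1 - frac))) if frac > 0 else 0
    )
    if n_intergenic and config.intergenic_length > 0:
        gaps = np.concatenate(
            [
                np.arange(g.end + 1, g.end + 1 + config.intergenic_length)
                for g in genes
            ]
        )
        inter = rng.choice(
            gaps, size=min(n_intergenic, len(gaps)), replace=False
        )
    else:
        inter = np.array([], dtype=int)

    positions = np.concatenate([in_gene, inter]).astype(int)
    site_gene = np.array(gene_of_position + [""] * len(inter), dtype=object)
    order = np.argsort(positions)
    return SyntheticLibrary(
        genes=genes, positions=positions[order], site_gene=site_gene[order]
    )


def _sample_reads(
    rng: np.random.Generator,
    frequencies: np.ndarray,
    depth: int,
    dispersion: float,
) -> np.ndarray:
    if dispersion > 0:
        positive = frequencies > 0
        p = np.zeros_like(frequencies)
        p[positive] = rng.dirichlet(frequencies[positive] / dispersion)
        frequencies = p
    return rng.multinomial(depth, frequencies)


def simulate_experiment(
    config: SimulationConfig,
    library: SyntheticLibrary,
    psi: float = DEFAULT_PSI,
) -> SyntheticExperiment:
    """Grow the pool, sequence every sample, and record ground truth.

    Mutant i with growth multiplier m (its gene's effect in the treatment)
    changes abundance by d^m while the bulk pool changes by ~d, so its
    frequency trajectory — and hence its true W — follows in closed form.
    Cell-abundance records are generated consistent with the realized pool
    expansion, so growth accounting recovers the simulated d exactly.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED])
    )
    known_genes = {g.gene_id for g in library.genes}
    for gene_id, treatment in config.effect_table:
        if gene_id not in known_genes or treatment not in config.treatments:
            raise ValueError(
                f"effect_table key ({gene_id!r}, {treatment!r}) does not match "
                "the simulated library/treatments"
            )

    n_sites = len(library.positions)
    weights = rng.lognormal(
        mean=0.0, sigma=config.init_jitter_sigma, size=n_sites
    )
    f1 = weights / weights.sum()

    tracks: dict[str, list[tuple[str, int, float]]] = {}
    samples: list[SampleMetadata] = []
    cell_records: list[CellAbundanceRecord] = []

    def track_from(counts: np.ndarray) -> list[tuple[str, int, float]]:
        return [
            (REPLICON, int(p), float(c))
            for p, c in zip(library.positions, counts)
            if c > 0
        ]

    for k in range(1, config.n_inoculum + 1):
        sample_id = f"inoculum_{k}"
        counts = _sample_reads(rng, f1, config.read_depth, config.dispersion)
        tracks[sample_id] = track_from(counts)
        samples.append(
            SampleMetadata(
                sample_id=sample_id,
                treatment="inoculum",
                replicate=k,
                timepoint="t1",
            )
        )

    gene_ids = [g.gene_id for g in library.genes]
    truth_rows = []
    base_cfu = 1e5
    for treatment in config.treatments:
        d = config.d_per_treatment[treatment]
        multipliers = np.ones(n_sites)
        for i, gene_id in enumerate(library.site_gene):
            if gene_id:
                multipliers[i] = config.effect_table.get(
                    (gene_id, treatment), 1.0
                )
        growth = d ** multipliers
        a2 = weights * growth
        f2 = a2 / a2.sum()
        d_real = a2.sum() / weights.sum()

        for gene_id in gene_ids:
            in_gene = library.site_gene == gene_id
            n1_g = float(f1[in_gene].sum())
            n2_g = float(f2[in_gene].sum())
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "treatment": treatment,
                    "multiplier": config.effect_table.get(
                        (gene_id, treatment), 1.0
                    ),
                    "true_N_t1": n1_g,
                    "true_N_t2": n2_g,
                    "d": d_real,
                    "true_W": relative_fitness(n1_g, n2_g, d_real),
                }
            )

        species = _SPECIES_IN_TREATMENT[treatment]
        for replicate in range(1, config.n_replicates + 1):
            sample_id = f"{treatment}_r{replicate}"
            counts = _sample_reads(
                rng, f2, config.read_depth, config.dispersion
            )
            tracks[sample_id] = track_from(counts)
            samples.append(
                SampleMetadata(
                    sample_id=sample_id,
                    treatment=treatment,
                    replicate=replicate,
                    timepoint="t2",
                )
            )
            cfu_t1 = {sp: base_cfu for sp in species}
            cfu_t2 = {"Rp": base_cfu * d_real}
            if "V" in species:
                cfu_t2["V"] = base_cfu * 1e-3   # competitor crash
            if "M" in species:
                cfu_t2["M"] = base_cfu * 2.0
            cell_records.append(
                CellAbundanceRecord(
                    treatment=treatment,
                    replicate=replicate,
                    day=0.0,
                    total_bacteria=sum(cfu_t1.values()),
                    species_cfu=cfu_t1,
                )
            )
            cell_records.append(
                CellAbundanceRecord(
                    treatment=treatment,
                    replicate=replicate,
                    day=8.0,
                    total_bacteria=sum(cfu_t2.values()),
                    species_cfu=cfu_t2,
                )
            )

    truth = pd.DataFrame(truth_rows)
    ref = truth[truth["treatment"] == "Rp"].set_index("gene_id")["true_W"]
    truth["true_log2fc_vs_Rp"] = [
        log2_fold_change(row.true_W, ref[row.gene_id], psi)
        if row.treatment != "Rp" and not math.isnan(row.true_W)
        else (0.0 if row.treatment == "Rp" else float("nan"))
        for row in truth.itertuples()
    ]
    return SyntheticExperiment(
        config=config,
        library=library,
        tracks=tracks,
        samples=samples,
        cell_records=cell_records,
        truth=truth,
    )


def write_experiment(exp: SyntheticExperiment, out_dir: str | Path) -> None:
    """Emit the experiment in the pipeline's external formats.

    One wig per sample under ``wig/``, plus annotation.tsv, samples.tsv,
    cell_abundance.tsv and truth.tsv.
    """
    out = Path(out_dir)
    (out / "wig").mkdir(parents=True, exist_ok=True)
    for sample_id, track in exp.tracks.items():
        write_wig(track, out / "wig" / f"{sample_id}.wig")
    write_annotation(exp.library.genes, out / "annotation.tsv")
    write_sample_metadata(exp.samples, out / "samples.tsv")
    write_cell_abundance(exp.cell_records, out / "cell_abundance.tsv")
    exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
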