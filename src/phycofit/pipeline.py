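"""End-to-end orchestration: counts -> curation -> fitness -> contrasts.

The stages follow the order of the wet experiment's analysis: combine
per-sample wig tracks into a site-by-sample matrix, curate sites to gene
central windows, grand-mean normalize across every sample (inoculum aliquots
included), sum within genes, drop genes below the read floor separately for
each treatment (a gene may be analyzable in one treatment pair and not in
another), compute per-replicate relative fitness against the mean inoculum
frequency with the treatment's expansion factor, and contrast each
multispecies treatment against the single-bacterium treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import curation, differential, fitness, growth, io_formats, normalization


@dataclass
class PipelineResult:
    site_matrix: pd.DataFrame
    library: curation.CuratedLibrary
    library_stats: dict[str, float]
    scale_factors: pd.Series
    gene_counts: pd.DataFrame
    retained: dict[str, pd.Index]
    expansion: pd.DataFrame
    fitness: pd.DataFrame
    mean_fitness: pd.DataFrame
    contrasts: pd.DataFrame


def run_pipeline(
    site_matrix: pd.DataFrame,
    genes: list[io_formats.GeneModel],
    samples: list[io_formats.SampleMetadata],
    cell_records: list[io_formats.CellAbundanceRecord],
    central_fraction: float = 0.9,
    read_floor: float = 10.0,
    psi: float = differential.DEFAULT_PSI,
    alpha: float = differential.DEFAULT_ALPHA,
    n_perm: int = differential.DEFAULT_N_PERM,
    seed: int = 0,
    null: str = "pooled",
    contrasts: tuple[tuple[str, str], ...] = differential.DEFAULT_CONTRASTS,
) -> PipelineResult:
    """Run the full fitness analysis on an in-memory experiment."""
    lib = curation.assign_sites(site_matrix, genes, central_fraction)
    normalized, scales = normalization.grand_mean_normalize(site_matrix)
    gene_counts = normalization.aggregate_by_gene(normalized, lib)

    inoculum = [s.sample_id for s in samples if s.treatment == "inoculum"]
    if not inoculum:
        raise ValueError("no inoculum samples in metadata")
    treatment_samples: dict[str, dict[int, str]] = {}
    for s in samples:
        if s.treatment == "inoculum":
            continue
        treatment_samples.setdefault(s.treatment, {})[s.replicate] = s.sample_id

    retained = {}
    for treatment, rep_samples in treatment_samples.items():
        kept, _ = normalization.low_count_filter(
            gene_counts, inoculum, list(rep_samples.values()), read_floor
        )
        retained[treatment] = kept

    by_key: dict[tuple[str, int, float], io_formats.CellAbundanceRecord] = {}
    for rec in cell_records:
        by_key[(rec.treatment, rec.replicate, rec.day)] = rec
    d_values: dict[tuple[str, int], float] = {}
    expansion_rows = []
    for treatment, rep_samples in treatment_samples.items():
        for replicate in rep_samples:
            days = sorted(
                day
                for (t, r, day) in by_key
                if t == treatment and r == replicate
            )
            if len(days) < 2:
                raise ValueError(
                    f"need cell records at two timepoints for "
                    f"{treatment} replicate {replicate}"
                )
            est = growth.expansion_factor(
                by_key[(treatment, replicate, days[0])],
                by_key[(treatment, replicate, days[-1])],
            )
            d_values[(treatment, replicate)] = est.d
            expansion_rows.append(
                {
                    "treatment": treatment,
                    "replicate": replicate,
                    "d": est.d,
                    "generations": est.generations,
                }
            )

    fit = fitness.fitness_table(
        gene_counts, inoculum, treatment_samples, d_values, retained
    )
    mean_fit = fitness.mean_fitness(fit)
    contrast_table = differential.contrast_table(
        fit,
        contrasts=contrasts,
        n_perm=n_perm,
        psi=psi,
        alpha=alpha,
        seed=seed,
        null=null,
    )
    return PipelineResult(
        site_matrix=site_matrix,
        library=lib,
        library_stats=curation.library_summary(lib),
        scale_factors=scales,
        gene_counts=gene_counts,
        retained=retained,
        expansion=pd.DataFrame(expansion_rows),
        fitness=fit,
        mean_fitness=mean_fit,
        contrasts=contrast_table,
    )


def run_from_dir(data_dir: str | Path, **kwargs) -> PipelineResult:
    """Run the pipeline on an on-disk experiment laid out as write_experiment
    emits it (wig/ per-sample tracks + annotation/samples/cell_abundance TSVs).
    """
    data_dir = Path(data_dir)
    samples = io_formats.read_sample_metadata(data_dir / "samples.tsv")
    tracks = [
        io_formats.read_wig(data_dir / "wig" / f"{s.sample_id}.wig")
        for s in samples
    ]
    matrix = io_formats.combine_wigs(tracks, [s.sample_id for s in samples])
    genes = io_formats.read_annotation(data_dir / "annotation.tsv", "tsv")
    cells = io_formats.read_cell_abundance(data_dir / "cell_abundance.tsv")
    return run_pipeline(matrix, genes, samples, cells, **kwargs)


def run_simulated(
    config, exp=None, **kwargs
) -> tuple["PipelineResult", pd.DataFrame]:
    """Simulate an experiment and analyze it in memory; returns
    (pipeline result, truth table)."""
    from . import simulate

    if exp is None:
        library = simulate.simulate_library(config)
        exp = simulate.simulate_experiment(config, library)
    tracks = [exp.tracks[s.sample_id] for s in exp.samples]
    matrix = io_formats.combine_wigs(
        tracks, [s.sample_id for s in exp.samples]
    )
    result = run_pipeline(
        matrix, exp.library.genes, exp.samples, exp.cell_records, **kwargs
    )
    return result, exp.truth
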