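"""Per-gene mutant frequencies and the relative-fitness statistic W.

A mutant's relative fitness compares its change in pool frequency over the
experiment with the expansion of the whole mutant pool:

    W = ln( N(t2) * d / N(t1) + 1 ) / ln( (1 - N(t2)) * d / (1 - N(t1)) + 1 )

where N(t1), N(t2) are the mutant's pool frequencies at the start and end and
d is the pool expansion factor. W = 1 means pool-average growth, W = 0 means
the mutant is extinct at t2, and a mutant growing at half the pool's
exponential rate approaches W = 0.5 for large d. The "+1" terms regularize
the ratio so that extinct mutants (N2 = 0) get W = 0 rather than a log of
zero.

Missing-value policy: W is undefined when N(t1) = 0 with N(t2) > 0 (a mutant
appearing from nothing) and when N(t2) = 1; both propagate as NaN rather than
being clamped, so downstream contrasts see the gap instead of a biased value.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def mutant_frequency(gene_counts: pd.DataFrame, sample: str) -> pd.Series:
    """Per-gene pool frequency in one sample: count / sample total."""
    column = gene_counts[sample]
    total = column.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total count")
    return column / total


def relative_fitness(n1: float, n2: float, d: float) -> float:
    """Relative fitness W of one mutant; NaN where the statistic is undefined."""
    if not 0 <= n1 < 1:
        raise ValueError(f"N(t1) must be in [0, 1), got {n1}")
    if not 0 <= n2 <= 1:
        raise ValueError(f"N(t2) must be in [0, 1], got {n2}")
    if d <= 0:
        raise ValueError(f"expansion factor d must be > 0, got {d}")
    if n2 == 0:
        return 0.0 if n1 > 0 else float("nan")
    if n1 == 0 or n2 == 1:
        return float("nan")
    return math.log(n2 * d / n1 + 1) / math.log((1 - n2) * d / (1 - n1) + 1)


def gene_fitness(w_values: Iterable[float]) -> tuple[float, int]:
    """Mean W over replicates, ignoring missing values.

    Returns (mean, n contributing replicates); mean is NaN when every
    replicate is missing.
    """
    values = [w for w in w_values if not math.isnan(w)]
    if not values:
        return float("nan"), 0
    return float(np.mean(values)), len(values)


def fitness_table(
    gene_counts: pd.DataFrame,
    inoculum_samples: Sequence[str],
    treatment_samples: Mapping[str, Mapping[int, str]],
    d_values: Mapping[tuple[str, int], float],
    retained: Mapping[str, pd.Index] | None = None,
) -> pd.DataFrame:
    """Compute W for every gene x treatment x replicate.

    ``treatment_samples`` maps treatment -> {replicate -> t2 sample_id};
    ``d_values`` maps (treatment, replicate) -> expansion factor. If
    ``retained`` gives a per-treatment gene whitelist (the low-count filter's
    output), frequencies for that treatment are computed over those genes
    only, so the frequency denominator matches the analyzed gene universe.

    N(t1) is the per-gene mean frequency over the sequenced inoculum
    aliquots, which are not paired to individual flasks. Returns a tidy frame
    with columns gene_id, treatment, replicate, N_t1, N_t2, d, W.
    """
    rows = []
    for treatment, rep_samples in treatment_samples.items():
        if retained is not None and treatment in retained:
            counts = gene_counts.loc[retained[treatment]]
        else:
            counts = gene_counts
        n1 = pd.concat(
            [mutant_frequency(counts, s) for s in inoculum_samples], axis=1
        ).mean(axis=1)
        for replicate, sample in rep_samples.items():
            d = d_values[(treatment, replicate)]
            n2 = mutant_frequency(counts, sample)
            for gene_id in counts.index:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "treatment": treatment,
                        "replicate": replicate,
                        "N_t1": n1[gene_id],
                        "N_t2": n2[gene_id],
                        "d": d,
                        "W": relative_fitness(n1[gene_id], n2[gene_id], d),
                    }
                )
    return pd.DataFrame(rows)


def mean_fitness(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean fitness per gene and treatment.

    Returns a frame with columns gene_id, treatment, W_mean, n_replicates;
    genes whose replicates are all missing carry NaN with n_replicates = 0.
    """
    records = []
    for (gene_id, treatment), group in table.groupby(
        ["gene_id", "treatment"], sort=True
    ):
        mean, n = gene_fitness(group["W"])
        records.append(
            {
                "gene_id": gene_id,
                "treatment": treatment,
                "W_mean": mean,
                "n_replicates": n,
            }
        )
    return pd.DataFrame(records)
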