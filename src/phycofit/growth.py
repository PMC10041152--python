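"""Mutant-pool growth accounting.

The fitness statistic needs the expansion factor d — the fold change of the
focal species' mutant pool between the two sequenced timepoints. Total
bacterial density comes from flow cytometry; in multispecies communities the
focal species' share of that total comes from differential CFU counts, so

    d = [total(t2) * proportion(t2)] / [total(t1) * proportion(t1)]

and the generation count is log2(d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import CellAbundanceRecord


@dataclass(frozen=True)
class ExpansionEstimate:
    treatment: str
    replicate: int
    d: float
    generations: float


def species_proportion(record: CellAbundanceRecord, species: str = "Rp") -> float:
    """Fraction of the community belonging to ``species``, from CFU counts."""
    total = sum(record.species_cfu.values())
    if total <= 0:
        raise ValueError("zero total CFU: proportions undefined")
    return record.species_cfu.get(species, 0.0) / total


def expansion_factor(
    t1: CellAbundanceRecord,
    t2: CellAbundanceRecord,
    species: str = "Rp",
) -> ExpansionEstimate:
    """Pool expansion factor d and generations for the focal species."""
    if t1.total_bacteria <= 0 or t2.total_bacteria <= 0:
        raise ValueError("total bacterial abundance must be > 0 at both timepoints")
    n1 = t1.total_bacteria * species_proportion(t1, species)
    n2 = t2.total_bacteria * species_proportion(t2, species)
    if n1 <= 0:
        raise ValueError(f"zero {species} abundance at t1: d undefined")
    d = n2 / n1
    return ExpansionEstimate(
        treatment=t2.treatment,
        replicate=t2.replicate,
        d=d,
        generations=math.log2(d),
    )
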