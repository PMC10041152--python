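"""Ecological-mode classification and report tables.

Genes whose mutants show significant fitness differences in multispecies
communities are grouped into phenomenological modes of bacterial interaction
— competition for resources, crossfeeding (auxotroph rescue by released
metabolites), chemically mediated interactions (antimicrobials, signaling,
efflux), and responses to an altered shared environment (oxygen dynamics,
reactive oxygen, translation demand) — plus bookkeeping modes for genes
outside the curated scheme. Mode assignment is annotation-driven: the package
ships the curated interaction tables as a versioned mapping fixture and
accepts user mappings of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

MODES = (
    "competition",
    "crossfeeding",
    "chemically_mediated",
    "altered_environment",
    "central_metabolism",
    "regulation",
    "mixed",
    "hypothetical",
)

CONTRAST_COLUMNS = ("Rp+V", "Rp+M", "Rp+V+M")

_TABLE_FILES = (
    "table1_competition.tsv",
    "table2_crossfeeding.tsv",
    "table3_chemically_mediated.tsv",
    "table4_altered_environment.tsv",
)


@dataclass(frozen=True)
class ModeAnnotation:
    gene_id: str
    protein_name: str
    function_label: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def load_reference_tables() -> pd.DataFrame:
    """The packaged curated interaction tables, one frame with a mode column.

    Columns: gene_id, protein_name, function_label, mode, and one
    significant-log2FC column per multispecies treatment (NaN = not
    significant there).
    """
    frames = []
    for name in _TABLE_FILES:
        with resources.as_file(
            resources.files("phycofit.data").joinpath(name)
        ) as path:
            frames.append(pd.read_csv(path, sep="\t"))
    table = pd.concat(frames, ignore_index=True)
    for col in CONTRAST_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table


def load_mode_annotations(path: str | Path | None = None) -> list[ModeAnnotation]:
    """Mode mapping as records; defaults to the packaged scheme."""
    if path is None:
        frame = load_reference_tables()
    else:
        frame = pd.read_csv(path, sep="\t")
    return [
        ModeAnnotation(
            gene_id=str(r.gene_id),
            protein_name=str(r.protein_name),
            function_label=str(r.function_label),
            mode=str(r.mode),
        )
        for r in frame.itertuples()
    ]


def annotate_modes(
    contrasts: pd.DataFrame,
    annotations: pd.DataFrame | list[ModeAnnotation],
    default_mode: str = "hypothetical",
) -> pd.DataFrame:
    """Attach a mode and fitness direction to every significant contrast row.

    ``contrasts`` needs columns gene_id, contrast, log2fc, significant.
    Non-significant rows are dropped; genes missing from the annotation get
    ``default_mode``. Direction is "increase" for log2fc > 0, "decrease"
    otherwise.
    """
    if default_mode not in MODES:
        raise ValueError(f"unknown default mode {default_mode!r}")
    if isinstance(annotations, list):
        annotations = pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    "protein_name": a.protein_name,
                    "function_label": a.function_label,
                    "mode": a.mode,
                }
                for a in annotations
            ]
        )
    significant = contrasts[contrasts["significant"]].copy()
    lookup = annotations.drop_duplicates("gene_id").set_index("gene_id")
    for col in ("mode", "protein_name", "function_label"):
        significant[col] = (
            significant["gene_id"].map(lookup[col])
            if col in lookup.columns
            else np.nan
        )
    significant["mode"] = significant["mode"].fillna(default_mode)
    significant["direction"] = np.where(
        significant["log2fc"] > 0, "increase", "decrease"
    )
    return significant


def mode_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of significant genes per ecological mode.

    A gene significant in several contrasts counts once; fractions sum to 1
    over the modes present.
    """
    if len(annotated) == 0:
        return pd.DataFrame(columns=["mode", "n_significant", "fraction_of_significant"])
    per_gene = annotated.drop_duplicates("gene_id")
    counts = per_gene.groupby("mode").size()
    return pd.DataFrame(
        {
            "mode": counts.index,
            "n_significant": counts.values,
            "fraction_of_significant": counts.values / counts.sum(),
        }
    ).reset_index(drop=True)


def _round_sig(value: float, sig: int = 2) -> float:
    if value == 0 or not np.isfinite(value):
        return value
    return float(np.format_float_positional(
        value, precision=sig, unique=False, fractional=False, trim="-"
    ))


def emit_table(
    contrasts: pd.DataFrame,
    contrast_names: tuple[str, ...] = CONTRAST_COLUMNS,
    sig_figures: int | None = 2,
) -> pd.DataFrame:
    """Wide report: one row per gene, per-contrast log2FC where significant.

    Cells of non-significant (gene, contrast) pairs are blank, mirroring the
    convention that empty cells mean no significant fitness change. Contrast
    labels of the form "X vs Rp" are shortened to "X". Values are rounded to
    ``sig_figures`` significant figures (None keeps full precision).
    """
    frame = contrasts.copy()
    frame["column"] = frame["contrast"].str.replace(" vs Rp", "", regex=False)
    frame = frame[frame["significant"]]
    wide = frame.pivot(index="gene_id", columns="column", values="log2fc")
    for name in contrast_names:
        if name not in wide.columns:
            wide[name] = np.nan
    wide = wide[list(contrast_names)]
    if sig_figures is not None:
        wide = wide.map(
            lambda v: _round_sig(v, sig_figures) if pd.notna(v) else v
        )
    wide.index.name = "gene_id"
    return wide.sort_index()


def write_report(wide: pd.DataFrame, path: str | Path) -> None:
    """Write an emit_table frame as TSV with blank cells for non-significant."""
    wide.to_csv(path, sep="\t", na_rep="")


def read_report(path: str | Path) -> pd.DataFrame:
    """Re-parse a written report; inverse of write_report over emit_table."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    return frame
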