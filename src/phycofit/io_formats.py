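"""Readers and writers for the external formats the pipeline touches.

Per-site transposon insertion counts travel as UCSC text wiggle tracks (one
track per sequenced sample, ``variableStep`` or ``fixedStep``); gene models as
GFF3 or a simple 5-column TSV; sample metadata and cell-abundance tables as
TSV. Coordinates are 1-based inclusive everywhere inside the package — wig and
GFF3 are already 1-based, so conversion happens only for other dialects.

The one piece of raw-read processing kept in scope is the transposon-junction
trimming rule: locate the transposon end motif near the read start and keep
the short genomic fragment that follows it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

#: Transposon end sequence marking the transposon/genome junction.
JUNCTION_MOTIF = "AGATGTGTATAAGAGACAG"
#: The junction must start within this many bases of the read start.
JUNCTION_SEARCH_WINDOW = 60
#: Genomic bases kept downstream of the junction.
JUNCTION_KEEP_LENGTH = 22


class WigParseError(ValueError):
    """Raised for malformed wiggle input, carrying the offending line number."""


@dataclass(frozen=True)
class InsertionSite:
    """One transposon insertion position with per-sample read counts."""

    replicon_id: str
    position: int
    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for sample, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative count {count} for sample {sample!r}")


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one sequenced sample within the experimental design."""

    sample_id: str
    treatment: str
    replicate: int
    timepoint: str

    TREATMENTS = ("Rp", "Rp+V", "Rp+M", "Rp+V+M", "inoculum")

    def __post_init__(self) -> None:
        if self.treatment not in self.TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.timepoint not in ("t1", "t2"):
            raise ValueError(f"timepoint must be t1 or t2, got {self.timepoint!r}")
        if (self.treatment == "inoculum") != (self.timepoint == "t1"):
            raise ValueError(
                "inoculum samples are the t1 observations: treatment='inoculum' "
                "iff timepoint='t1'"
            )


@dataclass(frozen=True)
class GeneModel:
    """A coding region: locus tag, 1-based inclusive coordinates, strand."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CellAbundanceRecord:
    """Flow-cytometry total with CFU-based per-species composition."""

    treatment: str
    replicate: int
    day: float
    total_bacteria: float
    species_cfu: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_bacteria < 0:
            raise ValueError("total_bacteria must be >= 0")
        bad = set(self.species_cfu) - {"Rp", "V", "M"}
        if bad:
            raise ValueError(f"unknown species in CFU record: {sorted(bad)}")
        if any(v < 0 for v in self.species_cfu.values()):
            raise ValueError("CFU abundances must be >= 0")


# ---------------------------------------------------------------------------
# wiggle tracks
# ---------------------------------------------------------------------------

def read_wig(path: str | Path | io.TextIOBase) -> list[tuple[str, int, float]]:
    """Parse a text wiggle track into ordered (replicon, position, count) records.

    Both ``variableStep`` and ``fixedStep`` declarations are accepted;
    ``track`` and comment lines are ignored. Counts must be non-negative.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()

    records: list[tuple[str, int, float]] = []
    chrom: str | None = None
    mode: str | None = None
    step = span = 1
    next_pos = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if fields[0] in ("variableStep", "fixedStep"):
            params = {}
            for tok in fields[1:]:
                if "=" not in tok:
                    raise WigParseError(
                        f"line {lineno}: malformed declaration token {tok!r}"
                    )
                key, _, val = tok.partition("=")
                params[key] = val
            if "chrom" not in params:
                raise WigParseError(f"line {lineno}: declaration missing chrom=")
            chrom = params["chrom"]
            mode = fields[0]
            if mode == "fixedStep":
                try:
                    next_pos = int(params["start"])
                    step = int(params.get("step", 1))
                except (KeyError, ValueError) as exc:
                    raise WigParseError(
                        f"line {lineno}: fixedStep needs integer start/step"
                    ) from exc
            continue
        if mode is None:
            raise WigParseError(f"line {lineno}: data before any step declaration")
        try:
            if mode == "variableStep":
                if len(fields) != 2:
                    raise ValueError
                pos, count = int(fields[0]), float(fields[1])
            else:
                if len(fields) != 1:
                    raise ValueError
                pos, count = next_pos, float(fields[0])
                next_pos += step
        except ValueError:
            raise WigParseError(f"line {lineno}: malformed data line {line!r}") from None
        if count < 0:
            raise ValueError(f"line {lineno}: negative count {count}")
        records.append((chrom, pos, count))
    return records


def write_wig(records: Iterable[tuple[str, int, float]], path: str | Path) -> None:
    """Write (replicon, position, count) records as a variableStep track."""
    with open(path, "w") as handle:
        current = None
        for chrom, pos, count in records:
            if chrom != current:
                handle.write(f"variableStep chrom={chrom}\n")
                current = chrom
            val = int(count) if float(count).is_integer() else count
            handle.write(f"{pos} {val}\n")


def combine_wigs(
    tracks: Sequence[Sequence[tuple[str, int, float]]],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Merge per-sample site records into one site-by-sample count matrix.

    Rows are the union of (replicon, position) keys across tracks, missing
    entries filled with 0; sites with no insertional mutants in any sample
    (all-zero rows) are excluded. Returns a DataFrame indexed by a
    (replicon, position) MultiIndex with one column per sample.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    if len(sample_ids) != len(tracks):
        raise ValueError("sample_ids must parallel tracks")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_ids must be unique")

    columns = {}
    for sample, track in zip(sample_ids, tracks):
        keys = [(chrom, pos) for chrom, pos, _ in track]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(
                f"sample {sample!r}: duplicate position {dup} makes the count ambiguous"
            )
        columns[sample] = pd.Series(
            [c for _, _, c in track],
            index=pd.MultiIndex.from_tuples(
                keys or [("", 0)], names=["replicon", "position"]
            )[: len(keys)],
        )
    matrix = pd.DataFrame(columns).fillna(0.0)
    matrix.index.names = ["replicon", "position"]
    matrix = matrix[list(sample_ids)].sort_index()
    return matrix.loc[matrix.sum(axis=1) > 0]


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand"]


def read_annotation(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Load gene models from GFF3 (CDS/gene features) or a 5-column TSV.

    The TSV needs a header with columns gene_id, replicon_id, start, end,
    strand (an optional ``product`` column is carried through). Duplicate
    gene_ids are rejected.
    """
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        missing = set(_ANNOTATION_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
        genes = [
            GeneModel(
                gene_id=row.gene_id,
                replicon_id=str(row.replicon_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                product=str(getattr(row, "product", "") or ""),
            )
            for row in frame.itertuples()
        ]
    elif format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
        genes = []
        for feature in db.all_features():
            if feature.featuretype not in ("gene", "CDS"):
                continue
            attrs = feature.attributes
            gene_id = (
                attrs.get("locus_tag", attrs.get("ID", [feature.id]))[0]
            )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    replicon_id=feature.seqid,
                    start=feature.start,  # gffutils keeps GFF3 1-based inclusive
                    end=feature.end,
                    strand=feature.strand,
                    product=attrs.get("product", [""])[0],
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_ids in annotation: {dup}")
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "replicon_id": g.replicon_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata and cell abundances
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t")
    samples = [
        SampleMetadata(
            sample_id=str(row.sample_id),
            treatment=str(row.treatment),
            replicate=int(row.replicate),
            timepoint=str(row.timepoint),
        )
        for row in frame.itertuples()
    ]
    keys = [(s.treatment, s.replicate, s.timepoint) for s in samples]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (treatment, replicate, timepoint) in metadata")
    return samples


def write_sample_metadata(samples: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "replicate": s.replicate,
                "timepoint": s.timepoint,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_cell_abundance(path: str | Path) -> list[CellAbundanceRecord]:
    """Read a cell-abundance TSV (columns: treatment, replicate, day,
    total_bacteria, cfu_Rp, cfu_V, cfu_M; absent species columns mean the
    species was not in that community)."""
    frame = pd.read_csv(path, sep="\t")
    records = []
    for row in frame.itertuples():
        cfu = {}
        for species in ("Rp", "V", "M"):
            col = f"cfu_{species}"
            if col in frame.columns and pd.notna(getattr(row, col)):
                cfu[species] = float(getattr(row, col))
        records.append(
            CellAbundanceRecord(
                treatment=str(row.treatment),
                replicate=int(row.replicate),
                day=float(row.day),
                total_bacteria=float(row.total_bacteria),
                species_cfu=cfu,
            )
        )
    return records


def write_cell_abundance(
    records: Iterable[CellAbundanceRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "treatment": r.treatment,
                "replicate": r.replicate,
                "day": r.day,
                "total_bacteria": r.total_bacteria,
                **{f"cfu_{sp}": v for sp, v in r.species_cfu.items()},
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# junction trimming
# ---------------------------------------------------------------------------

def trim_junction_read(
    read: str,
    motif: str = JUNCTION_MOTIF,
    search_window: int = JUNCTION_SEARCH_WINDOW,
    keep_length: int = JUNCTION_KEEP_LENGTH,
) -> str | None:
    """Extract the genomic fragment downstream of the transposon junction.

    If the first occurrence of ``motif`` starts within the first
    ``search_window`` bases of the read, return the ``keep_length`` bases that
    immediately follow it (fewer if the read ends first, minimum one base);
    otherwise return None — absence of the junction is a legitimate outcome,
    not an error.
    """
    if not read:
        raise ValueError("empty read")
    hit = read.find(motif)
    if hit < 0 or hit >= search_window:
        return None
    fragment = read[hit + len(motif): hit + len(motif) + keep_length]
    return fragment or None


def trim_fastq(
    path: str | Path,
    out_path: str | Path,
    motif: str = JUNCTION_MOTIF,
    search_window: int = JUNCTION_SEARCH_WINDOW,
    keep_length: int = JUNCTION_KEEP_LENGTH,
) -> tuple[int, int]:
    """Apply the junction rule to every read of a FASTQ file.

    Trimmed fragments (with matching quality slices) go to ``out_path``;
    reads without a junction are dropped. Returns (n_reads, n_trimmed).
    """
    from Bio import SeqIO

    n_total = n_kept = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_total += 1
            seq = str(rec.seq)
            fragment = trim_junction_read(seq, motif, search_window, keep_length)
            if fragment is None:
                continue
            start = seq.find(motif) + len(motif)
            trimmed = rec[start: start + len(fragment)]
            SeqIO.write(trimmed, out, "fastq")
            n_kept += 1
    return n_total, n_kept


def _sites_to_records(
    matrix: pd.DataFrame,
) -> Iterator[InsertionSite]:
    """View a site-by-sample matrix as InsertionSite objects."""
    for (chrom, pos), row in matrix.iterrows():
        yield InsertionSite(
            replicon_id=chrom, position=int(pos), counts=row.to_dict()
        )
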