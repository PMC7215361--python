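"""Readers/writers for FASTA and ICAT peptide quantification tables.

The peptide table emulates a search-engine export of cleavable-ICAT
quantification: one row per quantified peptide observation with a
heavy:light (H:L) intensity ratio, an identification confidence, and the
cysteine positions that carried the label.  Coordinates are 1-based and
inclusive throughout, matching proteomics convention (sites are reported
like "Cys160").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)

#: Logical column names of the peptide table dialect (tab-separated, header
#: row required).  ``column_map`` in :class:`TableDialect` maps these logical
#: names onto whatever the physical file calls them.
LOGICAL_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "replicate",
    "accession",
    "peptide",
    "cys_positions",
    "confidence",
    "h_to_l",
)


class FormatError(ValueError):
    """Raised for malformed input files (FASTA or peptide tables)."""


class UnmappedPeptideError(ValueError):
    """Raised when a peptide sequence is not a substring of its protein."""

    def __init__(self, accession: str, peptide_sequence: str):
        self.accession = accession
        self.peptide_sequence = peptide_sequence
        super().__init__(
            f"unmapped peptide: {peptide_sequence!r} not found in protein "
            f"{accession!r}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from the search database."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession}")

    def cys_positions(self) -> list[int]:
        """All 1-based cysteine positions in the protein."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "C"]


@dataclass(frozen=True)
class SiteKey:
    """A single cysteine site: protein accession + 1-based residue index."""

    accession: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One quantified ICAT peptide observation in one sample.

    ``h_to_l`` is the heavy:light intensity ratio — the glutathionylated to
    reduced thiol ratio (SG/SH) for the labeled cysteines of this peptide.
    """

    sample_id: str
    subject_id: str
    group: str
    replicate_index: int
    accession: str
    peptide_sequence: str
    peptide_cys_positions: tuple[int, ...]
    confidence_pct: float
    h_to_l: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")
        for pos in self.peptide_cys_positions:
            if pos < 1 or pos > len(self.peptide_sequence):
                raise ValueError(
                    f"cysteine index {pos} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
            if self.peptide_sequence[pos - 1] != "C":
                raise ValueError(
                    f"residue {pos} of {self.peptide_sequence!r} is not 'C'"
                )
        if not (0.0 <= self.confidence_pct <= 100.0):
            raise ValueError("confidence_pct must lie in [0, 100]")
        if not (self.h_to_l > 0.0 and math.isfinite(self.h_to_l)):
            raise ValueError("h_to_l must be a positive finite ratio")

    @property
    def peptide_key(self) -> tuple[str, str, tuple[int, ...]]:
        """Identity of the quantified analyte: accession, sequence, Cys set."""
        return (self.accession, self.peptide_sequence, self.peptide_cys_positions)


@dataclass(frozen=True)
class TableDialect:
    """Configuration of the peptide-table dialect (delimiter, column names)."""

    separator: str = "\t"
    cys_separator: str = ";"
    column_map: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in LOGICAL_COLUMNS}
    )
    group_labels: Mapping[str, str] = field(
        default_factory=lambda: {CASE: CASE, CONTROL: CONTROL}
    )


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class SiteMapping:
    """Result of mapping one peptide's cysteines onto protein coordinates."""

    sites: tuple[SiteKey, ...]
    ambiguous: bool  # peptide occurs more than once in the protein


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into records keyed by accession.

    The accession is the first whitespace-delimited token after ``>``;
    sequences are uppercased with line breaks removed.  Duplicate accessions
    and empty files are errors.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate accession in FASTA: {rec.id!r}")
        records[rec.id] = ProteinRecord(
            accession=rec.id,
            description=rec.description,
            sequence=str(rec.seq).upper(),
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records to FASTA (60-column wrapped, sorted input order)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    if not seq_records:
        raise FormatError("refusing to write an empty FASTA")
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peptide quantification table
# ---------------------------------------------------------------------------

def _parse_cys_positions(text: str, separator: str) -> tuple[int, ...]:
    parts = [p for p in str(text).split(separator) if p.strip()]
    return tuple(int(p) for p in parts)


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> tuple[list[PeptideMeasurement], list[tuple[int, str]]]:
    """Parse a peptide quantification table.

    Returns ``(measurements, rejected)`` where ``rejected`` lists
    ``(row_number, reason)`` for rows with unparsable or invalid fields.
    Row numbers are 1-based over data rows (the header is row 0).
    Missing required columns and empty tables raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep=dialect.separator, dtype=str, keep_default_na=False)
    missing = [
        logical
        for logical in LOGICAL_COLUMNS
        if dialect.column_map[logical] not in df.columns
    ]
    if missing:
        raise FormatError(
            "peptide table is missing required columns: "
            + ", ".join(dialect.column_map[m] for m in missing)
        )
    if len(df) == 0:
        raise FormatError(f"peptide table {path} has no data rows")

    label_to_group = {v: k for k, v in dialect.group_labels.items()}
    col = dialect.column_map
    measurements: list[PeptideMeasurement] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        record = dict(zip(df.columns, row))
        try:
            group = label_to_group.get(record[col["group"]])
            if group is None:
                raise ValueError(f"unknown group label {record[col['group']]!r}")
            measurements.append(
                PeptideMeasurement(
                    sample_id=record[col["sample_id"]],
                    subject_id=record[col["subject_id"]],
                    group=group,
                    replicate_index=int(record[col["replicate"]]),
                    accession=record[col["accession"]],
                    peptide_sequence=record[col["peptide"]].upper(),
                    peptide_cys_positions=_parse_cys_positions(
                        record[col["cys_positions"]], dialect.cys_separator
                    ),
                    confidence_pct=float(record[col["confidence"]]),
                    h_to_l=float(record[col["h_to_l"]]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append((idx, str(exc)))
    return measurements, rejected


def measurements_to_frame(
    measurements: Sequence[PeptideMeasurement],
    dialect: TableDialect = DEFAULT_DIALECT,
) -> pd.DataFrame:
    """Render measurements back into the table dialect (inverse of reading)."""
    col = dialect.column_map
    rows = [
        {
            col["sample_id"]: m.sample_id,
            col["subject_id"]: m.subject_id,
            col["group"]: dialect.group_labels[m.group],
            col["replicate"]: m.replicate_index,
            col["accession"]: m.accession,
            col["peptide"]: m.peptide_sequence,
            col["cys_positions"]: dialect.cys_separator.join(
                str(p) for p in m.peptide_cys_positions
            ),
            col["confidence"]: m.confidence_pct,
            col["h_to_l"]: m.h_to_l,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=[col[c] for c in LOGICAL_COLUMNS])


# ---------------------------------------------------------------------------
# Peptide -> protein site mapping
# ---------------------------------------------------------------------------

def map_peptide_to_protein(
    peptide_sequence: str,
    peptide_cys_positions: Sequence[int],
    protein: ProteinRecord,
) -> SiteMapping:
    """Map peptide-relative cysteine indices onto protein coordinates.

    Every exact occurrence of the peptide in the protein contributes sites;
    a peptide occurring more than once is retained and flagged ambiguous
    rather than dropped (silent dropping would bias site counts).
    """
    if not peptide_sequence:
        raise ValueError("peptide_sequence must be nonempty")
    starts: list[int] = []
    start = protein.sequence.find(peptide_sequence)
    while start != -1:
        starts.append(start)  # 0-based
        start = protein.sequence.find(peptide_sequence, start + 1)
    if not starts:
        raise UnmappedPeptideError(protein.accession, peptide_sequence)
    sites = tuple(
        SiteKey(protein.accession, s + i)  # (s+1) - 1 + i in 1-based terms
        for s in starts
        for i in peptide_cys_positions
    )
    for site in sites:
        if protein.sequence[site.position - 1] != "C":
            raise ValueError(
                f"mapped position {site.position} in {protein.accession} "
                "is not a cysteine"
            )
    return SiteMapping(sites=sites, ambiguous=len(starts) > 1)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

_SORT_PRIORITY = ("accession", "position", "peptide", "cys_positions", "set_id")


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with deterministic row and column order.

    Rows are sorted by accession, then site position, then peptide (whichever
    of those columns exist).  Floats are rendered at 12 significant digits so
    a read round-trips without loss; two runs on identical input are
    byte-identical.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    sort_cols = [c for c in _SORT_PRIORITY if c in results.columns]
    out = results.sort_values(sort_cols, kind="mergesort") if sort_cols else results
    out.to_csv(
        path,
        sep="\t",
        index=False,
        float_format="%.12g",
        lineterminator="\n",
    )


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")
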