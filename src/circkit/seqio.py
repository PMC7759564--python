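"""Sequence / table I/O and the circRNA locus-identifier convention.

Loci are 1-based with both ends inclusive, so the spliced length of a locus
is ``end - start + 1``.  The canonical string form is
``<chrom>:<start>-<end><strand>``; a parser additionally accepts whitespace
between the coordinates and the strand glyph, as both variants occur in
published tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

_CIRC_ID_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s*(?P<strand>[+\-−])$"
)

#: Unicode minus sometimes survives copy/paste from PDFs; normalize it.
_MINUS_GLYPHS = {"-", "−"}


@dataclass(frozen=True, order=True)
class CircLocus:
    """A circRNA locus: chromosome, 1-based inclusive coordinates, strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ParseError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ParseError(
                f"start > end in locus {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}{self.strand}"


def parse_circ_id(text: str) -> CircLocus:
    """Parse a locus identifier like ``chr1:668-844+`` or ``chr1:668-844 +``."""
    m = _CIRC_ID_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed circRNA identifier: {text!r}")
    strand = m.group("strand")
    if strand in _MINUS_GLYPHS:
        strand = "-"
    return CircLocus(
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=strand,
    )


def format_circ_id(locus: CircLocus) -> str:
    """Canonical string form (strand glyph attached, no whitespace)."""
    return str(locus)


def circ_length(locus: CircLocus) -> int:
    """Predicted sequence length in bp of a locus (inclusive coordinates)."""
    return locus.end - locus.start + 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

#: Constant Phred+33 quality used when writing FASTQ ('I' == Q40).
FASTQ_QUALITY = 40


def read_sequences(
    path: str | Path, format: str = "fasta", u_to_t: bool = False
) -> Dict[str, str]:
    """Read FASTA/FASTQ into an ordered ``{name: sequence}`` mapping.

    Sequences are uppercased; with ``u_to_t`` uracil is normalized to thymine.
    """
    if format not in ("fasta", "fastq"):
        raise ParseError(f"unsupported sequence format: {format!r}")
    out: Dict[str, str] = {}
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            seq = str(rec.seq).upper()
            if u_to_t:
                seq = seq.replace("U", "T")
            out[rec.id] = seq
    except ValueError as exc:  # Biopython signals truncated/inconsistent records
        raise ParseError(f"error parsing {path} (record {len(out)}): {exc}") from exc
    return out


def write_sequences(
    path: str | Path, sequences: Mapping[str, str], format: str = "fasta"
) -> None:
    """Write ``{name: sequence}`` to FASTA or FASTQ (constant quality)."""
    if format not in ("fasta", "fastq"):
        raise ParseError(f"unsupported sequence format: {format!r}")
    records = []
    for name, seq in sequences.items():
        rec = SeqRecord(Seq(seq), id=name, description="")
        if format == "fastq":
            rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(seq)
        records.append(rec)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, format)


# ---------------------------------------------------------------------------
# circRNA table / BED
# ---------------------------------------------------------------------------

CIRC_TABLE_COLUMNS = ("circ_id", "bsj_reads", "length", "name", "norm_expr")


def write_circ_table(path: str | Path, records: Iterable) -> None:
    """Write CircRNARecord-like objects as a TSV with a fixed column schema."""
    with open(path, "w") as handle:
        handle.write("\t".join(CIRC_TABLE_COLUMNS) + "\n")
        for rec in records:
            norm = "" if rec.norm_expr is None else f"{rec.norm_expr:.6f}"
            handle.write(
                f"{format_circ_id(rec.locus)}\t{rec.bsj_reads}\t{rec.length}\t"
                f"{rec.name}\t{norm}\n"
            )


def read_circ_table(path: str | Path):
    """Read a circRNA TSV back into a pandas DataFrame (circ_id parsed lazily)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "name": str})
    missing = set(CIRC_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"circRNA table {path} missing columns: {sorted(missing)}")
    return df


def write_bed6(path: str | Path, records: Iterable) -> None:
    """BED6 export; the 0-based half-open conversion happens here and only here."""
    with open(path, "w") as handle:
        for rec in records:
            loc = rec.locus
            handle.write(
                f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{rec.name}\t"
                f"{rec.bsj_reads}\t{loc.strand}\n"
            )
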