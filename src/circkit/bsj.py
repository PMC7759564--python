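"""Back-splice junction detection.

Reads that fail to place full-length on the reference are split into two
20-nt terminal anchors.  When both anchors place on the same chromosome and
strand with the read-3'-end anchor *upstream* of the read-5'-end anchor
(coordinates A1-A2 and A3-A4 respectively), the geometry is the signature of
a back-splice.  The two anchor placements are then extended toward each other
over every admissible split of the read; a split is accepted only when the
reconstructed locus carries the canonical splice signal (AG upstream of the
acceptor, GT downstream of the donor; AC/CT on the reverse strand) and the
total mismatch count stays within budget.  Junction support is counted per
distinct read, filtered at a minimum read count, normalized to junction reads
per million mapped and log2-transformed, and each call is named
``{bsj_reads}-{length}``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .alignment import AlignmentHit, ReferenceIndex, align_anchor, align_full_read, build_index, revcomp
from .config import PipelineConfig
from .seqio import CircLocus, circ_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorGeometry:
    """Reference placements of the two anchors of one candidate read.

    A1/A2 are start/stop of the read-3'-end anchor, A3/A4 of the read-5'-end
    anchor; a back-splice requires A1 <= A2 < A3 <= A4 on one chrom/strand.
    """

    read_id: str
    chrom: str
    strand: str
    a1: int
    a2: int
    a3: int
    a4: int

    def __post_init__(self) -> None:
        if not (self.a1 <= self.a2 < self.a3 <= self.a4):
            raise ValueError(
                f"invalid anchor geometry A1..A4 = "
                f"{self.a1},{self.a2},{self.a3},{self.a4}"
            )


@dataclass
class BsjCandidate:
    """One validated candidate junction with its supporting reads."""

    locus: CircLocus
    supporting_read_ids: Set[str] = field(default_factory=set)
    splice_signal: str = ""


@dataclass(frozen=True)
class CircRNARecord:
    """A called circRNA: locus, junction support, normalized expression, name."""

    locus: CircLocus
    bsj_reads: int
    length: int
    name: str
    norm_expr: Optional[float]

    @classmethod
    def from_support(
        cls, locus: CircLocus, bsj_reads: int, norm_expr: Optional[float]
    ) -> "CircRNARecord":
        length = circ_length(locus)
        return cls(
            locus=locus,
            bsj_reads=bsj_reads,
            length=length,
            name=f"{bsj_reads}-{length}",
            norm_expr=norm_expr,
        )


def extract_anchors(seq: str, anchor_length: int = 20) -> Tuple[str, str]:
    """(5' anchor, 3' anchor): the first and last ``anchor_length`` bases."""
    if len(seq) < 2 * anchor_length:
        raise ValueError(
            f"read of length {len(seq)} too short for two {anchor_length}-nt anchors"
        )
    return seq[:anchor_length], seq[-anchor_length:]


def pair_anchors(
    hits_5p: List[AlignmentHit],
    hits_3p: List[AlignmentHit],
    max_span: int = 100_000,
    read_id: str = "",
    strand: Optional[str] = None,
    require_unique: bool = True,
) -> List[AnchorGeometry]:
    """Back-splice geometries from the placements of a read's two anchors.

    Emits every same-chrom, same-strand pair with the 3' anchor strictly
    upstream (A2 < A3) and overall span A4 - A1 + 1 within ``max_span``.
    With ``require_unique`` (default) only uniquely-placed anchors pair.
    """
    if require_unique and (len(hits_5p) != 1 or len(hits_3p) != 1):
        return []
    geoms: List[AnchorGeometry] = []
    for h3 in hits_3p:
        for h5 in hits_5p:
            if h3.chrom != h5.chrom or h3.strand != h5.strand:
                continue
            if h3.end >= h5.start:  # colinear or overlapping: not a back-splice
                continue
            if h5.end - h3.start + 1 > max_span:
                continue
            geoms.append(
                AnchorGeometry(
                    read_id=read_id,
                    chrom=h3.chrom,
                    strand=strand if strand is not None else h3.strand,
                    a1=h3.start,
                    a2=h3.end,
                    a3=h5.start,
                    a4=h5.end,
                )
            )
    return geoms


def splice_signal_ok(
    genome: Mapping[str, str], chrom: str, s: int, e: int, strand: str
) -> bool:
    """Canonical splice signal at a candidate locus (1-based inclusive s, e).

    '+' strand: AG immediately upstream of ``s`` and GT immediately
    downstream of ``e``; '-' strand the reverse complement (AC ... CT in
    forward-genome letters).  Loci too close to a contig edge fail.
    """
    seq = genome[chrom]
    if s < 3 or e > len(seq) - 2:
        return False
    acceptor = seq[s - 3 : s - 1]
    donor = seq[e : e + 2]
    if strand == "+":
        return acceptor == "AG" and donor == "GT"
    return acceptor == "AC" and donor == "CT"


def extend_to_breakpoint(
    oriented_seq: str,
    geometry: AnchorGeometry,
    genome: Mapping[str, str],
    max_mismatches: int = 2,
    anchor_length: int = 20,
) -> Optional[BsjCandidate]:
    """Resolve the exact breakpoint of a candidate read.

    ``oriented_seq`` is the read in transcript orientation (reverse
    complemented beforehand for '-' geometries).  For each split position p
    the left part extends the 5' anchor rightward (ending at e = A3 + p - 1)
    and the right part extends the 3' anchor leftward (starting at
    s = A2 - (L - p) + 1); the first (smallest) p whose total mismatch count
    is within budget and whose locus passes :func:`splice_signal_ok` wins.
    """
    seq = oriented_seq.upper()
    L = len(seq)
    chrom_seq = genome[geometry.chrom]
    for p in range(anchor_length, L - anchor_length + 1):
        e = geometry.a3 + p - 1
        s = geometry.a2 - (L - p) + 1
        if s < 1 or e > len(chrom_seq):
            continue
        mm = _mismatches(seq[:p], chrom_seq[geometry.a3 - 1 : e])
        if mm > max_mismatches:
            continue
        mm += _mismatches(seq[p:], chrom_seq[s - 1 : geometry.a2])
        if mm > max_mismatches:
            continue
        if not splice_signal_ok(genome, geometry.chrom, s, e, geometry.strand):
            continue
        locus = CircLocus(geometry.chrom, s, e, geometry.strand)
        signal = chrom_seq[s - 3 : s - 1] + chrom_seq[e : e + 2]
        cand = BsjCandidate(locus=locus, splice_signal=signal)
        cand.supporting_read_ids.add(geometry.read_id)
        return cand
    return None


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        return len(a) + len(b)  # length disagreement can never align
    return sum(1 for x, y in zip(a, b) if x != y)


def detect_read_bsj(
    index: ReferenceIndex,
    genome: Mapping[str, str],
    read_id: str,
    seq: str,
    config: PipelineConfig,
) -> Optional[BsjCandidate]:
    """Run anchor extraction, pairing, and breakpoint extension on one read.

    The '+' orientation is tried first, then the reverse complement; the
    first validated candidate is returned.
    """
    seq = seq.upper()
    if len(seq) < 2 * config.anchor_length:
        return None
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        a5, a3 = extract_anchors(oriented, config.anchor_length)
        hits5 = [
            h
            for h in align_anchor(index, f"{read_id}/a5", a5, config.max_mismatches_anchor)
            if h.strand == "+"
        ]
        hits3 = [
            h
            for h in align_anchor(index, f"{read_id}/a3", a3, config.max_mismatches_anchor)
            if h.strand == "+"
        ]
        geoms = pair_anchors(
            hits5,
            hits3,
            max_span=config.max_span,
            read_id=read_id,
            strand=strand,
            require_unique=config.unique_anchors,
        )
        for geom in geoms:
            cand = extend_to_breakpoint(
                oriented,
                geom,
                genome,
                max_mismatches=config.max_mismatches_extend,
                anchor_length=config.anchor_length,
            )
            if cand is not None:
                return cand
    return None


def call_circrnas(
    reads: Iterable[Tuple[str, str]],
    genome: Mapping[str, str],
    config: Optional[PipelineConfig] = None,
) -> List[CircRNARecord]:
    """Full caller: partition reads, detect junctions, filter, normalize, name.

    ``reads`` is an iterable of ``(read_id, sequence)``.  Reads that place
    full-length within ``max_mismatches_linear`` count as mapped; the rest
    are fed to the anchor pipeline.  Candidates are aggregated by locus,
    support below ``min_reads`` is dropped, and expression is
    ``log2(bsj_reads / total_mapped * 1e6)`` where ``total_mapped`` is the
    number of linearly placed reads plus all junction reads.
    """
    config = config or PipelineConfig()
    genome = {name: seq.upper() for name, seq in genome.items()}
    index = build_index(genome, k=config.index_k)

    n_mapped = 0
    n_unmapped = 0
    candidates: Dict[CircLocus, BsjCandidate] = {}
    junction_reads: Set[str] = set()
    for read_id, seq in reads:
        hit = align_full_read(index, read_id, seq, config.max_mismatches_linear)
        if hit is not None:
            n_mapped += 1
            continue
        n_unmapped += 1
        cand = detect_read_bsj(index, genome, read_id, seq, config)
        if cand is None:
            continue
        support_id = _support_id(read_id, config.dedupe_fragments)
        existing = candidates.get(cand.locus)
        if existing is None:
            cand.supporting_read_ids = {support_id}
            candidates[cand.locus] = cand
        else:
            existing.supporting_read_ids.add(support_id)
        junction_reads.add(read_id)

    total_mapped = n_mapped + len(junction_reads)
    logger.info(
        "caller: %d mapped, %d unmapped, %d junction reads, %d candidate loci",
        n_mapped,
        n_unmapped,
        len(junction_reads),
        len(candidates),
    )

    records: List[CircRNARecord] = []
    for locus in sorted(candidates, key=lambda l: (l.chrom, l.start, l.end, l.strand)):
        support = len(candidates[locus].supporting_read_ids)
        if support < config.min_reads:
            continue
        if total_mapped > 0:
            norm = math.log2(support / total_mapped * 1e6)
        else:
            norm = None
            logger.warning("zero mapped reads: norm_expr left unset")
        records.append(CircRNARecord.from_support(locus, support, norm))
    return records


def _support_id(read_id: str, dedupe_fragments: bool) -> str:
    """Support is per read by default; optionally collapse /1 and /2 mates."""
    if dedupe_fragments and (read_id.endswith("/1") or read_id.endswith("/2")):
        return read_id[:-2]
    return read_id
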