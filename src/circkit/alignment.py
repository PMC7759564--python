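"""Exact/ungapped short-sequence alignment against a small reference.

A k-mer hash index over the forward genome provides seed candidates; reverse
strand queries are handled by reverse-complementing the query, never the
genome.  Full-read placement allows a small number of substitutions and is
made exhaustive by pigeonhole seeding (``m`` mismatches cannot hit all of
``m + 1`` disjoint seeds).  Anchor placement is exact by default; when anchor
mismatches are enabled a vectorized full scan guarantees completeness.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Deterministic ordering of strands for tie-breaking: '+' before '-'.
_STRAND_RANK = {"+": 0, "-": 1}


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet, N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement of a query (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    query_id: str
    query_span: Tuple[int, int]


class ReferenceIndex:
    """k-mer position index over the forward strand of a genome."""

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if k < 8:
            raise ConfigurationError(f"index k-mer size must be >= 8, got {k}")
        if not genome:
            raise ConfigurationError("cannot index an empty genome")
        self.k = k
        self.genome: Dict[str, str] = {name: seq.upper() for name, seq in genome.items()}
        self.chrom_rank = {name: i for i, name in enumerate(sorted(self.genome))}
        self._kmers: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for name in sorted(self.genome):
            seq = self.genome[name]
            for pos in range(len(seq) - k + 1):
                self._kmers[seq[pos : pos + k]].append((name, pos))
        self._arrays: Dict[str, np.ndarray] = {}

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        """All 0-based forward-strand positions of ``kmer``."""
        return self._kmers.get(kmer, [])

    def array(self, chrom: str) -> np.ndarray:
        """uint8 view of a chromosome, cached for vectorized scans."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.genome[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]


def build_index(genome: Mapping[str, str], k: int = 12) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` with k-mer size ``k`` (k >= 8)."""
    return ReferenceIndex(genome, k=k)


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with early exit once ``limit`` is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _hit_sort_key(index: ReferenceIndex, hit: AlignmentHit):
    return (
        hit.mismatches,
        index.chrom_rank[hit.chrom],
        hit.start,
        _STRAND_RANK[hit.strand],
    )


def _seed_candidates(
    index: ReferenceIndex, query: str, max_mismatches: int
) -> set[Tuple[str, int]]:
    """Candidate 0-based placements of ``query`` via pigeonhole seeding."""
    k = index.k
    L = len(query)
    n_seeds = max_mismatches + 1
    if L >= n_seeds * k:
        offsets = [i * k for i in range(n_seeds)]
    else:
        # Not enough room for disjoint seeds: slide a seed across every
        # offset; complete whenever some length-k window is mismatch free.
        offsets = list(range(0, L - k + 1))
    candidates: set[Tuple[str, int]] = set()
    for off in offsets:
        for chrom, pos in index.lookup(query[off : off + k]):
            start = pos - off
            if start >= 0 and start + L <= len(index.genome[chrom]):
                candidates.add((chrom, start))
    return candidates


def align_full_read(
    index: ReferenceIndex,
    query_id: str,
    seq: str,
    max_mismatches: int = 2,
) -> Optional[AlignmentHit]:
    """Best full-length ungapped placement of a read, or ``None``.

    Ties broken by (fewest mismatches, lowest chromosome id, lowest start,
    '+' before '-') so runs are bit-identical.
    """
    seq = seq.upper()
    L = len(seq)
    if L < index.k:
        return None
    hits: List[AlignmentHit] = []
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        for chrom, start in _seed_candidates(index, query, max_mismatches):
            ref = index.genome[chrom][start : start + L]
            mm = _hamming(query, ref, max_mismatches)
            if mm <= max_mismatches:
                hits.append(
                    AlignmentHit(
                        chrom=chrom,
                        start=start + 1,
                        end=start + L,
                        strand=strand,
                        mismatches=mm,
                        query_id=query_id,
                        query_span=(1, L),
                    )
                )
    if not hits:
        return None
    return min(hits, key=lambda h: _hit_sort_key(index, h))


def _scan_all(
    index: ReferenceIndex, query: str, max_mismatches: int
) -> List[Tuple[str, int, int]]:
    """All 0-based placements (chrom, start, mismatches) via vectorized scan."""
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    L = len(query)
    out = []
    for chrom in sorted(index.genome):
        arr = index.array(chrom)
        if len(arr) < L:
            continue
        windows = sliding_window_view(arr, L)
        mm = (windows != q).sum(axis=1)
        for start in np.nonzero(mm <= max_mismatches)[0]:
            out.append((chrom, int(start), int(mm[start])))
    return out


def align_anchor(
    index: ReferenceIndex,
    query_id: str,
    anchor: str,
    max_mismatches: int = 0,
) -> List[AlignmentHit]:
    """All placements of an anchor with at most ``max_mismatches`` substitutions.

    The anchor is unique when exactly one hit is returned.  Results are sorted
    deterministically (chrom, start, strand).
    """
    anchor = anchor.upper()
    L = len(anchor)
    if L < index.k:
        raise ConfigurationError(
            f"anchor length {L} shorter than index k-mer size {index.k}"
        )
    if max_mismatches > 2:
        raise ConfigurationError("anchor mismatches limited to 0-2")
    hits: List[AlignmentHit] = []
    for strand in ("+", "-"):
        query = anchor if strand == "+" else revcomp(anchor)
        if max_mismatches == 0:
            placements = [
                (chrom, start, 0)
                for chrom, start in _seed_candidates(index, query, 0)
                if index.genome[chrom][start : start + L] == query
            ]
        else:
            placements = _scan_all(index, query, max_mismatches)
        for chrom, start, mm in placements:
            hits.append(
                AlignmentHit(
                    chrom=chrom,
                    start=start + 1,
                    end=start + L,
                    strand=strand,
                    mismatches=mm,
                    query_id=query_id,
                    query_span=(1, L),
                )
            )
    hits.sort(key=lambda h: (index.chrom_rank[h.chrom], h.start, _STRAND_RANK[h.strand]))
    return hits
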