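"""Synthetic genomes, transcripts, reads, miRNAs, and luciferase plates.

Every generator is a pure function of its seed, so downstream stages are
testable without downloads.  Planted circular transcripts receive canonical
splice flanks (AG upstream / GT downstream on '+', AC/CT on '-'), circular
reads are drawn from the doubled transcript sequence truncated to one full
rotation, RNase R treatment rescales linear abundance by a survival fraction,
and simulated miRNAs are reverse complements of sites inside their designated
targets (guaranteeing a seed match of class 7mer-m8 or better).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .alignment import revcomp
from .errors import ConfigurationError, PlacementError
from .luciferase import LuciferasePlate

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int
    chromosome_lengths: Tuple[int, ...]
    gc_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosome_lengths", tuple(self.chromosome_lengths)
        )
        if self.n_chromosomes < 1:
            raise ConfigurationError("need at least one chromosome")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigurationError(
                "chromosome_lengths must have n_chromosomes entries"
            )
        if any(L < 1000 for L in self.chromosome_lengths):
            raise ConfigurationError("every chromosome must be >= 1000 bp")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTranscript:
    id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    kind: str  # "linear" or "circular"
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError("transcript start must be <= end")
        if self.kind not in ("linear", "circular"):
            raise ConfigurationError(f"unknown transcript kind {self.kind!r}")
        if self.abundance <= 0:
            raise ConfigurationError("abundance must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 150
    coverage: float = 10.0
    error_rate: float = 0.0
    paired: bool = False
    rnase_r: bool = False
    linear_survival: float = 1.0
    fragment_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ConfigurationError("read_length must be positive")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must lie in [0, 1)")
        if not 0.0 <= self.linear_survival <= 1.0:
            raise ConfigurationError("linear_survival must lie in [0, 1]")


def generate_genome(spec: GenomeSpec) -> Dict[str, str]:
    """i.i.d. chromosomes at the requested GC fraction, named chr1..chrN."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome: Dict[str, str] = {}
    for i, length in enumerate(spec.chromosome_lengths, start=1):
        draw = rng.choice(_BASES, size=length, p=probs)
        genome[f"chr{i}"] = draw.tobytes().decode("ascii")
    return genome


def transcript_sequence(genome: Mapping[str, str], t: PlantedTranscript) -> str:
    """Transcript sequence in its own 5'->3' orientation."""
    seq = genome[t.chrom][t.start - 1 : t.end]
    return revcomp(seq) if t.strand == "-" else seq


_FLANKS = {"+": ("AG", "GT"), "-": ("AC", "CT")}

#: flank margin in bp required on each side of a planted circle
_MARGIN = 2


def plant_circrnas(
    genome: Mapping[str, str],
    n: int,
    length_range: Tuple[int, int],
    strand_mix: float = 0.5,
    seed: int = 0,
    max_retries: int = 200,
) -> Tuple[Dict[str, str], List[PlantedTranscript]]:
    """Plant ``n`` non-overlapping circular transcripts with splice flanks.

    Returns an edited copy of the genome plus the ground-truth transcripts.
    ``strand_mix`` is the probability of the '+' strand.  Placement failure
    after bounded retries raises :class:`PlacementError`.
    """
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ConfigurationError(f"bad length_range {length_range}")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    arrays = {c: bytearray(genome[c].encode("ascii")) for c in chroms}
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    transcripts: List[PlantedTranscript] = []
    for i in range(n):
        placed = False
        for _ in range(max_retries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(lo, hi + 1))
            chrom_len = len(arrays[chrom])
            if chrom_len < length + 2 * _MARGIN:
                continue
            start = int(rng.integers(_MARGIN + 1, chrom_len - length - _MARGIN + 2))
            end = start + length - 1
            span = (start - _MARGIN, end + _MARGIN)
            if any(a <= span[1] and span[0] <= b for a, b in occupied[chrom]):
                continue
            strand = "+" if rng.random() < strand_mix else "-"
            acceptor, donor = _FLANKS[strand]
            arrays[chrom][start - 3 : start - 1] = acceptor.encode("ascii")
            arrays[chrom][end : end + 2] = donor.encode("ascii")
            occupied[chrom].append(span)
            transcripts.append(
                PlantedTranscript(
                    id=f"circ_{i + 1}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    kind="circular",
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place circRNA {i + 1}/{n} after {max_retries} tries"
            )
    edited = {c: arrays[c].decode("ascii") for c in chroms}
    return edited, transcripts


def plant_linear(
    genome: Mapping[str, str],
    n: int,
    length_range: Tuple[int, int],
    seed: int = 0,
    avoid: Optional[List[PlantedTranscript]] = None,
    max_retries: int = 200,
) -> List[PlantedTranscript]:
    """Pick ``n`` linear transcript loci (no genome edits), avoiding ``avoid``."""
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for t in avoid or []:
        occupied.setdefault(t.chrom, []).append((t.start - _MARGIN, t.end + _MARGIN))
    transcripts: List[PlantedTranscript] = []
    for i in range(n):
        placed = False
        for _ in range(max_retries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(lo, hi + 1))
            chrom_len = len(genome[chrom])
            if chrom_len < length:
                continue
            start = int(rng.integers(1, chrom_len - length + 2))
            end = start + length - 1
            if any(a <= end and start <= b for a, b in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            occupied[chrom].append((start, end))
            transcripts.append(
                PlantedTranscript(
                    id=f"lin_{i + 1}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    kind="linear",
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place linear transcript {i + 1}/{n}")
    return transcripts


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    genome: Mapping[str, str],
    transcripts: List[PlantedTranscript],
    config: ReadSimConfig,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """FASTQ-ready reads plus a ground-truth table.

    Circular transcripts are sampled from one full rotation of the doubled
    sequence so a read may span the back-splice junction; linear transcripts
    yield only colinear reads.  With ``rnase_r`` linear abundance is
    multiplied by ``linear_survival`` before sampling.  Truth rows:
    (read_id, source_id, kind, spans_junction).
    """
    rl = config.read_length
    for t in transcripts:
        if rl > t.length:
            raise ConfigurationError(
                f"read_length {rl} exceeds transcript {t.id} length {t.length}"
            )
    rng = np.random.default_rng(config.seed)
    reads: Dict[str, str] = {}
    truth_rows: List[Dict[str, object]] = []

    def emit(read_id: str, seq: str, source: PlantedTranscript, spans: bool) -> None:
        reads[read_id] = _apply_errors(seq, config.error_rate, rng)
        truth_rows.append(
            {
                "read_id": read_id,
                "source_id": source.id,
                "kind": source.kind,
                "spans_junction": spans,
            }
        )

    for t in transcripts:
        seq = transcript_sequence(genome, t)
        L = t.length
        scale = t.abundance
        if t.kind == "linear" and config.rnase_r:
            scale *= config.linear_survival
        n_reads = int(round(config.coverage * L / rl * scale))
        if n_reads == 0:
            continue
        if config.paired:
            flen = config.fragment_length or min(2 * rl, L)
            flen = max(rl, min(flen, L))
            n_frag = math.ceil(n_reads / 2)
            for i in range(n_frag):
                if t.kind == "circular":
                    start = int(rng.integers(0, L))
                    frag = (seq + seq)[start : start + flen]
                    j = L - start  # fragment offset where the junction falls
                else:
                    start = int(rng.integers(0, L - flen + 1))
                    frag = seq[start : start + flen]
                    j = -1
                mate1 = frag[:rl]
                mate2 = revcomp(frag[-rl:])
                spans1 = t.kind == "circular" and 0 < j < rl
                spans2 = t.kind == "circular" and flen - rl < j < flen
                emit(f"{t.id}_r{i + 1}/1", mate1, t, spans1)
                emit(f"{t.id}_r{i + 1}/2", mate2, t, spans2)
        else:
            for i in range(n_reads):
                if t.kind == "circular":
                    start = int(rng.integers(0, L))
                    read = (seq + seq)[start : start + rl]
                    spans = start + rl > L
                else:
                    start = int(rng.integers(0, L - rl + 1))
                    read = seq[start : start + rl]
                    spans = False
                emit(f"{t.id}_r{i + 1}", read, t, spans)

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source_id", "kind", "spans_junction"]
    )
    assert len(truth) == len(reads)  # conservation: one truth row per read
    return reads, truth


def simulate_mirnas(
    targets: Mapping[str, str],
    n: int,
    seed: int = 0,
    length_range: Tuple[int, int] = (21, 23),
) -> Dict[str, str]:
    """miRNAs (RNA alphabet) fully complementary to sites in their targets.

    Each miRNA is the reverse complement of a randomly placed site inside a
    designated target (targets are cycled in sorted order), so positions 2-8
    are guaranteed to seed-match that target.  Targets shorter than the site
    are skipped with a warning.
    """
    if n > 0 and not targets:
        raise ConfigurationError("need at least one target sequence")
    rng = np.random.default_rng(seed)
    names = sorted(targets)
    mirnas: Dict[str, str] = {}
    for i in range(n):
        target_id = names[i % len(names)]
        target = targets[target_id].upper().replace("U", "T")
        mlen = int(rng.integers(length_range[0], length_range[1] + 1))
        if len(target) < mlen:
            logger.warning(
                "target %s shorter than miRNA site (%d < %d); skipping",
                target_id, len(target), mlen,
            )
            continue
        pos = int(rng.integers(0, len(target) - mlen + 1))
        site = target[pos : pos + mlen]
        mirnas[f"mir_{i + 1}_{target_id}"] = revcomp(site).replace("T", "U")
    return mirnas


def simulate_utr(
    mirnas: Mapping[str, str],
    length: int = 1000,
    seed: int = 0,
    name: str = "utr_1",
) -> Dict[str, str]:
    """A random 3'UTR with one perfectly complementary site per miRNA."""
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    seq = list(arr)
    slot = 10
    for mid in sorted(mirnas):
        site = revcomp(mirnas[mid].upper().replace("U", "T"))
        if slot + len(site) > length:
            raise ConfigurationError("UTR too short for all planted sites")
        seq[slot : slot + len(site)] = site
        slot += len(site) + 15
    return {name: "".join(seq)}


def simulate_luciferase_plate(
    effect: float,
    cv: float,
    n_replicates: int = 3,
    seed: int = 0,
    base_renilla: float = 1000.0,
) -> LuciferasePlate:
    """Plate with control F/R centered at 1.0 and experimental at ``effect``.

    Multiplicative lognormal noise with coefficient of variation ``cv``;
    deterministic given the seed.
    """
    if not 0.0 < effect <= 1.0:
        raise ConfigurationError("effect must lie in (0, 1]")
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates")
    if cv < 0:
        raise ConfigurationError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    def noisy(center: float) -> float:
        if sigma == 0.0:
            return center
        return center * math.exp(rng.normal(-sigma * sigma / 2.0, sigma))

    control = [(noisy(1.0) * base_renilla, base_renilla) for _ in range(n_replicates)]
    experimental = [
        (noisy(effect) * base_renilla, base_renilla) for _ in range(n_replicates)
    ]
    return LuciferasePlate(control_wells=control, experimental_wells=experimental)


def write_truth_table(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_transcript_table(path, transcripts: List[PlantedTranscript]) -> None:
    with open(path, "w") as handle:
        handle.write("id\tchrom\tstart\tend\tstrand\tkind\tabundance\n")
        for t in transcripts:
            handle.write(
                f"{t.id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t{t.kind}\t"
                f"{t.abundance}\n"
            )
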