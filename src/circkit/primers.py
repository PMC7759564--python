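"""Divergent/convergent validation-primer template design.

The divergent template is the circRNA sequence rotated at its midpoint so
that the back-splice junction lies mid-template; primers flanking that point
amplify only across the junction.  Convergent primers are picked on the
unrotated sequence, so their amplicon never contains the junction and also
amplifies from the linear precursor.  The picker itself is deliberately
simple: length 18-27 nt, GC 40-60%, Wallace-rule melting temperatures within
3 degrees of each other, deterministic search order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

from .alignment import revcomp
from .errors import DesignError


@dataclass(frozen=True)
class PrimerParams:
    min_len: int = 18
    max_len: int = 27
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_tm_diff: float = 3.0
    #: how far from the anchor point candidate start positions are explored
    search_window: int = 80


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    pair_kind: str  # "divergent" or "convergent"
    expected_product_bp: int
    spans_junction: bool
    #: 1-based start of the forward primer on its design template
    forward_start: int = 0


def rotate_template(circ_seq: str) -> str:
    """Midpoint rotation: with h = floor(L/2), tail half + head half.

    The back-splice junction of the circle then sits between template
    positions L - h and L - h + 1 (1-based).
    """
    if len(circ_seq) < 2:
        raise DesignError("cannot rotate a sequence shorter than 2 nt")
    h = len(circ_seq) // 2
    return circ_seq[h:] + circ_seq[:h]


def junction_position(circ_len: int) -> int:
    """1-based template position immediately left of the rotated junction."""
    return circ_len - circ_len // 2


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C)."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def _gc_fraction(seq: str) -> float:
    return sum(seq.count(b) for b in "GC") / len(seq)


def _candidates(
    template: str,
    starts: Iterable[int],
    params: PrimerParams,
) -> List[Tuple[int, int]]:
    """(start0, length) windows passing the GC filter, in search order."""
    out = []
    for start in starts:
        for length in range(params.min_len, params.max_len + 1):
            if start < 0 or start + length > len(template):
                continue
            if params.gc_min <= _gc_fraction(template[start : start + length]) <= params.gc_max:
                out.append((start, length))
    return out


def _pick_pair(
    template: str,
    fwd_starts: Iterable[int],
    rev_starts: Iterable[int],
    params: PrimerParams,
    fwd_max_end: Optional[int] = None,
    rev_min_start: Optional[int] = None,
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """First (forward, reverse) window pair with compatible Tm."""
    fwd = _candidates(template, fwd_starts, params)
    rev = _candidates(template, rev_starts, params)
    for fs, fl in fwd:
        if fwd_max_end is not None and fs + fl - 1 > fwd_max_end:
            continue
        tm_f = wallace_tm(template[fs : fs + fl])
        for rs, rl in rev:
            if rev_min_start is not None and rs < rev_min_start:
                continue
            if rs < fs + fl:  # primers must not overlap
                continue
            tm_r = wallace_tm(template[rs : rs + rl])
            if abs(tm_f - tm_r) <= params.max_tm_diff:
                return (fs, fl), (rs, rl)
    raise DesignError("no primer pair satisfies the length/GC/Tm constraints")


def design_divergent(
    circ_seq: str, params: Optional[PrimerParams] = None
) -> PrimerPair:
    """Primer pair on the rotated template whose amplicon spans the junction."""
    params = params or PrimerParams()
    circ_seq = circ_seq.upper()
    L = len(circ_seq)
    if L < 2 * params.min_len + 4:
        raise DesignError(f"circRNA of {L} bp too short for divergent design")
    template = rotate_template(circ_seq)
    jz = junction_position(L)  # junction is between jz and jz+1 (1-based)
    # forward primer must end at or before the junction, reverse must start
    # after it, so the amplicon always contains the junction point.
    fwd_starts = [jz - params.min_len - back for back in range(params.search_window)]
    rev_starts = [jz + off for off in range(params.search_window)]
    (fs, fl), (rs, rl) = _pick_pair(
        template,
        fwd_starts,
        rev_starts,
        params,
        fwd_max_end=jz - 1,
        rev_min_start=jz,
    )
    forward = template[fs : fs + fl]
    reverse = revcomp(template[rs : rs + rl])
    product = (rs + rl) - fs
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        pair_kind="divergent",
        expected_product_bp=product,
        spans_junction=True,
        forward_start=fs + 1,
    )


def design_convergent(
    circ_seq: str, params: Optional[PrimerParams] = None
) -> PrimerPair:
    """Inward-pointing pair on the unrotated sequence; amplicon excludes the junction."""
    params = params or PrimerParams()
    circ_seq = circ_seq.upper()
    L = len(circ_seq)
    if L < 2 * params.min_len + 4:
        raise DesignError(f"circRNA of {L} bp too short for convergent design")
    fwd_starts = list(range(params.search_window))
    rev_starts = [L - params.min_len - off for off in range(params.search_window)]
    (fs, fl), (rs, rl) = _pick_pair(circ_seq, fwd_starts, rev_starts, params)
    forward = circ_seq[fs : fs + fl]
    reverse = revcomp(circ_seq[rs : rs + rl])
    product = (rs + rl) - fs
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        pair_kind="convergent",
        expected_product_bp=product,
        spans_junction=False,
        forward_start=fs + 1,
    )


def in_silico_pcr(circ_seq: str, pair: PrimerPair) -> Optional[int]:
    """Smallest amplicon of a primer pair on the circular template.

    Searches the doubled circle (one full rotation) for the forward primer
    and, downstream of it, the binding site of the reverse primer; returns
    the product size or None when either primer fails to bind.
    """
    doubled = (circ_seq.upper() + circ_seq.upper())
    rev_site = revcomp(pair.reverse)
    best: Optional[int] = None
    start = doubled.find(pair.forward)
    while start != -1 and start < len(circ_seq):
        pos = doubled.find(rev_site, start + len(pair.forward))
        if pos != -1:
            product = pos + len(rev_site) - start
            if product <= len(circ_seq) and (best is None or product < best):
                best = product
        start = doubled.find(pair.forward, start + 1)
    return best
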