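"""circRNA-miRNA-mRNA sponge network construction.

Target sites are found by Watson-Crick complementarity to the miRNA seed
(positions 2-7 core, with 7mer-m8 / 7mer-A1 / 8mer extensions), scored by a
configurable per-class table on a 0-100 scale, and assigned a hybridization
free energy from the best ungapped antiparallel register under a
nearest-neighbor stacking model (shipped as a data file) with a constant
duplex-initiation penalty.  Edges enter the network only when they clear the
energy and score thresholds, and circRNAs at or above the length cutoff are
excluded before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

from .alignment import revcomp
from .errors import ConfigurationError

SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Default per-class site scores on a 0-100 scale.
DEFAULT_SITE_SCORES: Dict[str, float] = {
    "8mer": 100.0,
    "7mer-m8": 95.0,
    "7mer-A1": 90.0,
    "6mer": 80.0,
}


def _load_stack_table() -> Tuple[Dict[str, float], float]:
    data = json.loads(
        resources.files("circkit.data").joinpath("rna_stack_energies.json").read_text()
    )
    return data["stacks"], float(data["duplex_initiation"])


STACK_ENERGIES, DUPLEX_INITIATION = _load_stack_table()

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _norm(seq: str) -> str:
    """Uppercase and collapse the RNA/DNA alphabets (U -> T) for matching."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site on a target (1-based inclusive coords)."""

    start: int
    end: int
    seed_class: str


@dataclass(frozen=True)
class DuplexHit:
    """A scored miRNA/target interaction site."""

    mirna_id: str
    target_id: str
    target_kind: str  # "circRNA" or "mRNA_3UTR"
    site_start: int
    site_end: int
    seed_class: str
    site_score: float
    mfe: float

    def __post_init__(self) -> None:
        if self.mfe > 0:
            raise ValueError("duplex free energy must be <= 0")
        if not 0 <= self.site_score <= 100:
            raise ValueError("site_score must lie in [0, 100]")


@dataclass(frozen=True)
class NetworkEdge:
    source_id: str
    target_id: str
    edge_kind: str  # "circ-miR" or "miR-mRNA"
    mfe: float
    site_score: float


def find_seed_sites(mirna: str, target: str) -> List[SeedSite]:
    """All seed-complementary sites of ``mirna`` on ``target``.

    The 6mer core is a Watson-Crick match of miRNA positions 2-7; pairing at
    position 8 upgrades to 7mer-m8, an A in the target opposite position 1 to
    7mer-A1, and both together to 8mer.  Overlapping sites are all reported.
    """
    m = _norm(mirna)
    t = _norm(target)
    if len(m) < 8 or len(t) < 8:
        raise ConfigurationError("miRNA and target must both be >= 8 nt")
    core = revcomp(m[1:7])  # complements of positions 2-7, target 5'->3'
    m8 = _DNA_COMPLEMENT.get(m[7], "N")
    sites: List[SeedSite] = []
    for i in range(len(t) - 5):
        if t[i : i + 6] != core:
            continue
        has_m8 = i > 0 and t[i - 1] == m8
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            cls = "8mer"
        elif has_m8:
            cls = "7mer-m8"
        elif has_a1:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        start0 = i - 1 if has_m8 else i
        end0 = i + 6 if has_a1 else i + 5
        sites.append(SeedSite(start=start0 + 1, end=end0 + 1, seed_class=cls))
    return sites


def site_score(
    seed_class: str, score_table: Optional[Mapping[str, float]] = None
) -> float:
    """Per-class site score on a 0-100 scale (configurable mapping)."""
    table = score_table if score_table is not None else DEFAULT_SITE_SCORES
    if seed_class not in table:
        raise ConfigurationError(f"unknown seed class: {seed_class!r}")
    return float(table[seed_class])


def duplex_mfe(mirna: str, target_context: str) -> float:
    """Best ungapped hybridization energy (kcal/mol) over all registers.

    For every antiparallel register of the miRNA along the context, adjacent
    Watson-Crick pairs contribute the nearest-neighbor stack energy keyed by
    the miRNA-strand dinucleotide; unpaired positions contribute nothing.  A
    register with at least one stack pays the duplex-initiation penalty once.
    A duplex with no stacked pairs scores 0 (no hybridization); the result is
    clamped at 0 so it is never positive.
    """
    m = _norm(mirna)
    t = _norm(target_context)
    M, C = len(m), len(t)
    rc_m = revcomp(m)  # colinear matching of rc(miRNA) against the target
    best = 0.0
    for d in range(-(M - 1), C):
        lo = max(0, -d)
        hi = min(M, C - d)
        if hi - lo < 2:
            continue
        match = [rc_m[x] == t[d + x] for x in range(lo, hi)]
        energy = 0.0
        for idx in range(len(match) - 1):
            if match[idx] and match[idx + 1]:
                x = lo + idx
                # pair (x, x+1) in rc coords is miRNA step M-2-x .. M-1-x, 5'->3'
                step = m[M - 2 - x : M - x].replace("T", "U")
                energy += STACK_ENERGIES[step]
        if energy < 0:
            energy += DUPLEX_INITIATION
            best = min(best, energy)
    return min(best, 0.0)


def _site_context(target: str, site: SeedSite, mirna_len: int) -> str:
    """Target window opposite the full miRNA for energy evaluation."""
    # 0-based core start of the 6mer (site.start may include the m8 position)
    end0 = site.end - 1
    start0 = max(0, end0 - mirna_len - 1)
    return target[start0 : min(len(target), end0 + 2)]


def scan_target(
    mirna_id: str,
    mirna: str,
    target_id: str,
    target: str,
    target_kind: str,
    score_table: Optional[Mapping[str, float]] = None,
) -> List[DuplexHit]:
    """All scored interaction sites of one miRNA on one target."""
    hits = []
    for site in find_seed_sites(mirna, target):
        ctx = _site_context(_norm(target), site, len(mirna))
        hits.append(
            DuplexHit(
                mirna_id=mirna_id,
                target_id=target_id,
                target_kind=target_kind,
                site_start=site.start,
                site_end=site.end,
                seed_class=site.seed_class,
                site_score=site_score(site.seed_class, score_table),
                mfe=duplex_mfe(mirna, ctx),
            )
        )
    return hits


def build_network(
    circ_seqs: Mapping[str, str],
    mirnas: Mapping[str, str],
    utr_seqs: Optional[Mapping[str, str]] = None,
    mfe_threshold: float = -20.0,
    score_threshold: float = 90.0,
    circ_max_len: int = 2000,
    score_table: Optional[Mapping[str, float]] = None,
) -> Tuple[List[NetworkEdge], List[Dict[str, str]]]:
    """Threshold-filtered sponge network.

    circRNAs with length >= ``circ_max_len`` are excluded before scoring.  An
    edge is emitted iff ``mfe < mfe_threshold`` (strict) and
    ``site_score >= score_threshold`` (inclusive); multiple sites for one
    (miRNA, target) pair are collapsed keeping the lowest energy.  Returns
    (edges, node table), the node table labelling each node's kind.
    """
    utr_seqs = utr_seqs or {}
    targets: List[Tuple[str, str, str]] = []
    for cid, seq in circ_seqs.items():
        if len(seq) >= circ_max_len:
            continue
        targets.append((cid, seq, "circRNA"))
    for uid, seq in utr_seqs.items():
        targets.append((uid, seq, "mRNA_3UTR"))

    best: Dict[Tuple[str, str], DuplexHit] = {}
    for mid, mseq in mirnas.items():
        for tid, tseq, kind in targets:
            for hit in scan_target(mid, mseq, tid, tseq, kind, score_table):
                if not (hit.mfe < mfe_threshold and hit.site_score >= score_threshold):
                    continue
                key = (mid, tid)
                if key not in best or hit.mfe < best[key].mfe:
                    best[key] = hit

    edges: List[NetworkEdge] = []
    nodes: Dict[str, str] = {}
    for (mid, tid), hit in sorted(best.items()):
        kind = "circ-miR" if hit.target_kind == "circRNA" else "miR-mRNA"
        edges.append(
            NetworkEdge(
                source_id=tid if kind == "circ-miR" else mid,
                target_id=mid if kind == "circ-miR" else tid,
                edge_kind=kind,
                mfe=hit.mfe,
                site_score=hit.site_score,
            )
        )
        nodes[mid] = "miRNA"
        nodes[tid] = hit.target_kind
    node_table = [{"node_id": n, "kind": k} for n, k in sorted(nodes.items())]
    return edges, node_table


def write_network(
    edges: Iterable[NetworkEdge],
    nodes: Iterable[Dict[str, str]],
    out_dir: str | Path,
    graphml: bool = True,
) -> None:
    """Write node/edge TSVs (Cytoscape-importable) and optionally GraphML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = list(edges)
    nodes = list(nodes)
    with open(out_dir / "edges.tsv", "w") as handle:
        handle.write("source\ttarget\tedge_kind\tmfe\tsite_score\n")
        for e in edges:
            handle.write(
                f"{e.source_id}\t{e.target_id}\t{e.edge_kind}\t{e.mfe:.2f}\t"
                f"{e.site_score:.1f}\n"
            )
    with open(out_dir / "nodes.tsv", "w") as handle:
        handle.write("node_id\tkind\n")
        for n in nodes:
            handle.write(f"{n['node_id']}\t{n['kind']}\n")
    if graphml:
        g = nx.Graph()
        for n in nodes:
            g.add_node(n["node_id"], kind=n["kind"])
        for e in edges:
            g.add_edge(
                e.source_id, e.target_id, edge_kind=e.edge_kind, mfe=e.mfe,
                site_score=e.site_score,
            )
        nx.write_graphml(g, out_dir / "network.graphml")
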