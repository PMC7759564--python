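"""Descriptive signature statistics for a circRNA catalog.

Covers sequencing QC ratios, junction-read support categories, per-chromosome
counts and circRNAs-per-Mb densities, and the length histogram.  Percentages
and densities are rounded to two decimals, matching typical report precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .errors import ConfigurationError

#: Support categories, inclusive on both ends; ">100" means >= 101 reads and
#: "<2" means <= 1 read — the only reading that makes the five classes a
#: partition.
BSJ_BINS: Tuple[Tuple[str, int, float], ...] = (
    (">100", 101, float("inf")),
    ("10-100", 10, 100),
    ("4-9", 4, 9),
    ("2-3", 2, 3),
    ("<2", 0, 1),
)

DEFAULT_LENGTH_EDGES = (100, 200, 400, 700, 1000, 2000, 4000, 10000)


@dataclass(frozen=True)
class QcCounts:
    """Library-level read accounting."""

    raw_reads: int
    clean_reads: int
    mapped_reads: int
    n_circ: int = 0

    def __post_init__(self) -> None:
        if min(self.raw_reads, self.clean_reads, self.mapped_reads, self.n_circ) < 0:
            raise ConfigurationError("QC counts must be non-negative")
        if self.clean_reads > self.raw_reads:
            raise ConfigurationError("clean_reads cannot exceed raw_reads")
        if self.mapped_reads > self.clean_reads:
            raise ConfigurationError("mapped_reads cannot exceed clean_reads")


def qc_ratios(qc: QcCounts) -> Dict[str, float]:
    """Clean ratio (clean/raw) and mapping ratio (mapped/clean), in percent."""
    if qc.raw_reads == 0:
        raise ConfigurationError("raw_reads must be > 0 to compute ratios")
    clean_ratio = round(qc.clean_reads / qc.raw_reads * 100, 2)
    mapping_ratio = (
        round(qc.mapped_reads / qc.clean_reads * 100, 2) if qc.clean_reads else 0.0
    )
    return {"clean_ratio": clean_ratio, "mapping_ratio": mapping_ratio}


def _support_counts(records: Iterable) -> List[int]:
    out = []
    for rec in records:
        out.append(rec if isinstance(rec, int) else rec.bsj_reads)
    return out


def bsj_categories(records: Iterable) -> pd.DataFrame:
    """Junction-support categories with counts and percentages.

    ``records`` may be CircRNARecord-like objects or plain read counts.
    Returns a DataFrame with columns category/count/percent, ordered from the
    highest-support class down.
    """
    counts = _support_counts(records)
    total = len(counts)
    rows = []
    for label, lo, hi in BSJ_BINS:
        n = sum(1 for c in counts if lo <= c <= hi)
        pct = round(n / total * 100, 2) if total else 0.0
        rows.append({"category": label, "count": n, "percent": pct})
    df = pd.DataFrame(rows)
    assert df["count"].sum() == total  # the bins are a partition
    return df


def chromosome_density(
    records: Iterable, chrom_sizes_mb: Mapping[str, float]
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-chromosome counts and circRNAs-per-Mb, plus genome-wide ratios.

    Reported both for all records and restricted to records with more than
    four junction reads.  ``chrom_sizes_mb`` maps chromosome name to size in
    megabases.  Unknown chromosomes raise, listing every offender.
    """
    records = list(records)
    unknown = sorted({r.locus.chrom for r in records} - set(chrom_sizes_mb))
    if unknown:
        raise ConfigurationError(f"records on unknown chromosomes: {unknown}")
    rows = []
    for chrom in chrom_sizes_mb:
        size = chrom_sizes_mb[chrom]
        if size <= 0:
            raise ConfigurationError(f"chromosome {chrom} has non-positive size")
        n_total = sum(1 for r in records if r.locus.chrom == chrom)
        n_gt4 = sum(1 for r in records if r.locus.chrom == chrom and r.bsj_reads > 4)
        rows.append(
            {
                "chrom": chrom,
                "size_mb": size,
                "n_circ": n_total,
                "density": round(n_total / size, 2),
                "n_circ_gt4": n_gt4,
                "density_gt4": round(n_gt4 / size, 2),
            }
        )
    df = pd.DataFrame(rows)
    total_mb = float(sum(chrom_sizes_mb.values()))
    summary = {
        "genome_density": round(len(records) / total_mb, 2),
        "genome_density_gt4": round(
            sum(1 for r in records if r.bsj_reads > 4) / total_mb, 2
        ),
    }
    return df, summary


def length_distribution(
    records: Iterable, bin_edges: Sequence[int] = DEFAULT_LENGTH_EDGES
) -> Tuple[pd.DataFrame, float]:
    """Length histogram over half-open bins plus the fraction past the top edge.

    Bins are ``[0, e1), [e1, e2), ..., [e_last, inf)``; the fraction of
    records at or beyond the last edge (default 10,000 bp) is also returned
    separately.
    """
    lengths = [rec if isinstance(rec, int) else rec.length for rec in records]
    edges = [0] + sorted(bin_edges) + [float("inf")]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = sum(1 for L in lengths if lo <= L < hi)
        if hi == float("inf"):
            label = f">={lo}"
        else:
            label = f"{lo}-{int(hi) - 1}"
        rows.append({"bin": label, "count": n})
    df = pd.DataFrame(rows)
    assert df["count"].sum() == len(lengths)
    top = sorted(bin_edges)[-1]
    frac_over = (
        sum(1 for L in lengths if L >= top) / len(lengths) if lengths else 0.0
    )
    return df, frac_over


def plot_length_pie(df: pd.DataFrame, path: str) -> None:
    """Pie chart of the length bins (occupied bins only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    occupied = df[df["count"] > 0]
    fig, ax = plt.subplots()
    ax.pie(occupied["count"], labels=occupied["bin"], autopct="%1.1f%%")
    ax.set_title("circRNA length distribution")
    fig.savefig(path)
    plt.close(fig)


def plot_chromosome_bars(df: pd.DataFrame, path: str) -> None:
    """Bar chart of per-chromosome circRNA counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(df)), 4))
    ax.bar(df["chrom"], df["n_circ"], label="all")
    ax.bar(df["chrom"], df["n_circ_gt4"], label="BSJ reads > 4")
    ax.set_ylabel("circRNAs")
    ax.legend()
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
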