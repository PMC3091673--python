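"""Per-gene census of exact priming sites for a chosen primer.

A priming site is an exact match between a transcript window on the mRNA
sense strand and the reverse complement of the primer (the mRNA-sense
motif).  The census reports, per gene, every site position, plus the
transcriptome-level summary: how many genes carry at least one site, the
mean site count among those genes, and the full site-count histogram.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from .motif import DegenerateMotif, SiteList, count_sites, reverse_complement
from .transcriptome import TranscriptomePartition

__all__ = ["CensusSummary", "CensusResult", "site_census", "bucket_fraction",
           "summarize_counts", "write_sites_tsv", "read_sites_tsv"]


@dataclass(frozen=True)
class CensusSummary:
    """Summary statistics of the per-gene site counts.

    The mean is over genes containing >= 1 site; with no containing genes
    it is NaN.  The histogram maps site count (>= 1) to number of genes.
    """

    n_genes_total: int
    n_genes_with_sites: int
    fraction_with_sites: float
    mean_sites_per_containing_gene: float
    histogram: dict[int, int]
    max_sites: int


@dataclass(frozen=True)
class CensusResult:
    sites: list[SiteList]
    summary: CensusSummary
    rrna_occurrences: int
    trna_occurrences: int


def summarize_counts(counts: list[int]) -> CensusSummary:
    """Build a :class:`CensusSummary` from raw per-gene site counts."""
    containing = [c for c in counts if c > 0]
    hist: dict[int, int] = {}
    for c in containing:
        hist[c] = hist.get(c, 0) + 1
    n = len(counts)
    k = len(containing)
    return CensusSummary(
        n_genes_total=n,
        n_genes_with_sites=k,
        fraction_with_sites=k / n if n else math.nan,
        mean_sites_per_containing_gene=sum(containing) / k if k else math.nan,
        histogram=hist,
        max_sites=max(containing) if containing else 0,
    )


def site_census(
    primer: DegenerateMotif | str, partition: TranscriptomePartition
) -> CensusResult:
    """Census of exact priming sites of ``primer`` across a transcriptome.

    Scans the reverse complement of the primer over each mRNA sense strand;
    also reports total occurrence counts in the rRNA and tRNA sets.
    """
    motif = reverse_complement(primer)
    sites = [count_sites(motif, rec) for rec in partition.mrna]
    summary = summarize_counts([s.count for s in sites])
    rrna_occ = sum(count_sites(motif, rec).count for rec in partition.rrna)
    trna_occ = sum(count_sites(motif, rec).count for rec in partition.trna)
    return CensusResult(sites, summary, rrna_occ, trna_occ)


def bucket_fraction(summary: CensusSummary, lo: int, hi: int) -> float:
    """Fraction of site-containing genes whose count lies in [lo, hi]."""
    if lo > hi:
        raise ValueError(f"lo must be <= hi, got [{lo}, {hi}]")
    if summary.n_genes_with_sites == 0:
        return math.nan
    in_bucket = sum(v for k, v in summary.histogram.items() if lo <= k <= hi)
    return in_bucket / summary.n_genes_with_sites


def write_sites_tsv(sites: list[SiteList], path: str | Path) -> None:
    """TSV columns: gene_id, n_sites, comma-joined 0-based starts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "n_sites", "starts"])
        for s in sites:
            w.writerow([s.transcript_id, s.count, ",".join(map(str, s.positions))])


def read_sites_tsv(path: str | Path) -> list[SiteList]:
    out: list[SiteList] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["gene_id", "n_sites"]:
            raise ValueError(f"{path}: not a sites TSV")
        for row in reader:
            starts = tuple(int(x) for x in row[2].split(",")) if row[2] else ()
            if len(starts) != int(row[1]):
                raise ValueError(f"{path}: n_sites mismatch for {row[0]!r}")
            out.append(SiteList(row[0], starts))
    return out
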