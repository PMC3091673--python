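"""Digital gene expression (DGE) tag analytics.

A tag-profiling run yields short (16-17 nt) cDNA tags.  After adapter
removal each tag is matched exactly against the transcriptome and
classified as a single mRNA / rRNA / tRNA match, a multiple match, or
unmatched; single-mRNA tags are tabulated per gene.  Differential
expression between two samples is tested per gene with a binomial
likelihood-ratio test: the tag proportion p = n/N is estimated by maximum
likelihood (maximizing p^n (1-p)^(N-n)) pooled and per sample, and
-2 log(likelihood ratio) is referred to a chi-square distribution with
one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .transcriptome import TranscriptomePartition

__all__ = [
    "TagRead",
    "TagAssignment",
    "TagCountTable",
    "LrtResult",
    "CATEGORIES",
    "trim_adapter",
    "classify_tag",
    "tabulate",
    "lrt_test",
    "lrt_vector",
    "signed_fold_ratio",
    "differential_expression",
]

CATEGORIES = ("single_mRNA", "single_rRNA", "single_tRNA", "multiple", "unmatched")


@dataclass(frozen=True)
class TagRead:
    """A raw read and the tag remaining after adapter removal."""

    read: str
    tag: str

    def __post_init__(self) -> None:
        if not (1 <= len(self.tag) <= len(self.read)):
            raise ValueError("tag must be a nonempty prefix of the read")
        if not self.read.startswith(self.tag):
            raise ValueError("tag must be the read prefix")


def trim_adapter(
    read: str, adapter: Optional[str] = None, tag_length: int = 17
) -> Optional[TagRead]:
    """Strip the ligated adapter from a raw read.

    With ``adapter`` given, the tag is the read prefix before the first
    exact adapter occurrence (falling back to the first ``tag_length``
    bases if the adapter is absent).  Without an adapter the first
    ``tag_length`` bases are taken.  Returns ``None`` for a discarded
    read (adapter at position 0, i.e. an empty tag).
    """
    if not read:
        raise ValueError("read must be nonempty")
    read = read.upper()
    if adapter is not None:
        pos = read.find(adapter.upper())
        if pos == 0:
            return None
        tag = read[:pos] if pos > 0 else read[:tag_length]
    else:
        tag = read[:tag_length]
    return TagRead(read, tag)


@dataclass(frozen=True)
class TagAssignment:
    """A tag's match category, and its gene for single-class matches."""

    tag: str
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        is_single = self.category.startswith("single_")
        if is_single != (self.gene_id is not None):
            raise ValueError("gene_id must be set iff the category is single_*")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def classify_tag(
    tag: str,
    partition: TranscriptomePartition,
    both_strands: bool = False,
) -> TagAssignment:
    """Exact-substring classification of a tag against the transcriptome.

    Tags hitting no transcript are ``unmatched``; tags hitting two or more
    distinct transcripts (of any class) are ``multiple``; a unique hit is
    ``single_<class>`` with the transcript id.  DGE tags are strand
    specific, so only the sense strand is searched unless ``both_strands``.
    """
    tag = tag.upper()
    if not tag or set(tag) - set("ACGT"):
        raise ValueError(f"tag must be nonempty over ACGT, got {tag!r}")
    queries = (tag, _revcomp(tag)) if both_strands else (tag,)
    hits: list = []
    for rec in partition.all_records():
        if any(q in rec.seq for q in queries):
            hits.append(rec)
            if len(hits) > 1:
                return TagAssignment(tag, "multiple")
    if not hits:
        return TagAssignment(tag, "unmatched")
    return TagAssignment(tag, f"single_{hits[0].rna_class}", hits[0].id)


@dataclass
class TagCountTable:
    """Per-gene single-mRNA tag counts for two samples.

    ``counts`` has columns ``n1``/``n2`` indexed by gene id; ``N1``/``N2``
    are the library totals (the single-match mRNA tag totals).
    """

    counts: pd.DataFrame
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if (self.counts[["n1", "n2"]] < 0).to_numpy().any():
            raise ValueError("counts must be nonnegative")


def tabulate(
    assignments1: Iterable[TagAssignment],
    assignments2: Iterable[TagAssignment],
) -> tuple[TagCountTable, pd.DataFrame]:
    """Tabulate per-gene counts and per-category totals for two samples.

    Library totals N1/N2 are the single-match mRNA totals.  The category
    table has one row per category and one column per sample; each column
    sums to that sample's input tag count.
    """
    per_gene: dict[str, list[int]] = {}
    cat_totals = {c: [0, 0] for c in CATEGORIES}
    for col, assignments in enumerate((assignments1, assignments2)):
        for a in assignments:
            cat_totals[a.category][col] += 1
            if a.category == "single_mRNA":
                per_gene.setdefault(a.gene_id, [0, 0])[col] += 1
    counts = pd.DataFrame.from_dict(per_gene, orient="index", columns=["n1", "n2"])
    counts.index.name = "gene_id"
    categories = pd.DataFrame(cat_totals, index=["sample1", "sample2"]).T
    table = TagCountTable(
        counts, int(counts["n1"].sum()) if len(counts) else 0,
        int(counts["n2"].sum()) if len(counts) else 0,
    )
    return table, categories


@dataclass(frozen=True)
class LrtResult:
    """Per-gene binomial LRT: pooled vs per-sample ML tag proportions."""

    gene_id: str
    p_hat: float
    p1_hat: float
    p2_hat: float
    lrt_stat: float
    p_value: float
    signed_ratio: float


def _binom_ll(n: np.ndarray, N: np.ndarray, p: np.ndarray) -> np.ndarray:
    # log[p^n (1-p)^(N-n)] with the 0*log(0) = 0 convention
    return xlogy(n, p) + xlogy(N - n, 1.0 - p)


def lrt_vector(
    n1, N1, n2, N2
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized LRT statistic and chi-square(1) upper-tail p-value."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    if np.any(N1 < 1) or np.any(N2 < 1):
        raise ValueError("library totals must be >= 1")
    if np.any(n1 > N1) or np.any(n2 > N2) or np.any(n1 < 0) or np.any(n2 < 0):
        raise ValueError("counts must satisfy 0 <= n <= N")
    p1 = n1 / N1
    p2 = n2 / N2
    p0 = (n1 + n2) / (N1 + N2)
    stat = 2.0 * (
        _binom_ll(n1, N1, p1) + _binom_ll(n2, N2, p2)
        - _binom_ll(n1, N1, p0) - _binom_ll(n2, N2, p0)
    )
    stat = np.maximum(stat, 0.0)  # guard tiny negative round-off
    return stat, chi2.sf(stat, df=1)


def signed_fold_ratio(n1: int, N1: int, n2: int, N2: int) -> float:
    """Fold ratio q = (n1/N1)/(n2/N2), reported as -1/q when q < 1.

    Down-regulation is thus a negative number whose magnitude is the fold
    change.  Undefined (NaN) when either count is zero; no pseudocounts.
    """
    if n1 == 0 or n2 == 0:
        return math.nan
    q = (n1 / N1) / (n2 / N2)
    return q if q >= 1 else -1.0 / q


def lrt_test(gene_id: str, n1: int, N1: int, n2: int, N2: int) -> LrtResult:
    """Binomial likelihood-ratio test for one gene's tag proportions."""
    stat, p = lrt_vector([n1], [N1], [n2], [N2])
    return LrtResult(
        gene_id=gene_id,
        p_hat=(n1 + n2) / (N1 + N2),
        p1_hat=n1 / N1,
        p2_hat=n2 / N2,
        lrt_stat=float(stat[0]),
        p_value=float(p[0]),
        signed_ratio=signed_fold_ratio(n1, N1, n2, N2),
    )


def differential_expression(
    table: TagCountTable, bh: bool = False
) -> pd.DataFrame:
    """Per-gene LRT results for a two-sample tag-count table.

    Returns columns gene_id, n1, N1, n2, N2, p1, p2, ratio, lrt_stat,
    p_value (raw); with ``bh`` a Benjamini-Hochberg adjusted column
    ``p_adj`` is appended.
    """
    df = table.counts.reset_index()
    n1 = df["n1"].to_numpy()
    n2 = df["n2"].to_numpy()
    stat, pval = lrt_vector(n1, table.N1, n2, table.N2)
    p1 = n1 / table.N1
    p2 = n2 / table.N2
    with np.errstate(divide="ignore", invalid="ignore"):
        q = p1 / p2
        ratio = np.where(q >= 1, q, -1.0 / q)
    ratio = np.where((n1 == 0) | (n2 == 0), np.nan, ratio)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "n1": n1,
            "N1": table.N1,
            "n2": n2,
            "N2": table.N2,
            "p1": p1,
            "p2": p2,
            "ratio": ratio,
            "lrt_stat": stat,
            "p_value": pval,
        }
    )
    if bh:
        out["p_adj"] = multipletests(pval, method="fdr_bh")[1] if len(out) else []
    return out
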