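"""Synthetic data with known ground truth for every analysis in the package.

Three generators:

* :func:`make_transcriptome` — a random-sequence transcriptome with a
  degenerate motif planted at controlled prevalence in the mRNA set and
  (in strict mode) guaranteed absent everywhere else, so the planted
  motif's score components are known exactly.
* :func:`make_tag_counts` — two-condition multinomial tag counts over
  log-normal gene abundances with a known set of differentially
  expressed genes.
* :func:`make_power_table` — per-gene fold changes and significance
  indicators drawn from a logistic model with a known GEL50.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif import DegenerateMotif, IUPAC_SETS, scan_positions
from .tags import TagCountTable
from .transcriptome import TranscriptRecord, TranscriptomePartition

__all__ = [
    "PlantedTruth",
    "make_transcriptome",
    "make_tag_counts",
    "make_power_table",
    "DEFAULT_MOTIF",
]

#: Default planted motif: moderate degeneracy (4) so the planted signal is
#: identifiable against chance matching — a fully degenerate motif like the
#: published yeast one matches so much sequence by composition alone that a
#: planted copy of it carries no recoverable signal.  Its reverse complement
#: (the primer) ends in G,C, so the 3'-GC selection rule is exercised too.
DEFAULT_MOTIF = "GCWTACGRTAGC"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted-motif transcriptome."""

    motif: DegenerateMotif
    planted_gene_ids: frozenset[str]
    prevalence: float
    strict: bool


def _draw_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _expand(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    """A uniformly drawn concrete expansion of the motif."""
    return "".join(
        sorted(IUPAC_SETS[s])[rng.integers(len(IUPAC_SETS[s]))] for s in motif.symbols
    )


def make_transcriptome(
    n_mrna: int = 300,
    n_rrna: int = 5,
    n_trna: int = 10,
    length_range: tuple[int, int] = (500, 500),
    rrna_length_range: tuple[int, int] = (1500, 1800),
    trna_length_range: tuple[int, int] = (70, 90),
    gc: float = 0.40,
    motif: DegenerateMotif | str = DEFAULT_MOTIF,
    prevalence: float = 0.8,
    strict: bool = True,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[TranscriptomePartition, PlantedTruth]:
    """Random transcriptome with a motif planted in a known mRNA subset.

    ``round(prevalence * n_mrna)`` mRNAs each receive one uniformly chosen
    concrete expansion of the motif at a uniform position.  In strict mode
    every sequence is rejection-resampled until its motif occurrence count
    is exactly its planted count (1 or 0), so the planted motif's
    evaluation returns exactly (n_planted, 0, 0, n_mrna).  Sequence bases
    are i.i.d. with the given GC content.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    for rng_name, (lo, hi) in (
        ("mRNA", length_range), ("rRNA", rrna_length_range), ("tRNA", trna_length_range)
    ):
        if lo < len(motif.symbols):
            raise ValueError(f"{rng_name} lengths must be >= motif length")
    rng = np.random.default_rng(seed)
    n_planted = round(prevalence * n_mrna)
    planted_idx = set(rng.choice(n_mrna, size=n_planted, replace=False).tolist())

    def build_seq(length: int, plant: bool) -> str:
        target = 1 if plant else 0
        for _ in range(max_attempts):
            seq = _draw_seq(rng, length, gc)
            if plant:
                pos = int(rng.integers(length - len(motif.symbols) + 1))
                ins = _expand(motif, rng)
                seq = seq[:pos] + ins + seq[pos + len(ins):]
            if not strict:
                return seq
            if scan_positions(motif, seq).size == target:
                return seq
        raise ValueError(
            f"strict mode infeasible: no clean sequence after {max_attempts} "
            "attempts (motif too permissive?)"
        )

    def lengths(n: int, lo: int, hi: int) -> list[int]:
        return [int(rng.integers(lo, hi + 1)) for _ in range(n)]

    mrna = [
        TranscriptRecord(f"gene{i:04d}", build_seq(L, i in planted_idx), "mRNA")
        for i, L in enumerate(lengths(n_mrna, *length_range))
    ]
    rrna = [
        TranscriptRecord(f"rrna{i:02d}", build_seq(L, False), "rRNA")
        for i, L in enumerate(lengths(n_rrna, *rrna_length_range))
    ]
    trna = [
        TranscriptRecord(f"trna{i:02d}", build_seq(L, False), "tRNA")
        for i, L in enumerate(lengths(n_trna, *trna_length_range))
    ]
    truth = PlantedTruth(
        motif=motif,
        planted_gene_ids=frozenset(mrna[i].id for i in planted_idx),
        prevalence=prevalence,
        strict=strict,
    )
    return TranscriptomePartition(mrna, rrna, trna), truth


def make_tag_counts(
    n_genes: int = 2000,
    library_sizes: tuple[int, int] = (100_000, 100_000),
    de_fraction: float = 0.1,
    fold_change: float = 4.0,
    abundance_dispersion: float = 1.0,
    seed: int = 0,
) -> tuple[TagCountTable, pd.DataFrame]:
    """Two-condition multinomial tag counts with a known DE gene set.

    Baseline abundances are log-normal with the given log-scale SD;
    condition-2 abundances of the DE genes are multiplied by
    ``fold_change``; each sample's counts are one multinomial draw with
    the stated library size, so column sums equal the library sizes
    exactly.  Returns the count table and a truth frame (gene_id, is_de,
    baseline abundance).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=0.0, sigma=abundance_dispersion, size=n_genes)
    n_de = round(de_fraction * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    abundance2 = baseline.copy()
    abundance2[is_de] *= fold_change
    N1, N2 = library_sizes
    counts1 = rng.multinomial(N1, baseline / baseline.sum())
    counts2 = rng.multinomial(N2, abundance2 / abundance2.sum())
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    counts = pd.DataFrame({"n1": counts1, "n2": counts2},
                          index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "baseline": baseline}
    )
    return TagCountTable(counts, N1, N2), truth


def make_power_table(
    n_genes: int = 5000,
    beta0: float | None = None,
    beta1: float = 3.0,
    ratio_sd: float = 1.0,
    seed: int = 0,
    n_sites_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene (fold change, significance) rows from a logistic power model.

    log2 ratios are Normal(0, ratio_sd); significance is Bernoulli with
    probability logistic(beta0 + beta1*|log2 ratio|).  The true GEL50 is
    ``2**(-beta0/beta1)``.  ``beta0`` defaults to the value giving a true
    GEL50 of 1.5.  With ``n_sites_range`` an integer covariate column is
    added (uniform, independent of the outcome).
    """
    if beta1 <= 0:
        raise ValueError("beta1 must be > 0")
    if beta0 is None:
        beta0 = -beta1 * math.log2(1.5)
    rng = np.random.default_rng(seed)
    log2r = rng.normal(0.0, ratio_sd, size=n_genes)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * np.abs(log2r))))
    significant = rng.random(n_genes) < prob
    table = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "ratio": 2.0 ** log2r,
            "significant": significant,
        }
    )
    if n_sites_range is not None:
        lo, hi = n_sites_range
        table["n_sites"] = rng.integers(lo, hi + 1, size=n_genes)
    true_gel50 = float(2.0 ** (-beta0 / beta1))
    return table, true_gel50
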