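"""Stochastic search for a multi-targeted primer (MTP).

The goal is a single degenerate 12-mer that occurs in as many mRNAs as
possible while avoiding rRNA and tRNA, so that its reverse complement can
prime reverse transcription of most of the message pool without wasting
reads on structural RNA.  Exhaustive search over the 16^12 degenerate
12-mers is infeasible, so the search is a simulated-annealing-style walk:

* score a candidate motif as ``s = m / (m_t * (1 + t + r))`` where ``m``
  is the number of mRNAs containing the motif, ``t`` and ``r`` are the
  total occurrence counts in tRNA and rRNA, and ``m_t`` is the total
  number of annotated mRNAs;
* mutate one position to a different IUPAC code, re-score, and keep the
  mutant if a uniform draw is below ``(s_new / s_old) ** 10`` (so any
  non-worsening move is always kept);
* record every accepted motif; restart from several random initial
  motifs and rank the merged ledger by score.

The primer finally reported is the reverse complement of a high-ranking
motif whose primer 3' end is strong-binding (G/C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._engine import get_encoded
from .motif import IUPAC_ALPHABET, DegenerateMotif, reverse_complement
from .transcriptome import TranscriptomePartition

__all__ = [
    "ScoreComponents",
    "Candidate",
    "SearchConfig",
    "SearchResult",
    "PrimerChoice",
    "score_fn",
    "evaluate",
    "mutate",
    "accept",
    "acceptance_probability",
    "search",
    "select_primer",
]

logger = logging.getLogger(__name__)

#: The published multi-targeted primers (reverse complements of the
#: mRNA-sense motifs the searches selected).
YEAST_PRIMER = "NDKTBBBBDWGS"  # targets 76% of the 6608 S. cerevisiae mRNAs
NEUROSPORA_PRIMER = "VWNVNNBDKGGC"  # targets 85% of the 9846 N. crassa ORFs


@dataclass(frozen=True)
class ScoreComponents:
    """Hit counts entering the score.

    ``m``: mRNAs containing >= 1 motif occurrence (presence);
    ``t``, ``r``: total occurrences in tRNA / rRNA sequences;
    ``m_t``: total number of annotated mRNAs.
    """

    m: int
    t: int
    r: int
    m_t: int

    def __post_init__(self) -> None:
        if self.m_t < 1:
            raise ValueError("m_t must be >= 1 (score undefined otherwise)")
        if not (0 <= self.m <= self.m_t):
            raise ValueError(f"m must lie in [0, m_t]; got m={self.m}, m_t={self.m_t}")
        if self.t < 0 or self.r < 0:
            raise ValueError("t and r must be nonnegative")


def score_fn(components: ScoreComponents) -> float:
    """``m / (m_t * (1 + t + r))`` — the search objective.

    Rewards mRNA coverage and divides through by one plus the structural-RNA
    occurrence count, so a single rRNA/tRNA hit halves the score of an
    otherwise perfect motif.  With a clean background (t = r = 0) the score
    is simply the fraction of mRNAs hit, hence lies in [0, 1].
    """
    c = components
    return c.m / (c.m_t * (1 + c.t + c.r))


@dataclass(frozen=True)
class Candidate:
    """An accepted motif with its score, components and acceptance iteration."""

    motif: DegenerateMotif
    score: float
    components: ScoreComponents
    iteration: int
    restart: int = 0


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters.

    ``iterations`` defaults to the production value of 2e6 mutations per
    restart; desk-scale runs use far fewer.  ``acceptance_exponent`` is the
    power applied to the score ratio in the acceptance rule.
    """

    motif_length: int = 12
    iterations: int = 2_000_000
    acceptance_exponent: float = 10.0
    restarts: int = 4
    seed: int = 0
    gc_rule_width: int = 2
    mrna_hit_mode: str = "presence"  # or "occurrences"

    def __post_init__(self) -> None:
        if self.motif_length < 1 or self.restarts < 1 or self.iterations < 0:
            raise ValueError("motif_length and restarts must be positive, iterations >= 0")
        if self.acceptance_exponent <= 0:
            raise ValueError("acceptance_exponent must be > 0")
        if self.mrna_hit_mode not in ("presence", "occurrences"):
            raise ValueError("mrna_hit_mode must be 'presence' or 'occurrences'")


@dataclass
class SearchResult:
    """Ranked ledger of all accepted motifs across restarts."""

    ledger: list[Candidate]
    best: Candidate
    trajectory_summary: list[dict]


def evaluate(
    motif: DegenerateMotif | str,
    partition: TranscriptomePartition,
    mrna_hit_mode: str = "presence",
) -> ScoreComponents:
    """Count motif hits in each class of the partition.

    ``m`` counts mRNAs containing the motif at least once ("presence", the
    default) or total mRNA occurrences ("occurrences"); ``t`` and ``r`` are
    always total occurrence counts.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    enc = get_encoded(partition)
    m_presence, m_total = enc.mrna.scan(motif)
    _, t = enc.trna.scan(motif)
    _, r = enc.rrna.scan(motif)
    if mrna_hit_mode == "presence":
        return ScoreComponents(m=m_presence, t=t, r=r, m_t=partition.m_t)
    # occurrence counting can exceed m_t, so bypass the presence-mode bound
    obj = object.__new__(ScoreComponents)
    object.__setattr__(obj, "m", m_total)
    object.__setattr__(obj, "t", t)
    object.__setattr__(obj, "r", r)
    object.__setattr__(obj, "m_t", partition.m_t)
    return obj


def mutate(motif: DegenerateMotif, rng: np.random.Generator) -> DegenerateMotif:
    """Replace one uniformly chosen position by a different uniform IUPAC code."""
    pos = int(rng.integers(len(motif.symbols)))
    cur = motif.symbols[pos]
    alternatives = [c for c in IUPAC_ALPHABET if c != cur]
    new = alternatives[int(rng.integers(len(alternatives)))]
    return DegenerateMotif(motif.symbols[:pos] + new + motif.symbols[pos + 1 :])


def acceptance_probability(s_new: float, s_old: float, exponent: float = 10.0) -> float:
    """Probability of keeping a mutant: ``min(1, (s_new/s_old)**exponent)``."""
    if s_new < 0 or s_old < 0:
        raise ValueError("scores must be nonnegative")
    if s_old == 0:
        return 1.0
    return min(1.0, (s_new / s_old) ** exponent)


def accept(s_new: float, s_old: float, u: float, exponent: float = 10.0) -> bool:
    """Keep the mutant iff ``u < (s_new/s_old)**exponent``.

    Any ``s_new >= s_old`` is always kept (the ratio power is >= 1 > u).
    A zero previous score always accepts, escaping degenerate starts.
    """
    if s_new < 0 or s_old < 0:
        raise ValueError("scores must be nonnegative")
    if s_old == 0:
        return True
    return u < (s_new / s_old) ** exponent


def random_motif(length: int, rng: np.random.Generator) -> DegenerateMotif:
    """Each symbol uniform over the 15 IUPAC codes."""
    idx = rng.integers(len(IUPAC_ALPHABET), size=length)
    return DegenerateMotif("".join(IUPAC_ALPHABET[i] for i in idx))


def search(partition: TranscriptomePartition, config: SearchConfig) -> SearchResult:
    """Run the annealing search and return the ranked ledger of accepted motifs.

    Per-restart random streams are derived deterministically from the master
    seed, so results are reproducible and restart-count independent.
    Evaluations are cached per motif (scores are deterministic).
    """
    get_encoded(partition)  # build (and JIT-warm) once up front
    cache: dict[str, ScoreComponents] = {}
    ledger_map: dict[str, Candidate] = {}
    trajectory: list[dict] = []

    def eval_cached(motif: DegenerateMotif) -> ScoreComponents:
        comps = cache.get(motif.symbols)
        if comps is None:
            comps = evaluate(motif, partition, config.mrna_hit_mode)
            cache[motif.symbols] = comps
        return comps

    def record(motif: DegenerateMotif, score: float, comps: ScoreComponents,
               iteration: int, restart: int) -> None:
        if motif.symbols not in ledger_map:
            ledger_map[motif.symbols] = Candidate(motif, score, comps, iteration, restart)

    streams = np.random.SeedSequence(config.seed).spawn(config.restarts)
    for restart, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        current = random_motif(config.motif_length, rng)
        comps = eval_cached(current)
        s_old = score_fn(comps)
        record(current, s_old, comps, 0, restart)
        best_score = s_old
        n_accepted = 0
        for it in range(1, config.iterations + 1):
            proposal = mutate(current, rng)
            comps = eval_cached(proposal)
            s_new = score_fn(comps)
            u = float(rng.random())
            if accept(s_new, s_old, u, config.acceptance_exponent):
                current = proposal
                s_old = s_new
                n_accepted += 1
                record(current, s_new, comps, it, restart)
                if s_new > best_score:
                    best_score = s_new
        trajectory.append(
            {"restart": restart, "best_score": best_score,
             "n_accepted": n_accepted, "n_iterations": config.iterations}
        )
        logger.info("restart %d: best score %.5f, %d accepted states",
                    restart, best_score, n_accepted)

    ledger = sorted(
        ledger_map.values(),
        key=lambda c: (-c.score, -c.motif.degeneracy, c.motif.symbols),
    )
    return SearchResult(ledger=ledger, best=ledger[0], trajectory_summary=trajectory)


@dataclass(frozen=True)
class PrimerChoice:
    """The selected primer, its mRNA-sense motif candidate, and its ledger rank."""

    primer: DegenerateMotif
    candidate: Candidate
    rank: int  # 0-based rank in the ledger; equals the number of candidates skipped


_STRONG_3P = frozenset("GCS")  # symbols whose code sets are subsets of {G, C}


def select_primer(result: SearchResult, gc_rule_width: int = 2) -> PrimerChoice:
    """Pick the best-ranked candidate whose primer has a strong-binding 3' end.

    The primer is the reverse complement of the mRNA-sense motif; the rule
    requires each of the primer's final ``gc_rule_width`` symbols to denote
    only G/C bases (symbols G, C or S).  ``gc_rule_width = 0`` returns the
    top-scoring candidate unconditionally.
    """
    if not result.ledger:
        raise ValueError("empty ledger")
    for rank, cand in enumerate(result.ledger):
        primer = reverse_complement(cand.motif)
        tail = primer.symbols[len(primer.symbols) - gc_rule_width :] if gc_rule_width else ""
        if all(s in _STRONG_3P for s in tail):
            if rank > 0:
                logger.info("GC 3'-end rule skipped %d higher-scoring candidates", rank)
            return PrimerChoice(primer=primer, candidate=cand, rank=rank)
    raise ValueError(
        f"no candidate primer ends in {gc_rule_width} strong-binding (G/C) symbols; "
        "widen the ledger (more iterations/restarts) or use gc_rule_width=0"
    )
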