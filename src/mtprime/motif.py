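"""Degenerate-oligonucleotide algebra over the IUPAC nucleotide alphabet.

A degenerate motif is a string over the 15 IUPAC nucleotide codes; each
symbol denotes a set of 1-4 concrete bases and the motif stands for the
mixture of all its concrete expansions.  Matching is subset containment:
a DNA window matches iff at every position the window's base is a concrete
A/C/G/T that lies inside the motif symbol's code set.  Ambiguous bases in
the *target* sequence never match (a primer cannot be guaranteed to anneal
to an unknown base), which keeps occurrence counts conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "DegenerateMotif",
    "SiteList",
    "code_set",
    "degeneracy",
    "reverse_complement",
    "matches",
    "count_sites",
]

#: Standard IUPAC nucleotide code table (code -> set of concrete bases).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Watson-Crick complement lifted to code sets (A<->T, C<->G, R<->Y,
#: K<->M, B<->V, D<->H; S, W and N are self-complementary).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

#: Fixed symbol order used by random draws (search initialisation/mutation).
IUPAC_ALPHABET: str = "ACGTRYSWKMBDHVN"

# bit encoding A=1 C=2 G=4 T=8; anything else (ambiguity codes in targets,
# record separators) gets bit 16 and can never be a subset of a motif mask
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {
    sym: reduce(lambda a, b: a | b, (_BASE_BITS[x] for x in bases))
    for sym, bases in IUPAC_SETS.items()
}

_SEQ_LUT = np.full(256, 16, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _SEQ_LUT[ord(_b)] = _v
    _SEQ_LUT[ord(_b.lower())] = _v


def encode_target(seq: str) -> np.ndarray:
    """Encode a target DNA string as uint8 base bits (non-ACGT -> 16)."""
    return _SEQ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def code_set(symbol: str) -> frozenset[str]:
    """Concrete base set of a single IUPAC code."""
    try:
        return IUPAC_SETS[symbol]
    except KeyError:
        raise ValueError(f"unknown IUPAC nucleotide code: {symbol!r}") from None


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC-coded oligonucleotide with subset-match semantics.

    Primers are the reverse complements of mRNA-sense motifs; the same
    class represents both.
    """

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("motif must have length >= 1")
        bad = [s for s in self.symbols if s not in IUPAC_SETS]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in motif: {bad}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def degeneracy(self) -> int:
        """Number of concrete expansions (product of code-set sizes)."""
        n = 1
        for s in self.symbols:
            n *= len(IUPAC_SETS[s])
        return n

    def reverse_complement(self) -> "DegenerateMotif":
        return DegenerateMotif(
            "".join(IUPAC_COMPLEMENT[s] for s in reversed(self.symbols))
        )

    def matches(self, window: str) -> bool:
        """True iff ``window`` (concrete DNA, same length) lies in every code set."""
        if len(window) != len(self.symbols):
            raise ValueError(
                f"window length {len(window)} != motif length {len(self.symbols)}"
            )
        for sym, base in zip(self.symbols, window.upper()):
            if base not in IUPAC_SETS[sym]:
                return False
        return True

    def inv_masks(self) -> np.ndarray:
        """Per-position inverted bit masks: target bits & mask != 0 => mismatch."""
        return np.array(
            [0xFF ^ _CODE_BITS[s] for s in self.symbols], dtype=np.uint8
        )

    def expansions(self) -> Iterable[str]:
        """All concrete expansions, lexicographic (use only for small degeneracy)."""
        from itertools import product

        for combo in product(*(sorted(IUPAC_SETS[s]) for s in self.symbols)):
            yield "".join(combo)


def _as_motif(motif: "DegenerateMotif | str") -> DegenerateMotif:
    return motif if isinstance(motif, DegenerateMotif) else DegenerateMotif(motif)


def degeneracy(motif: "DegenerateMotif | str") -> int:
    return _as_motif(motif).degeneracy


def reverse_complement(motif: "DegenerateMotif | str") -> DegenerateMotif:
    return _as_motif(motif).reverse_complement()


def matches(motif: "DegenerateMotif | str", window: str) -> bool:
    return _as_motif(motif).matches(window)


@dataclass(frozen=True)
class SiteList:
    """Exact occurrence sites of a motif on one transcript (sense strand).

    Positions are 0-based start offsets, strictly increasing; overlapping
    occurrences are all counted.
    """

    transcript_id: str
    positions: tuple[int, ...]
    count: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "count", len(self.positions))
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")


def scan_positions(motif: "DegenerateMotif | str", seq: str) -> np.ndarray:
    """Start offsets of all (overlapping) motif occurrences in ``seq``."""
    motif = _as_motif(motif)
    L = len(motif)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    arr = encode_target(seq)
    inv = motif.inv_masks()
    ok = (arr[0:n] & inv[0]) == 0
    for j in range(1, L):
        ok &= (arr[j : j + n] & inv[j]) == 0
    return np.nonzero(ok)[0]


def count_sites(motif: "DegenerateMotif | str", record) -> SiteList:
    """All start offsets where the motif matches a transcript's sense strand.

    ``record`` is a :class:`~mtprime.transcriptome.TranscriptRecord` (or any
    object with ``id`` and ``seq``).  Sequences shorter than the motif yield
    an empty site list.
    """
    pos = scan_positions(motif, record.seq)
    return SiteList(record.id, tuple(int(p) for p in pos))
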