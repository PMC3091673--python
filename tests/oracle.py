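"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and self-contained: a literal IUPAC table and a
position-by-position window scan, kept independent of the package's
accelerated code paths.
"""

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ORACLE_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}


def oracle_positions(motif: str, seq: str) -> list[int]:
    """All start offsets where every window base lies in the motif's code set."""
    L = len(motif)
    out = []
    for i in range(len(seq) - L + 1):
        if all(seq[i + j] in ORACLE_IUPAC[motif[j]] for j in range(L)):
            out.append(i)
    return out


def oracle_revcomp(motif: str) -> str:
    return "".join(ORACLE_COMPLEMENT[s] for s in reversed(motif))


def oracle_degeneracy(motif: str) -> int:
    n = 1
    for s in motif:
        n *= len(ORACLE_IUPAC[s])
    return n


def oracle_evaluate(motif: str, partition) -> tuple[int, int, int]:
    """(m as presence over mRNAs, t and r as total occurrences)."""
    m = sum(bool(oracle_positions(motif, rec.seq)) for rec in partition.mrna)
    t = sum(len(oracle_positions(motif, rec.seq)) for rec in partition.trna)
    r = sum(len(oracle_positions(motif, rec.seq)) for rec in partition.rrna)
    return m, t, r
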