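"""Fast occurrence scanning over a bit-encoded, concatenated transcriptome.

Each sequence set of a partition is packed once into a single uint8 array
(base bits A=1 C=2 G=4 T=8; everything else, including the separators
between records, gets bit 16 and can never match).  A motif is a vector of
inverted masks; a window matches iff ``target_bits & inv_mask == 0`` at
every position.  Windows spanning a record boundary hit a separator and
fail, so one separator per boundary suffices.

Two scan paths share that match definition:

* a plain early-exit kernel over every window start;
* a 6-mer index path: the concrete 6-mer expansions of the motif's least
  degenerate 6-symbol block are enumerated, candidate positions are read
  from a precomputed CSR index of the sequence, and only those candidates
  are verified in full.  Used when the block has few enough expansions to
  make the lookup cheaper than the full scan.

This is an internal acceleration layer: its observable behaviour is
defined by (and tested against) the naive position-by-position scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .motif import IUPAC_SETS, DegenerateMotif, encode_target

_SEP = np.array([16], dtype=np.uint8)

_K = 6  # index word size
_NKEYS = 4 ** _K

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
#: per IUPAC symbol, the sorted 2-bit base codes of its code set
_CODE4 = {
    sym: np.array(sorted(_BASE_IDX[b] for b in bases), dtype=np.int64)
    for sym, bases in IUPAC_SETS.items()
}

# fallback to the plain scan when the chosen block expands to this many
# 6-mers or more (lookup would touch a large fraction of all windows)
_MAX_BLOCK_KEYS = 2048

_IDX_LUT = np.full(256, 4, dtype=np.int8)
for _b, _v in _BASE_IDX.items():
    _IDX_LUT[ord(_b)] = _v
    _IDX_LUT[ord(_b.lower())] = _v


@njit(cache=False)
def _scan(arr, rec_ids, n_rec, inv):  # pragma: no cover - jitted
    L = inv.shape[0]
    n = arr.shape[0] - L + 1
    hit = np.zeros(n_rec, np.uint8)
    total = 0
    for i in range(n):
        ok = True
        for j in range(L):
            if arr[i + j] & inv[j]:
                ok = False
                break
        if ok:
            total += 1
            hit[rec_ids[i]] = 1
    n_hit = 0
    for k in range(n_rec):
        n_hit += hit[k]
    return n_hit, total


@njit(cache=False)
def _gather_verify(keys, offsets, pos_by_key, block_off, arr, rec_ids, n_rec, inv):  # pragma: no cover - jitted
    L = inv.shape[0]
    n = arr.shape[0]
    hit = np.zeros(n_rec, np.uint8)
    total = 0
    for ki in range(keys.shape[0]):
        k = keys[ki]
        for idx in range(offsets[k], offsets[k + 1]):
            start = pos_by_key[idx] - block_off
            if start < 0 or start + L > n:
                continue
            ok = True
            for j in range(L):
                if arr[start + j] & inv[j]:
                    ok = False
                    break
            if ok:
                total += 1
                hit[rec_ids[start]] = 1
    n_hit = 0
    for k in range(n_rec):
        n_hit += hit[k]
    return n_hit, total


def _block_keys(symbols: str) -> np.ndarray:
    """Packed 2-bit keys of every concrete expansion of a 6-symbol block."""
    keys = np.zeros(1, dtype=np.int64)
    for s in symbols:
        keys = (keys[:, None] * 4 + _CODE4[s][None, :]).ravel()
    return keys


class EncodedClass:
    """One sequence class packed (and 6-mer indexed) for scanning."""

    __slots__ = ("arr", "rec_ids", "n_rec", "offsets", "pos_by_key")

    def __init__(self, records) -> None:
        self.n_rec = len(records)
        if not records:
            self.arr = np.empty(0, dtype=np.uint8)
            self.rec_ids = np.empty(0, dtype=np.int32)
            self.offsets = None
            self.pos_by_key = None
            return
        chunks = []
        id_chunks = []
        for i, rec in enumerate(records):
            enc = encode_target(rec.seq)
            chunks.append(enc)
            id_chunks.append(np.full(enc.shape[0], i, dtype=np.int32))
            if i != len(records) - 1:
                chunks.append(_SEP)
                id_chunks.append(np.full(1, i, dtype=np.int32))
        self.arr = np.concatenate(chunks)
        self.rec_ids = np.concatenate(id_chunks)
        self._build_index(records)

    def _build_index(self, records) -> None:
        raw = "".join(rec.seq + "\x00" for rec in records)[:-1]
        c = _IDX_LUT[np.frombuffer(raw.encode("latin-1"), dtype=np.uint8)].astype(np.int64)
        n6 = c.shape[0] - _K + 1
        if n6 <= 0:
            self.offsets = None
            self.pos_by_key = None
            return
        bad = c >= 4
        anybad = bad[0:n6].copy()
        key = c[0:n6].copy()
        for j in range(1, _K):
            anybad |= bad[j : j + n6]
            key = key * 4 + c[j : j + n6]
        key[anybad] = _NKEYS  # overflow bucket, never queried
        counts = np.bincount(key, minlength=_NKEYS + 1)
        self.offsets = np.zeros(_NKEYS + 2, dtype=np.int64)
        np.cumsum(counts, out=self.offsets[1 : counts.shape[0] + 1])
        self.offsets[counts.shape[0] + 1 :] = self.offsets[counts.shape[0]]
        self.pos_by_key = np.argsort(key, kind="stable").astype(np.int64)

    def scan(self, motif: DegenerateMotif) -> tuple[int, int]:
        """(number of records with >=1 occurrence, total occurrences)."""
        if self.n_rec == 0:
            return 0, 0
        symbols = motif.symbols
        L = len(symbols)
        inv = motif.inv_masks()
        if L >= _K and self.pos_by_key is not None:
            # pick the less degenerate of the head / tail 6-symbol blocks
            best_off, best_deg = None, _MAX_BLOCK_KEYS
            for off in (0, L - _K):
                deg = 1
                for s in symbols[off : off + _K]:
                    deg *= len(IUPAC_SETS[s])
                if deg < best_deg:
                    best_off, best_deg = off, deg
            if best_off is not None:
                keys = _block_keys(symbols[best_off : best_off + _K])
                n_hit, total = _gather_verify(
                    keys, self.offsets, self.pos_by_key, best_off,
                    self.arr, self.rec_ids, self.n_rec, inv,
                )
                return int(n_hit), int(total)
        n_hit, total = _scan(self.arr, self.rec_ids, self.n_rec, inv)
        return int(n_hit), int(total)


class EncodedPartition:
    __slots__ = ("mrna", "rrna", "trna")

    def __init__(self, partition) -> None:
        self.mrna = EncodedClass(partition.mrna)
        self.rrna = EncodedClass(partition.rrna)
        self.trna = EncodedClass(partition.trna)


def get_encoded(partition) -> EncodedPartition:
    """Encode a partition once, caching on the partition instance."""
    enc = partition.__dict__.get("_encoded")
    if enc is None:
        enc = EncodedPartition(partition)
        partition.__dict__["_encoded"] = enc
    return enc
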