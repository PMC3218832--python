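"""Canonical (strand-collapsed) k-mer counting and cross-pool normalization.

Oligos are double-stranded in the binding reaction, so a k-mer and its
reverse complement are the same binding substrate.  Counting therefore
collapses each window onto its *canonical* form — the lexicographically
smaller of the k-mer and its reverse complement — which makes the 11-mer
universe 4^11 / 2 = 2,097,152 sequences.  Pools of different sequencing
depth are made comparable by scaling every table down to the total of
the smallest pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")
_BASES = "ACGT"
_ASCII_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ASCII_LUT[ord(_b)] = _i
#: above this matrix width the dense 4^k count array would be too large
_MAX_FAST_K = 13


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return the canonical form: ``min(kmer, revcomp(kmer))`` lexicographically.

    Idempotent; raises ``ValueError`` on non-ACGT characters.
    """
    if not _VALID.issuperset(kmer):
        bad = sorted(set(kmer) - _VALID)
        raise ValueError(f"non-ACGT character(s) {bad} in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_space_size(k: int) -> int:
    """Number of distinct canonical k-mers.

    4^k sequences pair up under reverse complement; for even k the
    4^(k/2) palindromes are their own partner, hence
    ``(4**k + 4**(k//2)) // 2``; for odd k there are no reverse-complement
    palindromes and the count is ``4**k // 2``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


@dataclass
class KmerTable:
    """Counts of canonical k-mers for one pool.

    Before normalization all counts are integers summing to ``n_total``.
    After :func:`normalize_to_smallest` counts are reals and
    ``n_total`` equals the smallest pool's total.
    """

    k: int
    counts: dict[str, float] = field(default_factory=dict)
    n_total: float = 0.0
    normalized: bool = False
    scale_factor: float = 1.0

    def get(self, kmer: str, default: float = 0.0) -> float:
        return self.counts.get(canonical(kmer), default)

    def write_tsv(self, path: str | Path) -> None:
        """Sorted two-column TSV with a header line carrying the metadata."""
        with open(path, "w") as fh:
            fh.write(
                f"# k={self.k}\tn_total={self.n_total:.10g}"
                f"\tscale_factor={self.scale_factor:.10g}"
                f"\tnormalized={int(self.normalized)}\n"
            )
            fh.write("kmer\tcount\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]:.10g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KmerTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header line")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").strip().split("\t")
            )
            fh.readline()  # column header
            counts: dict[str, float] = {}
            for line in fh:
                kmer, count = line.rstrip("\n").split("\t")
                counts[kmer] = float(count)
        return cls(
            k=int(meta["k"]),
            counts=counts,
            n_total=float(meta["n_total"]),
            normalized=bool(int(meta.get("normalized", "0"))),
            scale_factor=float(meta.get("scale_factor", "1")),
        )


def encode_pool(sequences: list[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 code matrix."""
    if not sequences:
        return np.zeros((0, 0), dtype=np.uint8)
    length = len(sequences[0])
    raw = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes = _ASCII_LUT[raw].reshape(len(sequences), length)
    if (codes == 255).any():
        raise ValueError("non-ACGT character in pool sequences")
    return codes


def _decode_indices(indices: np.ndarray, k: int) -> list[str]:
    """Integer k-mer codes (base-4, most significant base first) -> strings."""
    digits = np.empty((len(indices), k), dtype=np.uint8)
    rem = indices.astype(np.int64).copy()
    for i in range(k - 1, -1, -1):
        digits[:, i] = rem % 4
        rem //= 4
    flat = np.array(list(_BASES))[digits]
    return ["".join(row) for row in flat]


def _count_equal_length(sequences: list[str], k: int, stranded: bool) -> KmerTable:
    """Dense vectorized counting path for equal-length ACGT pools."""
    codes = encode_pool(sequences)
    n, length = codes.shape
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    acc = np.zeros(4**k, dtype=np.int64)
    for offset in range(length - k + 1):
        sub = codes[:, offset : offset + k].astype(np.int64)
        fwd = sub @ powers
        if stranded:
            keys = fwd
        else:
            rc = (3 - sub) @ powers[::-1]
            keys = np.minimum(fwd, rc)
        acc += np.bincount(keys, minlength=4**k)
    nonzero = np.flatnonzero(acc)
    kmers = _decode_indices(nonzero, k)
    counts = dict(zip(kmers, acc[nonzero].astype(float)))
    return KmerTable(k=k, counts=counts, n_total=float(n * (length - k + 1)))


def count_kmers(sequences, k: int, stranded: bool = False) -> KmerTable:
    """Count every length-k window of every sequence.

    Each window contributes 1 to its canonical key (or to its literal
    key when ``stranded``).  ``n_total`` equals the number of windows,
    irrespective of strand composition.  Equal-length ACGT pools with
    modest k take a dense vectorized path; the generic path handles
    ragged input.
    """
    sequences = sequences if isinstance(sequences, list) else list(sequences)
    if sequences and len(sequences[0]) < k:
        raise ValueError(
            f"sequence of length {len(sequences[0])} shorter than k={k}"
        )
    if (
        sequences
        and k <= _MAX_FAST_K
        and len({len(s) for s in sequences}) == 1
        and all(_VALID.issuperset(s) for s in sequences)
    ):
        return _count_equal_length(sequences, k, stranded)
    counts: dict[str, float] = {}
    n_total = 0
    for seq in sequences:
        if len(seq) < k:
            raise ValueError(
                f"sequence of length {len(seq)} shorter than k={k}"
            )
        n_total += len(seq) - k + 1
        for i in range(len(seq) - k + 1):
            key = seq[i : i + k] if stranded else canonical(seq[i : i + k])
            counts[key] = counts.get(key, 0) + 1
    return KmerTable(k=k, counts=counts, n_total=float(n_total))


def normalize_to_smallest(tables: list[KmerTable]) -> list[KmerTable]:
    """Scale every table by ``min(n_total) / n_total``.

    The smallest pool is left unchanged; within-table proportions are
    preserved exactly.  Intended for reporting and ranking — the
    enrichment test consumes the raw integer counts.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to normalize")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"tables have mixed k: {sorted(ks)}")
    if any(t.n_total <= 0 for t in tables):
        raise ValueError("cannot normalize an empty table")
    smallest = min(t.n_total for t in tables)
    out = []
    for t in tables:
        factor = smallest / t.n_total
        out.append(
            KmerTable(
                k=t.k,
                counts={kmer: c * factor for kmer, c in t.counts.items()},
                n_total=t.n_total * factor,
                normalized=True,
                scale_factor=factor,
            )
        )
    return out
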