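"""Small shared helpers: DNA encoding, reverse complement, k-mers, seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer base codes 0..3 = A,C,G,T; 4 = N (never matches)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def canonical_kmers(seq: str, k: int):
    """Yield (canonical_kmer, position, is_forward) for each k-mer without N.

    is_forward is True when the forward-strand k-mer is the canonical one.
    """
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        if fwd <= rev:
            yield fwd, i, True
        else:
            yield rev, i, False


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)
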