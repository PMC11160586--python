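"""64-bit hashing of k-mers and abstract set elements.

FracMinHash sketching needs a hash that behaves like a uniform map onto
``[0, H]`` with ``H = 2**64 - 1``.  Following the sourmash ecosystem, k-mers
are hashed with MurmurHash3 (x64_128 variant, lower 64 bits of the digest)
applied to the bytes of the *canonical* k-mer -- the lexicographically
smaller of a k-mer and its reverse complement -- so that sketches are
strand-independent.  The default seed is 42, the sourmash convention.

Two implementations of the hash are provided: a general pure-Python routine
for arbitrary byte strings (used for k-mers), and a numpy-vectorised routine
specialised to 8-byte inputs (used to hash millions of abstract integer
elements in the simulation harness).  Both follow the public-domain
MurmurHash3 reference algorithm and are cross-checked against each other and
against the published SMHasher verification constant in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HASH_MAX",
    "DEFAULT_SEED",
    "HashConfig",
    "InvalidKmerError",
    "canonical_kmer",
    "reverse_complement",
    "hash_kmer",
    "hash_element",
    "hash_elements",
    "murmur3_x64_128",
    "murmur64",
]

#: Upper end (inclusive) of the hash range: H = 2**64 - 1.
HASH_MAX = 2**64 - 1

#: Default MurmurHash3 seed, matching sourmash.
DEFAULT_SEED = 42

_MASK64 = 0xFFFFFFFFFFFFFFFF


class InvalidKmerError(ValueError):
    """Raised when a k-mer contains a character outside {A, C, G, T}."""


@dataclass(frozen=True)
class HashConfig:
    """Hashing parameters shared by every sketch in a comparison.

    Parameters
    ----------
    seed
        MurmurHash3 seed; sketches hashed under different seeds are
        incomparable.  Defaults to 42 (the sourmash convention).
    """

    seed: int = DEFAULT_SEED

    #: Maximum hash value (inclusive); fixed at 2**64 - 1.
    H: int = HASH_MAX

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("hash seed must be non-negative")
        if self.H != HASH_MAX:
            raise ValueError("hash range is fixed at H = 2**64 - 1")


# ---------------------------------------------------------------------------
# MurmurHash3 x64_128 (public-domain algorithm by Austin Appleby)
# ---------------------------------------------------------------------------

_C1 = 0x87C37B91114253D5
_C2 = 0x4CF5AD432745937F


def _rotl64(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _MASK64


def _fmix64(k: int) -> int:
    k ^= k >> 33
    k = (k * 0xFF51AFD7ED558CCD) & _MASK64
    k ^= k >> 33
    k = (k * 0xC4CEB9FE1A85EC53) & _MASK64
    k ^= k >> 33
    return k


def murmur3_x64_128(data: bytes, seed: int = 0) -> int:
    """MurmurHash3 x64_128 of ``data``; returns the 128-bit digest as an int.

    The digest integer is ``h1 | (h2 << 64)``, i.e. its low 64 bits are the
    first eight bytes of the canonical little-endian digest -- the value
    sourmash calls ``murmur64``.
    """
    length = len(data)
    h1 = seed & _MASK64
    h2 = seed & _MASK64

    nblocks = length // 16
    for i in range(nblocks):
        k1 = int.from_bytes(data[i * 16 : i * 16 + 8], "little")
        k2 = int.from_bytes(data[i * 16 + 8 : i * 16 + 16], "little")

        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1
        h1 = _rotl64(h1, 27)
        h1 = (h1 + h2) & _MASK64
        h1 = (h1 * 5 + 0x52DCB6F1) & _MASK64

        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2
        h2 = _rotl64(h2, 31)
        h2 = (h2 + h1) & _MASK64
        h2 = (h2 * 5 + 0x38495AB5) & _MASK64

    tail = data[nblocks * 16 :]
    k1 = 0
    k2 = 0
    tlen = len(tail)
    if tlen > 8:
        k2 = int.from_bytes(tail[8:], "little")
        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2
    if tlen > 0:
        k1 = int.from_bytes(tail[:8], "little")
        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1

    h1 ^= length
    h2 ^= length
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    h1 = _fmix64(h1)
    h2 = _fmix64(h2)
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    return h1 | (h2 << 64)


def murmur64(data: bytes, seed: int = DEFAULT_SEED) -> int:
    """Lower 64 bits of MurmurHash3 x64_128 -- the sourmash hash of ``data``."""
    return murmur3_x64_128(data, seed) & _MASK64


# ---------------------------------------------------------------------------
# Canonical k-mers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(kmer: str) -> str:
    """Reverse complement of an ACGT string (no validation)."""
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse
    complement.

    Raises
    ------
    InvalidKmerError
        If ``kmer`` contains any character outside {A, C, G, T}.  Callers
        that scan sequences skip such windows rather than aborting.
    """
    if not _VALID.issuperset(kmer):
        bad = sorted(set(kmer) - _VALID)
        raise InvalidKmerError(f"k-mer {kmer!r} contains invalid characters: {bad}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def hash_kmer(kmer: str, config: HashConfig = HashConfig()) -> int:
    """Hash a k-mer to a 64-bit value, strand-independently.

    The k-mer is canonicalised first, so ``hash_kmer(x) ==
    hash_kmer(reverse_complement(x))`` for every valid ``x``.
    """
    return murmur64(canonical_kmer(kmer).encode("ascii"), config.seed)


# ---------------------------------------------------------------------------
# Abstract elements (simulation support)
# ---------------------------------------------------------------------------


def hash_element(
    element: int, replicate_seed: int, config: HashConfig = HashConfig()
) -> int:
    """Hash a non-negative integer element to a 64-bit value.

    The element's 8-byte little-endian encoding is hashed with MurmurHash3
    at seed ``replicate_seed``.  Re-seeding per simulation replicate makes
    replicates statistically independent draws of the sketching process.
    """
    return murmur64(int(element).to_bytes(8, "little"), replicate_seed)


def hash_elements(elements: np.ndarray, replicate_seed: int) -> np.ndarray:
    """Vectorised :func:`hash_element` over a uint64 array.

    Specialised MurmurHash3 x64_128 for 8-byte inputs: with no 16-byte body
    blocks the whole message lands in the k1 tail, so the mixing reduces to
    a short fixed sequence of wrapping uint64 operations that numpy executes
    elementwise.  Bit-identical to the scalar routine.
    """
    x = np.ascontiguousarray(elements, dtype=np.uint64)
    seed = np.uint64(replicate_seed & _MASK64)
    c1 = np.uint64(_C1)
    c2 = np.uint64(_C2)

    k1 = x * c1
    k1 = (k1 << np.uint64(31)) | (k1 >> np.uint64(33))
    k1 = k1 * c2

    h1 = (seed ^ k1) ^ np.uint64(8)
    h2 = np.uint64(seed ^ np.uint64(8))

    h1 = h1 + h2
    h2 = h2 + h1

    for h in (0, 1):
        v = h1 if h == 0 else h2
        v = v ^ (v >> np.uint64(33))
        v = v * np.uint64(0xFF51AFD7ED558CCD)
        v = v ^ (v >> np.uint64(33))
        v = v * np.uint64(0xC4CEB9FE1A85EC53)
        v = v ^ (v >> np.uint64(33))
        if h == 0:
            h1 = v
        else:
            h2 = v

    h1 = h1 + h2
    return h1
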