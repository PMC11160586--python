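"""FracMinHash sketch construction and sourmash-compatible signature I/O.

A FracMinHash sketch of a set ``A`` under a hash ``h`` onto ``[0, H]`` and a
scale factor ``s`` in ``[0, 1]`` is the subset of hash values at or below
``H*s``::

    FRAC_s(A) = { h(a) : a in A, h(a) <= H*s }

Unlike classical fixed-size MinHash, the sketch grows proportionally with
the set, which is what makes containment-style and cosine estimates sound
for sets of dissimilar sizes.  Sketches are presence/absence only: a k-mer
occurring many times contributes one hash.

Signatures are serialised in the sourmash JSON layout (``mins`` list,
``max_hash``, ``ksize``, ``seed``, ``hash_function`` tag ``0.murmur64``) so
sketches can be exchanged with the wider ecosystem.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

import numpy as np
from Bio import SeqIO

from .hashing import (
    HASH_MAX,
    HashConfig,
    InvalidKmerError,
    canonical_kmer,
    hash_elements,
    murmur64,
)

__all__ = [
    "Sketch",
    "SequenceRecord",
    "SignatureFormatError",
    "max_hash_for_scale",
    "sketch_sequences",
    "sketch_element_set",
    "read_sequences",
    "write_signature",
    "read_signature",
]


class SignatureFormatError(ValueError):
    """Raised when a signature file does not parse as a valid sketch."""


def max_hash_for_scale(scale: float) -> int:
    """Retention threshold floor(H*s) for a scale factor ``s`` in [0, 1]."""
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"scale factor must be in [0, 1], got {scale}")
    if scale == 1.0:
        return HASH_MAX
    return int(HASH_MAX * scale)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (minimal FASTA/FASTQ record)."""

    id: str
    sequence: str


@dataclass
class Sketch:
    """A FracMinHash sketch: sorted distinct retained hash values.

    Attributes
    ----------
    ksize
        k-mer length; 0 for sketches of abstract element sets.
    scale
        Scale factor ``s`` in [0, 1]; the fraction of the hash range (and
        hence, in expectation, of the input set) retained.
    seed
        MurmurHash3 seed the hashes were produced with.
    hashes
        Strictly increasing uint64 array, each value <= floor(H*scale).
    name
        Free-text sample label.
    """

    ksize: int
    scale: float
    seed: int
    hashes: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        object.__setattr__(self, "hashes", h)
        if h.ndim != 1:
            raise ValueError("hashes must be one-dimensional")
        if h.size and not np.all(h[1:] > h[:-1]):
            raise ValueError("hashes must be strictly increasing")
        if h.size and int(h[-1]) > self.max_hash_kept:
            raise ValueError(
                f"hash {int(h[-1])} exceeds retention threshold {self.max_hash_kept}"
            )

    @property
    def max_hash_kept(self) -> int:
        """Largest hash value this sketch may retain: floor(H*scale)."""
        return max_hash_for_scale(self.scale)

    @property
    def num_hashes(self) -> int:
        return int(self.hashes.size)

    def __len__(self) -> int:
        return self.num_hashes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.ksize == other.ksize
            and self.scale == other.scale
            and self.seed == other.seed
            and self.name == other.name
            and np.array_equal(self.hashes, other.hashes)
        )

    def compatible_with(self, other: "Sketch") -> bool:
        """Sketches are comparable when ksize, scale and seed all match."""
        return (
            self.ksize == other.ksize
            and self.max_hash_kept == other.max_hash_kept
            and self.seed == other.seed
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _kmer_hashes(sequence: str, ksize: int, seed: int) -> Iterator[int]:
    """Hashes of all valid canonical k-mer windows of one sequence.

    Windows containing non-ACGT characters (N, ambiguity codes) are skipped
    silently; lowercase input is uppercased first.
    """
    seq = sequence.upper()
    for i in range(len(seq) - ksize + 1):
        window = seq[i : i + ksize]
        try:
            canon = canonical_kmer(window)
        except InvalidKmerError:
            continue
        yield murmur64(canon.encode("ascii"), seed)


def sketch_sequences(
    records: Iterable[SequenceRecord],
    ksize: int,
    scale: float,
    config: HashConfig = HashConfig(),
    name: str = "",
) -> Sketch:
    """Build a FracMinHash sketch of the canonical k-mer set of ``records``.

    Every valid length-``ksize`` window of every record is canonicalised,
    hashed, and retained iff its hash is at or below ``floor(H*scale)``.
    Duplicate k-mers collapse (presence/absence semantics); records shorter
    than ``ksize`` contribute nothing.  ``scale=0`` retains nothing.
    """
    if ksize < 1:
        raise ValueError(f"ksize must be >= 1, got {ksize}")
    threshold = max_hash_for_scale(scale)
    if scale == 0.0:
        threshold = -1  # retain nothing, including a hypothetical zero hash
    kept: set[int] = set()
    for record in records:
        seq = record.sequence.strip()
        for h in _kmer_hashes(seq, ksize, config.seed):
            if h <= threshold:
                kept.add(h)
    hashes = np.array(sorted(kept), dtype=np.uint64)
    return Sketch(ksize=ksize, scale=scale, seed=config.seed, hashes=hashes, name=name)


def sketch_element_set(
    elements: Union[Sequence[int], np.ndarray],
    scale: float,
    replicate_seed: int,
    config: HashConfig = HashConfig(),
    name: str = "",
) -> Sketch:
    """Build a FracMinHash sketch of a set of non-negative integers.

    Used by the simulation harness, where the universe is abstract rather
    than a k-mer space.  Elements are hashed (vectorised MurmurHash3 of
    their 8-byte encodings, seeded by ``replicate_seed``) and filtered at
    ``floor(H*scale)``.  ``ksize`` is recorded as 0.
    """
    arr = np.asarray(elements, dtype=np.uint64)
    if arr.size == 0:
        hashes = np.empty(0, dtype=np.uint64)
    else:
        hashed = hash_elements(arr, replicate_seed)
        if scale == 0.0:
            hashes = np.empty(0, dtype=np.uint64)
        else:
            threshold = np.uint64(max_hash_for_scale(scale))
            hashes = np.unique(hashed[hashed <= threshold])
    return Sketch(ksize=0, scale=scale, seed=replicate_seed, hashes=hashes, name=name)


# ---------------------------------------------------------------------------
# Sequence file reading
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Union[str, Path]) -> IO[str]:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def read_sequences(path: Union[str, Path]) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file, optionally gzipped.

    The format is auto-detected from the first non-whitespace character
    ('>' FASTA, '@' FASTQ); gzip from the magic bytes.
    """
    handle = _open_maybe_gzip(path)
    try:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return
        else:
            raise SignatureFormatError(
                f"{path}: not FASTA or FASTQ (leading character {first!r})"
            )
        handle.seek(0)
        for rec in SeqIO.parse(handle, fmt):
            yield SequenceRecord(id=rec.id, sequence=str(rec.seq))
    finally:
        handle.close()


# ---------------------------------------------------------------------------
# sourmash-compatible signature I/O
# ---------------------------------------------------------------------------

_HASH_FUNCTION_TAG = "0.murmur64"


def write_signature(sketch: Sketch, path: Union[str, Path]) -> None:
    """Write a sketch as a sourmash-layout JSON signature file.

    The record stores the sorted ``mins`` list, ``ksize``, ``seed``,
    ``max_hash`` (= floor(H*scale)), and the reciprocal ``scaled`` integer.
    Scale factors with a non-integral reciprocal (for which ``scaled``
    is only approximate) additionally store the exact ``scale`` and emit a
    warning; the exact field takes precedence when read back.
    """
    scaled = round(1.0 / sketch.scale) if sketch.scale > 0 else 0
    entry = {
        "ksize": sketch.ksize,
        "seed": sketch.seed,
        "max_hash": sketch.max_hash_kept,
        "scaled": scaled,
        "num": 0,
        "mins": [int(h) for h in sketch.hashes],
        "hash_function": _HASH_FUNCTION_TAG,
        "molecule": "DNA",
    }
    if sketch.scale > 0 and 1.0 / scaled != sketch.scale:
        warnings.warn(
            f"scale factor {sketch.scale} has a non-integral reciprocal; "
            f"storing exact value alongside scaled={scaled}",
            stacklevel=2,
        )
        entry["scale"] = sketch.scale
    elif sketch.scale == 0.0:
        entry["scale"] = 0.0
    doc = [
        {
            "class": "sourmash_signature",
            "name": sketch.name,
            "hash_function": _HASH_FUNCTION_TAG,
            "signatures": [entry],
            "version": 0.4,
        }
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_signature(path: Union[str, Path]) -> Sketch:
    """Read a JSON signature file back into a :class:`Sketch`.

    Accepts files written by :func:`write_signature` as well as
    sourmash-produced DNA signatures (first signature entry of the first
    record).  Raises :class:`SignatureFormatError` naming the offending
    field on malformed input.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SignatureFormatError(f"{path}: malformed JSON ({exc})") from exc
    if isinstance(doc, dict):
        doc = [doc]
    if not isinstance(doc, list) or not doc:
        raise SignatureFormatError(f"{path}: expected a list of signature records")
    record = doc[0]
    sigs = record.get("signatures")
    if not sigs:
        raise SignatureFormatError(f"{path}: missing field 'signatures'")
    entry = sigs[0]
    for fieldname in ("ksize", "mins"):
        if fieldname not in entry:
            raise SignatureFormatError(f"{path}: missing field {fieldname!r}")
    mins = np.asarray(entry["mins"], dtype=np.uint64)
    if mins.size and not np.all(mins[1:] > mins[:-1]):
        raise SignatureFormatError(f"{path}: field 'mins' is not sorted ascending")
    if "scale" in entry:
        scale = float(entry["scale"])
    elif entry.get("scaled"):
        scale = 1.0 / int(entry["scaled"])
    elif "max_hash" in entry:
        max_hash = int(entry["max_hash"])
        scale = 1.0 if max_hash >= HASH_MAX else max_hash / 2**64
    else:
        raise SignatureFormatError(f"{path}: missing field 'max_hash'")
    return Sketch(
        ksize=int(entry["ksize"]),
        scale=scale,
        seed=int(entry.get("seed", HashConfig().seed)),
        hashes=mins,
        name=str(record.get("name", "")),
    )
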