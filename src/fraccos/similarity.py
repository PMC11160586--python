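"""Cosine similarity of sets, exactly and from FracMinHash sketches.

Identifying a set ``A`` in a universe of ``N`` elements with its binary
presence/absence vector ``u`` (``u_i = 1`` iff element ``i`` is in ``A``),
the cosine similarity of two sets is the cosine of the angle between their
vectors,

    cos(theta) = (u . v) / (||u|| ||v||) = |A n B| / sqrt(|A| |B|),

so it never needs the exponentially large vectors themselves -- three set
cardinalities suffice.  The sketch estimator applies the same formula to
the retained hash sets; the scale factor cancels in the ratio, so no
rescaling is applied anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .sketch import Sketch

__all__ = [
    "CosineEstimate",
    "IncompatibleSketchError",
    "set_cosine",
    "sketch_cosine",
    "chord_to_cosine",
]

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


class IncompatibleSketchError(ValueError):
    """Raised when two sketches differ in ksize, scale, or seed.

    Sketches at different scales retain different fractions of the hash
    range; intersecting them estimates nothing meaningful.
    """


@dataclass(frozen=True)
class CosineEstimate:
    """A sketch-based cosine estimate together with the sketch cardinalities.

    ``value = q_sketch / sqrt(m_sketch * n_sketch)`` whenever both sketches
    are non-empty; 0 otherwise.
    """

    value: float
    m_sketch: int
    n_sketch: int
    q_sketch: int


def set_cosine(a, b) -> float:
    """Exact cosine similarity |A n B| / sqrt(|A| |B|) of two finite sets.

    Accepts Python sets or one-dimensional arrays of distinct elements
    (arrays are intersected with a sort-based merge).  Returns 0.0 when
    either set is empty: the all-zero vector has no direction, and 0 is the
    continuous limit as the overlap vanishes.
    """
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a = np.asarray(a)
        b = np.asarray(b)
        if a.size == 0 or b.size == 0:
            return 0.0
        q = int(np.intersect1d(a, b, assume_unique=True).size)
        return q / math.sqrt(a.size * b.size)
    a = a if isinstance(a, (set, frozenset)) else set(a)
    b = b if isinstance(b, (set, frozenset)) else set(b)
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def sketch_cosine(sketch_a: Sketch, sketch_b: Sketch) -> CosineEstimate:
    """Cosine similarity of two FracMinHash sketches.

    The intersection count is exact (computed on the sorted hash arrays),
    so the estimate is ``|H_A n H_B| / sqrt(|H_A| |H_B|)``.  Under the
    concentration results for sketch norms this estimates the true set
    cosine to relative error ``eps*(1+xi)`` with high probability.

    Raises
    ------
    IncompatibleSketchError
        If the sketches differ in ksize, scale, or hash seed.
    """
    if not sketch_a.compatible_with(sketch_b):
        raise IncompatibleSketchError(
            f"sketches are not comparable: "
            f"ksize {sketch_a.ksize}/{sketch_b.ksize}, "
            f"scale {sketch_a.scale}/{sketch_b.scale}, "
            f"seed {sketch_a.seed}/{sketch_b.seed}"
        )
    m = sketch_a.num_hashes
    n = sketch_b.num_hashes
    if m == 0 or n == 0:
        logger.warning("cosine of an empty sketch is defined as 0")
        return CosineEstimate(value=0.0, m_sketch=m, n_sketch=n, q_sketch=0)
    q = int(
        np.intersect1d(sketch_a.hashes, sketch_b.hashes, assume_unique=True).size
    )
    return CosineEstimate(
        value=q / math.sqrt(m * n), m_sketch=m, n_sketch=n, q_sketch=q
    )


def chord_to_cosine(d: float) -> float:
    """Convert a chord distance to a cosine similarity.

    The chord distance between two unit-normalised vectors is
    ``d = sqrt(2 - 2 cos(theta))``, so ``cos(theta) = 1 - d**2 / 2``.
    Tools such as Simka report chord distances; this inverts them.
    """
    if not 0.0 <= d <= _SQRT2 + 1e-12:
        raise ValueError(f"chord distance must be in [0, sqrt(2)], got {d}")
    return max(0.0, 1.0 - d * d / 2.0)
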