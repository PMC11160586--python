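"""Concentration guarantees for FracMinHash cosine estimation, and the
minimum-scale-factor planner built on them.

The guarantees rest on three facts about a FracMinHash sketch at scale
``s`` of a set of size ``|A|`` (with binary vector ``u`` and sketch vector
``u'``):

1. Expectation: ``E[||u'||^2] = s ||u||^2 = s |A|`` -- each element
   survives independently with probability ``s``.
2. Concentration (Chernoff): ``Pr[ | ||u'||^2 - s|A| | >= eps s|A| ]
   <= 2 exp(-s |A| eps^2 / 3)`` for ``0 < eps < 1``.
3. Cosine error: for sets with ``|A| = m``, ``|B| = n``, ``|A n B| = q``,
   the sketch cosine satisfies ``|cos' - cos| <= eps (1 + xi) cos`` with
   probability at least ``1 - 6 exp(-s min(m, n) eps^2 / 3)``, where
   ``xi = 3 (m + n - 2q) / q`` inflates the error band as the overlap
   shrinks.

Inverting the probability bound gives the smallest scale factor that keeps
the estimate within a relative error ``delta`` with confidence ``alpha``
whenever ``xi`` is bounded by a constant ``c`` (equivalently, whenever
``q >= (m + n) / (2 + c/3)``)::

    s >= 3 (1 + c)^2 ln(6 / (1 - alpha)) / (delta^2 min(m, n))

with the substitution ``delta = eps (1 + c)`` relating the tolerated
user-facing error to the free analysis parameter.  When the formula
exceeds 1 the whole set must be kept: there is no room to subsample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "OverlapProfile",
    "ScalePlan",
    "expected_sketch_norm",
    "concentration_tail",
    "cosine_error_envelope",
    "recommend_scale",
    "scale_table",
    "DEFAULT_XI_BOUND",
]

#: Default bound ``c`` on the overlap inflation xi; corresponds to assuming
#: the intersection holds at least ~46% of |A| + |B|.
DEFAULT_XI_BOUND = 0.5


@dataclass(frozen=True)
class OverlapProfile:
    """Cardinalities of a set pair: ``m = |A|``, ``n = |B|``, ``q = |A n B|``.

    ``xi = 3 (m + n - 2q) / q`` is the overlap-dependent inflation factor in
    the cosine error bound; it is 0 iff the sets are identical and is None
    (no guarantee) when the sets are disjoint.
    """

    m: int
    n: int
    q: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("set sizes m and n must be positive")
        if not 0 <= self.q <= min(self.m, self.n):
            raise ValueError(
                f"intersection size q={self.q} must be in [0, min(m, n)="
                f"{min(self.m, self.n)}]"
            )

    @property
    def xi(self) -> Optional[float]:
        """Error inflation 3(m + n - 2q)/q, or None when q = 0."""
        if self.q == 0:
            return None
        return 3.0 * (self.m + self.n - 2 * self.q) / self.q

    @property
    def min_size(self) -> int:
        return min(self.m, self.n)


@dataclass(frozen=True)
class ScalePlan:
    """A recommended scale factor and the requirements that produced it.

    ``s_raw`` is the formula value; ``s = min(s_raw, 1)`` since a scale
    factor cannot exceed 1 (when it would, no subsampling is safe and the
    full set must be used).
    """

    alpha: float
    delta: float
    c: float
    min_size: int
    s_raw: float
    s: float

    @property
    def s_rounded(self) -> float:
        """Scale factor rounded to 4 decimals, the printed-table resolution."""
        return round(self.s, 4)


def expected_sketch_norm(s: float, set_size: int) -> float:
    """Expected squared norm of a sketch vector: ``s * |A|``.

    Equivalently the expected sketch size, since the sketch vector is
    binary.
    """
    return s * set_size


def concentration_tail(s: float, set_size: int, eps: float) -> float:
    """Chernoff bound on the sketch-size deviation probability.

    ``Pr[ | |sketch| - s|A| | >= eps * s|A| ] <= 2 exp(-s |A| eps^2 / 3)``
    for ``0 < eps < 1``.  The bound is reported as-is even when vacuous
    (> 1).
    """
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must be in (0, 1), got {eps}")
    return 2.0 * math.exp(-s * set_size * eps * eps / 3.0)


def cosine_error_envelope(
    profile: OverlapProfile, s: float, eps: float
) -> tuple[Optional[float], float]:
    """Relative error bound and guarantee probability for a sketch cosine.

    Returns ``(bound_factor, guarantee_prob)`` where the sketch cosine
    satisfies ``|cos' - cos| <= bound_factor * cos`` with probability at
    least ``guarantee_prob``:

    - ``bound_factor = eps * (1 + xi)``,
    - ``guarantee_prob = max(0, 1 - 6 exp(-s min(m, n) eps^2 / 3))``.

    When the sets are disjoint (``q = 0``) the proportional bound is
    unbounded and ``bound_factor`` is None: both the true and the sketch
    cosine are then near zero, but no *relative* guarantee exists.
    """
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must be in (0, 1), got {eps}")
    guarantee = max(
        0.0, 1.0 - 6.0 * math.exp(-s * profile.min_size * eps * eps / 3.0)
    )
    if profile.xi is None:
        return None, guarantee
    return eps * (1.0 + profile.xi), guarantee


def recommend_scale(
    alpha: float,
    delta: float,
    c: float = DEFAULT_XI_BOUND,
    min_size: int = 1,
) -> ScalePlan:
    """Smallest scale factor keeping the cosine estimate within ``delta``.

    Guarantees, with probability at least ``alpha``, that the sketch cosine
    lies within a factor ``1 +/- delta`` of the true cosine, provided the
    overlap inflation ``xi`` is at most ``c``::

        s = 3 (1 + c)^2 ln(6 / (1 - alpha)) / (delta^2 min(m, n))

    capped at 1.  Larger sets admit smaller scale factors; tighter error or
    higher confidence demand larger ones.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha (confidence) must be in [0, 1), got {alpha}")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta (tolerable error) must be in (0, 1), got {delta}")
    if c <= 0.0:
        raise ValueError(f"c (xi bound) must be positive, got {c}")
    if min_size < 1:
        raise ValueError(f"min_size must be a positive integer, got {min_size}")
    s_raw = (
        3.0 * (1.0 + c) ** 2 * math.log(6.0 / (1.0 - alpha)) / (delta**2 * min_size)
    )
    return ScalePlan(
        alpha=alpha,
        delta=delta,
        c=c,
        min_size=min_size,
        s_raw=s_raw,
        s=min(s_raw, 1.0),
    )


def scale_table(
    alphas: Sequence[float],
    deltas: Sequence[float],
    c: float = DEFAULT_XI_BOUND,
    min_size: int = 10_000,
) -> list[list[float]]:
    """Grid of recommended scale factors (rows: deltas, columns: alphas),
    rounded to 4 decimals as printed in planning tables."""
    return [
        [recommend_scale(a, d, c, min_size).s_rounded for a in alphas]
        for d in deltas
    ]
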