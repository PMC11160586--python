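"""Coverage experiments for sketch-based cosine estimation.

The experiment draws two random subsets ``A`` and ``B`` (sizes configurable,
typically 1e5 to 5e5) uniformly without replacement from a finite universe
(typically 1e6 elements), computes their exact cosine from all elements,
sketches both sets at a chosen scale factor, estimates the cosine from the
sketches, and records whether the estimate falls within a relative band
``cos(theta) * (1 +/- delta)`` around the truth.  Repeating over many
replicates yields the *coverage fraction* -- the empirical probability that
the sketch estimate is within tolerance -- which can be compared against
the confidence level ``alpha`` the scale-factor planner was asked for.

Each replicate re-seeds the hash function (the seed is drawn from the
replicate's own random stream), so the sketching randomness is independent
across replicates; with a single fixed hash, all replicates would share one
realisation of the sketch process and the coverage fraction would not
estimate a probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Union

import numpy as np

from .similarity import set_cosine, sketch_cosine
from .sketch import sketch_element_set
from .theory import DEFAULT_XI_BOUND, recommend_scale

__all__ = [
    "RECOMMENDED",
    "SimulationSpec",
    "ReplicateOutcome",
    "SimulationResult",
    "run_replicate",
    "run_simulation",
]

#: Sentinel for ``SimulationSpec.scale``: use the planner's recommendation.
RECOMMENDED = "recommended"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one coverage experiment.

    ``scale`` is either a number in (0, 1] or the string ``"recommended"``,
    in which case the minimum safe scale for (``alpha``, ``delta``, ``c``,
    ``min(size_a, size_b)``) is computed and used.
    """

    universe_size: int = 1_000_000
    size_a: int = 100_000
    size_b: int = 100_000
    scale: Union[float, str] = RECOMMENDED
    delta: float = 0.05
    alpha: float = 0.95
    c: float = DEFAULT_XI_BOUND
    replicates: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")
        for label, size in (("size_a", self.size_a), ("size_b", self.size_b)):
            if not 1 <= size <= self.universe_size:
                raise ValueError(
                    f"{label}={size} must be in [1, universe_size={self.universe_size}]"
                )
        if isinstance(self.scale, str):
            if self.scale != RECOMMENDED:
                raise ValueError(
                    f"scale must be a number in (0, 1] or {RECOMMENDED!r}"
                )
        elif not 0.0 < self.scale <= 1.0:
            raise ValueError(f"scale={self.scale} must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")

    @property
    def resolved_scale(self) -> float:
        """The numeric scale factor actually used for sketching."""
        if self.scale == RECOMMENDED:
            return recommend_scale(
                self.alpha, self.delta, self.c, min(self.size_a, self.size_b)
            ).s
        return float(self.scale)


class ReplicateOutcome(NamedTuple):
    true_cosine: float
    estimated_cosine: float
    within: bool


@dataclass(frozen=True)
class SimulationResult:
    """Aggregated outcome of a coverage experiment."""

    spec: SimulationSpec
    per_replicate: List[ReplicateOutcome]

    @property
    def fraction_within(self) -> float:
        """Fraction of replicates whose estimate fell inside the band."""
        return sum(r.within for r in self.per_replicate) / len(self.per_replicate)

    def to_dict(self) -> dict:
        spec = self.spec
        return {
            "spec": {
                "universe_size": spec.universe_size,
                "size_a": spec.size_a,
                "size_b": spec.size_b,
                "scale": spec.scale,
                "resolved_scale": spec.resolved_scale,
                "delta": spec.delta,
                "alpha": spec.alpha,
                "c": spec.c,
                "replicates": spec.replicates,
                "master_seed": spec.master_seed,
            },
            "fraction_within": self.fraction_within,
            "per_replicate": [
                {"true_cosine": r.true_cosine, "estimated_cosine": r.estimated_cosine,
                 "within": bool(r.within)}
                for r in self.per_replicate
            ],
        }


def _replicate_rng(spec: SimulationSpec, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, replicate_index])
    )


def run_replicate(spec: SimulationSpec, replicate_index: int) -> ReplicateOutcome:
    """Run one draw of the coverage experiment.

    ``A`` and ``B`` are sampled independently and uniformly without
    replacement, so their overlap is hypergeometric (mean
    ``size_a * size_b / universe_size``).  The tolerance check uses the
    relative band ``|est - true| <= delta * true`` (non-strict at the edge).
    """
    rng = _replicate_rng(spec, replicate_index)
    replicate_seed = int(rng.integers(2**31))
    a = rng.choice(spec.universe_size, spec.size_a, replace=False).astype(np.uint64)
    b = rng.choice(spec.universe_size, spec.size_b, replace=False).astype(np.uint64)
    true_cos = set_cosine(a, b)
    scale = spec.resolved_scale
    sk_a = sketch_element_set(a, scale, replicate_seed)
    sk_b = sketch_element_set(b, scale, replicate_seed)
    est = sketch_cosine(sk_a, sk_b).value
    within = abs(est - true_cos) <= spec.delta * true_cos
    return ReplicateOutcome(true_cosine=true_cos, estimated_cosine=est, within=within)


def run_simulation(spec: SimulationSpec) -> SimulationResult:
    """Run all replicates of a coverage experiment.

    Fully reproducible: the per-replicate random streams are derived from
    ``(master_seed, replicate_index)``, so identical specs give bitwise
    identical results regardless of execution order.
    """
    outcomes = [run_replicate(spec, i) for i in range(spec.replicates)]
    return SimulationResult(spec=spec, per_replicate=outcomes)
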