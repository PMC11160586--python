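# Methods

## Model

A FracMinHash sketch of a set `A ⊆ Ω` under a hash `h: Ω → [0, H]`
(`H = 2⁶⁴ − 1`) and scale factor `s ∈ [0, 1]` is
`FRAC_s(A) = { h(a) : a ∈ A, h(a) ≤ H·s }`. Treating `h` as a uniform random
map, each element survives independently with probability `s`, so the sketch
size is Binomial(|A|, s). All downstream guarantees are consequences of a
Chernoff bound on that binomial:

- `E[|FRAC_s(A)|] = s·|A|`;
- `Pr[ | |FRAC_s(A)| − s|A| | ≥ ε·s|A| ] ≤ 2·exp(−s|A|ε²/3)` for `0 < ε < 1`;
- for two sets with `|A| = m`, `|B| = n`, `|A∩B| = q`, the sketch cosine
  satisfies `|cosθ′ − cosθ| ≤ ε(1 + ξ)·cosθ` with probability at least
  `1 − 6·exp(−s·min(m,n)·ε²/3)`, where `ξ = 3(m + n − 2q)/q`. The factor 6
  comes from a union bound over three norm-concentration events
  (`‖u′‖², ‖v′‖², ‖u′−v′‖²`); the `(1+ξ)` factor from expressing
  `‖u−v‖²/(‖u‖‖v‖)` in cardinalities.

The cosine of sets is computed entirely from cardinalities
(`|A∩B|/√(|A||B|)`); presence/absence vectors over the `4^k` k-mer universe
are never materialised (the test suite uses explicit small vectors as an
oracle). When either set or sketch is empty the cosine is defined as 0: the
zero vector has no direction, and 0 is the limit as the overlap vanishes.
When `q = 0`, `ξ` is undefined and the error envelope is reported as a
distinguished "no proportional guarantee" result (`bound_factor = None`)
rather than an exception — both cosines are then near zero, but not
provably proportionally close.

## Scale-factor planner

Requiring the guarantee probability to reach a confidence `α` and the
relative error to stay within a user-facing tolerance `δ`, with the overlap
inflation bounded as `ξ ≤ c`, the substitution `δ = ε(1 + c)` yields the
minimum safe scale

`s = 3(1 + c)²·ln[6/(1 − α)] / (δ²·min(m, n))`, capped at 1.

Parameters and defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| `α` | confidence that the estimate is within tolerance | 0.95 | `[0, 1)` |
| `δ` | tolerable relative cosine error | 0.05 | `(0, 1)` |
| `c` | assumed bound on ξ | 0.5 | equivalent to `q ≥ (m+n)/(2+c/3)` ≈ 46% of `m+n` |
| `min(m, n)` | smaller distinct-k-mer count | — | user-supplied |

The cap at 1 matters for small sets: below ~10⁴ elements at `δ = 5%` the
formula exceeds 1 and no subsampling is safe. `ScalePlan` reports both the
raw and the capped value. When the raw value is not capped, plugging `s`
back into the envelope with `ε = δ/(1+c)` recovers the guarantee
probability `α` exactly (a property test asserts this); when capped, the
achieved guarantee falls short of `α` by construction.

## Hashing

k-mers are hashed with MurmurHash3 x64_128 (lower 64 bits of the digest)
applied to the bytes of the canonical k-mer — the lexicographic minimum of
the window and its reverse complement — at seed 42. This is the sourmash
convention, making sketches bit-compatible with the wider ecosystem. The
implementation is in-package: a general pure-Python routine (k-mers are
hashed during file sketching, where I/O dominates) and a numpy-vectorised
specialisation for 8-byte inputs used to hash millions of abstract integers
in simulation. Both are cross-checked against each other and against
published reference vectors of the algorithm; uniformity is checked by a
Kolmogorov–Smirnov test (distance < 0.02 over 10⁵ hashes).

Windows containing characters outside `{A, C, G, T}` (N, ambiguity codes)
are skipped, not fatal; lowercase is uppercased first. Abundances are not
tracked (presence/absence semantics).

Threshold convention: retention is `h ≤ floor(H·s)`. sourmash itself uses a
strict inequality against `max_hash = 2⁶⁴/scaled`; at 64-bit resolution the
conventions can disagree on at most a single boundary hash value, which is
immaterial in practice. `scale = 0` retains nothing.

Signature files use the sourmash JSON layout (`mins`, `max_hash`, `ksize`,
`seed`, hash-function tag `0.murmur64`) plus an integer `scaled =
round(1/s)`. Scale factors whose reciprocal is not an integer (e.g. the
planner's 0.1293) cannot be represented by `scaled` alone, so an exact
`scale` field is written alongside (with a warning); the reader prefers
`scale`, then `scaled`, then `max_hash`, so round-trips are exact for every
scale while sourmash-produced files still load.

## Simulation design

The coverage experiment draws `A` and `B` independently and uniformly
without replacement from a universe of 10⁶ abstract elements (defaults:
|A| = |B| = 10⁵, δ = 0.05, α = 0.95, c = 0.5, 1000 replicates). The overlap
is therefore hypergeometric with mean `|A||B|/N` (≈ 10⁴, true cosine
≈ 0.1); no overlap control is applied. Each replicate:

1. draws `A`, `B` from a stream seeded by `(master_seed, replicate_index)`;
2. computes the exact cosine from all elements;
3. draws a fresh 31-bit hash seed from the same stream and sketches both
   sets with it (re-seeding per replicate makes the sketching randomness
   independent across replicates — with one fixed hash, all replicates
   would share a single realisation of the retention pattern and the
   coverage fraction would not estimate a probability);
4. records whether `|est − true| ≤ δ·true` (non-strict at the band edge).

The `fraction_within` over replicates is the empirical coverage, to be
compared with `α` when sketching at the planner's recommendation.

What the generator emulates — and does not. Abstract integer elements stand
in for distinct k-mers; this captures exactly the randomness the theory is
about (which elements survive sketching) and nothing else. Real sequence
data adds k-mer composition bias, sequencing errors (which inflate
singleton k-mers), and strand canonicalisation — none of which affect the
theory's validity for the *distinct k-mer sets* actually compared, but
passing simulations say nothing about, e.g., how error-containing reads
should be filtered upstream. A sequence-level end-to-end check (two
synthetic genomes at 1% divergence, k = 21) covers the k-mer path itself.

## Numerical choices

- Sketch intersections are exact integer counts on sorted uint64 arrays.
- Hash collisions (two elements, one 64-bit value) are ignored; at the
  simulated universe sizes (≤ 10⁶) a collision is a ~5·10⁻⁸ event per pair.
- Planner values are reported both at full precision and rounded to 4
  decimals (the resolution of the published planning tables).
- Comparing sketches with mismatched k, scale or seed raises an error
  rather than returning a number.
- The Chernoff tail is reported as-is even when vacuous (> 1); property
  tests clip it at 1 before adding sampling slack.

## Problem sizes used in validation

The test suite runs the 100K/100K coverage experiments at the full 1000
replicates and the ≥ 200K cells at 100 replicates each (those coverages are
≈ 1, so 100 replicates bound them away from 0.97 comfortably); concentration
property tests use 150–500 hash seeds per configuration. The acceptance
script runs both headline coverage experiments at 1000 replicates.

## Known limitations

- The coverage fraction at the preset scale 1/1000 for 100K/100K sets is
  measured at ≈ 0.13–0.14 (confirmed independently by a hash-free
  binomial-thinning model of the same protocol); published figures for this
  specific configuration are somewhat lower, which is consistent with the
  sampling noise visible in such tables (symmetric cells printed with
  asymmetric values) rather than with a protocol difference we could
  identify.
- Jaccard/containment estimators, abundance-weighted cosine, protein
  k-mers, and multi-k signature files are out of scope.
- The sketcher is a streaming pure-Python implementation built for
  correctness; it is not engineered for multi-gigabyte FASTQ throughput.
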