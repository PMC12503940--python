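"""Lempel-Ziv complexity of encoded phenotypes and the transition-probability bound.

Phenotypes are represented as finite-alphabet strings.  Complexity is
estimated with the Lempel-Ziv 1976 exhaustive-history word count ``W``:

    C_LZ(x) = log2(n)                       if x is uniform (or n == 1)
    C_LZ(x) = log2(n) * (W(x) + W(x[::-1])) / 2   otherwise

where n = len(x).  Averaging the forward and reversed parsings smooths the
small asymmetry of the LZ76 parse; the uniform-string base case keeps
trivial strings at the minimum of the scale.

Raw C_LZ values overestimate description length for short strings, so they
are affinely rescaled to an approximate Kolmogorov complexity ``K~`` in
bits,

    K~(x) = log2(N) * (C_LZ(x) - c_min) / (c_max - c_min),

with N the number of phenotypes (or accessible phenotypes in the
conditional case) and c_min/c_max the extremes of C_LZ over that set, so
that 0 <= K~ <= log2(N) on the set itself.

Conditional complexity is estimated by K~(y|x) = K~(xy) - K~(x): the extra
description length needed for y when x is available.  The central bound is

    P(x -> y) <= 2^(-a*K~(y|x) - b),

with defaults a = 1, b = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EncodedPattern",
    "ScalingParams",
    "lz76_word_count",
    "lz_raw",
    "scale_complexity",
    "conditional_raw",
    "bound_probability",
    "map_complexity_estimate",
    "COMPLEXITY_TOL",
]

#: two scaled complexities are treated as equal if they differ by less than this
COMPLEXITY_TOL = 1e-9


@dataclass(frozen=True)
class EncodedPattern:
    """A phenotype encoded as a string over a finite alphabet."""

    symbols: str
    alphabet_size: int

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("encoded pattern must be non-empty")
        if self.alphabet_size < 1:
            raise ValueError("alphabet size must be positive")
        if len(set(self.symbols)) > self.alphabet_size:
            raise ValueError(
                f"pattern uses {len(set(self.symbols))} symbols but declares "
                f"an alphabet of size {self.alphabet_size}"
            )

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the affine complexity rescaling.

    n_phenotypes is N (or Ny(x) for conditional complexities); c_min and
    c_max are the extremes of the raw C_LZ values over that phenotype set;
    a and b are the bound constants (defaults a=1, b=0).
    """

    n_phenotypes: float
    c_min: float
    c_max: float
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.n_phenotypes < 2:
            raise ValueError("need at least two phenotypes for a meaningful scale")
        if not self.c_max > self.c_min:
            raise ValueError("degenerate scaling: c_max must exceed c_min")
        if not self.a > 0:
            raise ValueError("bound constant a must be positive")


def _symbols(pattern: EncodedPattern | str) -> str:
    return pattern.symbols if isinstance(pattern, EncodedPattern) else pattern


def lz76_word_count(s: str) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``s``.

    Iterative Kaspar-Schuster formulation of the Lempel-Ziv 1976
    production complexity; the final word is counted even when it is
    reproducible from the preceding history (incomplete word).
    """
    n = len(s)
    if n == 0:
        raise ValueError("cannot parse an empty string")
    if n == 1:
        return 1
    c = 1  # words found so far
    l = 1  # start of the current word
    i = 0  # candidate copy source
    k = 1  # current match length
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz_raw(pattern: EncodedPattern | str) -> float:
    """Raw Lempel-Ziv complexity C_LZ of an encoded phenotype."""
    s = _symbols(pattern)
    n = len(s)
    if n == 0:
        raise ValueError("invalid pattern: empty string")
    if n == 1 or s == s[0] * n:
        return math.log2(n) if n > 1 else 0.0
    return math.log2(n) * (lz76_word_count(s) + lz76_word_count(s[::-1])) / 2.0


def scale_complexity(raw: float, params: ScalingParams) -> float:
    """Affine rescaling of a raw complexity to K~ in bits.

    raw = c_min maps to 0 and raw = c_max to log2(N).  Values outside
    [c_min, c_max] extrapolate linearly: mutant phenotypes may fall
    outside the min/max computed over a finite accessible set.
    """
    span = params.c_max - params.c_min
    return math.log2(params.n_phenotypes) * (raw - params.c_min) / span


def conditional_raw(
    x: EncodedPattern | str, y: EncodedPattern | str
) -> float:
    """Raw conditional complexity of y given x, C_LZ(xy) - C_LZ(x).

    Floored at zero: concatenation can parse into marginally fewer words
    than x alone, and the bound needs a non-negative exponent.
    """
    if isinstance(x, EncodedPattern) and isinstance(y, EncodedPattern):
        if x.alphabet_size != y.alphabet_size:
            raise ValueError(
                "conditional complexity requires patterns over a shared alphabet"
            )
    sx, sy = _symbols(x), _symbols(y)
    return max(0.0, lz_raw(sx + sy) - lz_raw(sx))


def bound_probability(k_cond: float, a: float = 1.0, b: float = 0.0) -> float:
    """Upper bound 2^(-a*k_cond - b) on P(x->y), clipped to at most 1."""
    if not math.isfinite(k_cond):
        raise ValueError("conditional complexity must be finite")
    return min(1.0, 2.0 ** (-a * k_cond - b))


def map_complexity_estimate(
    n_genotypes: float, n_phenotypes: float, genotype_length: int
) -> tuple[float, float]:
    """Information content of a random map vs. the matrix map (diagnostic).

    A purely random assignment of n_g genotypes to n_p phenotypes costs
    roughly n_g*log2(n_p) bits; a matrix map over length-L genotypes is
    described by its L^2 entries.  Returns (random_map_bits, matrix_map_bits).
    """
    if n_genotypes <= 0 or n_phenotypes <= 0 or genotype_length <= 0:
        raise ValueError("counts must be positive")
    return (n_genotypes * math.log2(n_phenotypes), float(genotype_length**2))
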