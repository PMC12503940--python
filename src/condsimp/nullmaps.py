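"""Synthetic transition generators with known, tunable simplicity bias.

These emulate the statistical structure the bound assumes — transition
probabilities decaying as 2^(-alpha*K~(y|x)) over a fixed phenotype
universe — so the assessment statistics can be validated by parameter
recovery: at alpha = 0 transitions are uniform (the Level I screen should
fire at its nominal false-positive rate), and at alpha = 1 the fitted
upper-bound slope should recover -log10(2) per bit and Level III should
pass.  A small exhaustively enumerable toy map exercises the genotype
path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional

import numpy as np
import pandas as pd

from .complexity import (
    COMPLEXITY_TOL,
    EncodedPattern,
    ScalingParams,
    conditional_raw,
    scale_complexity,
)
from .gpmaps.base import Genotype, MapContract
from .transitions import TransitionTable

__all__ = [
    "NullTransitionModel",
    "make_phenotype_universe",
    "null_transition_probabilities",
    "sample_null_transitions",
    "ToyMap",
    "toy_enumerable_map",
]


def make_phenotype_universe(n_phen: int, length: int, seed: int) -> list[str]:
    """Distinct random binary strings, always including the all-zero string."""
    if n_phen > 2**length:
        raise ValueError(f"cannot draw {n_phen} distinct strings of length {length}")
    rng = np.random.default_rng(seed)
    universe = {"0" * length}
    while len(universe) < n_phen:
        bits = rng.integers(0, 2, size=length)
        universe.add("".join("01"[b] for b in bits))
    return sorted(universe)


@dataclass(frozen=True)
class NullTransitionModel:
    """Null model: P(y) proportional to 2^(-alpha*K~(y|x)) over a universe."""

    universe: tuple[str, ...]
    alpha: float
    x: str
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.x not in self.universe:
            raise ValueError("focal phenotype must belong to the universe")
        if self.n < 1:
            raise ValueError("sample size must be positive")


def _scaled_conditionals(
    x: str, universe: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    xp = EncodedPattern(x, 2)
    raw = np.array([conditional_raw(xp, EncodedPattern(y, 2)) for y in universe])
    c_min, c_max = float(raw.min()), float(raw.max())
    if c_max - c_min <= COMPLEXITY_TOL:
        raise ValueError("universe has no complexity spread")
    params = ScalingParams(n_phenotypes=len(universe), c_min=c_min, c_max=c_max)
    scaled = np.array([scale_complexity(r, params) for r in raw])
    return raw, scaled, c_min, c_max


def null_transition_probabilities(model: NullTransitionModel) -> np.ndarray:
    """Analytic multinomial cell probabilities of the null model."""
    _, scaled, _, _ = _scaled_conditionals(model.x, model.universe)
    logw = -model.alpha * scaled * np.log(2.0)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def sample_null_transitions(model: NullTransitionModel) -> TransitionTable:
    """Draw n outcomes from the null model and package them as a
    TransitionTable shaped exactly like the real pipeline's output.

    Conditional complexities in the table are re-scaled over the
    *observed* accessible set, matching the estimation pipeline.
    """
    probs = null_transition_probabilities(model)
    rng = np.random.default_rng(model.seed)
    counts = rng.multinomial(model.n, probs)
    observed = np.flatnonzero(counts)
    obs_phenos = [model.universe[i] for i in observed]
    xp = EncodedPattern(model.x, 2)
    raw = np.array(
        [conditional_raw(xp, EncodedPattern(y, 2)) for y in obs_phenos]
    )
    ny = len(obs_phenos)
    c_min, c_max = float(raw.min()), float(raw.max())
    degenerate = ny < 2 or (c_max - c_min) <= COMPLEXITY_TOL
    if degenerate:
        scaled = np.full(ny, np.nan)
    else:
        params = ScalingParams(n_phenotypes=ny, c_min=c_min, c_max=c_max)
        scaled = np.array([scale_complexity(r, params) for r in raw])
    rows = pd.DataFrame(
        {
            "y": obs_phenos,
            "count": counts[observed],
            "probability": counts[observed] / model.n,
            "raw_cond": raw,
            "scaled_cond": scaled,
        }
    )
    return TransitionTable(
        x=model.x,
        x_encoded=model.x,
        rows=rows,
        total_mutants=model.n,
        n_neutral=1,
        ny=ny,
        c_min=c_min,
        c_max=c_max,
        degenerate_scaling=bool(degenerate),
    )


class ToyMap(MapContract):
    """Hand-enumerable 6-bit map: phenotype = run-length-quantized genotype.

    Each maximal run of identical bits is replaced by its symbol once
    (run length 1) or twice (run length >= 2), e.g. 001110 -> 00 11 0.
    64 genotypes, deterministic, many-to-one — small enough that the full
    transition structure can be verified by brute force.
    """

    def __init__(self, L: int = 6):
        self.genotype_length = L
        self.alphabet_sizes = (2,) * L

    def phenotype(self, g: Genotype) -> str:
        s = "".join("01"[b] for b in g.positions)
        out = []
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            out.append(s[i] * min(2, j - i))
            i = j
        return "".join(out)

    def encode(self, phenotype: Hashable) -> EncodedPattern:
        return EncodedPattern(str(phenotype), alphabet_size=2)


def toy_enumerable_map() -> ToyMap:
    return ToyMap()
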