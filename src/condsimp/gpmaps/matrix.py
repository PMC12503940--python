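"""Vector-matrix multiplication map: an abstract gene-regulation model.

A binary genotype g of length L is mapped to a binary phenotype
x = H(D.g), where D is an L x L matrix with entries drawn uniformly from
{-1, 0, 1} (promotion / no interaction / suppression) and H is the
component-wise Heaviside step: positive entries of D.g become 1,
everything else 0.
"""

from __future__ import annotations

from typing import Hashable, Optional, Sequence

import numpy as np

from ..complexity import EncodedPattern
from .base import Genotype, MapContract

__all__ = ["make_interaction_matrix", "matrix_map", "MatrixMap"]


def make_interaction_matrix(L: int, seed: int) -> np.ndarray:
    """L x L interaction matrix with i.i.d. uniform entries in {-1, 0, 1}."""
    if L < 1:
        raise ValueError("matrix size must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.integers(-1, 2, size=(L, L))


def matrix_map(g: Genotype | Sequence[int], D: np.ndarray) -> str:
    """Phenotype H(D.g) as a binary string of length L."""
    vec = np.asarray(g.positions if isinstance(g, Genotype) else g, dtype=int)
    if D.shape != (len(vec), len(vec)):
        raise ValueError(f"matrix shape {D.shape} does not match genotype length {len(vec)}")
    out = (D @ vec) > 0
    return "".join("1" if b else "0" for b in out)


class MatrixMap(MapContract):
    def __init__(self, L: int = 15, seed: int = 0, D: np.ndarray | None = None):
        self.D = make_interaction_matrix(L, seed) if D is None else np.asarray(D)
        if self.D.shape != (L, L):
            raise ValueError("matrix shape does not match L")
        self.genotype_length = L
        self.alphabet_sizes = (2,) * L

    def phenotype(self, g: Genotype) -> str:
        return matrix_map(g, self.D)

    def phenotype_batch(self, genotypes: Sequence[Genotype]) -> list[Optional[Hashable]]:
        if not genotypes:
            return []
        G = np.asarray([g.positions for g in genotypes], dtype=int)
        out = ((G @ self.D.T) > 0).astype(int)
        return ["".join("01"[b] for b in row) for row in out]

    def encode(self, phenotype: Hashable) -> EncodedPattern:
        return EncodedPattern(str(phenotype), alphabet_size=2)
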