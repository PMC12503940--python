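"""Uniform contract shared by the genotype-phenotype map simulators."""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np

from ..complexity import EncodedPattern

__all__ = ["Genotype", "MapContract", "DISCARDED"]

#: reserved phenotype key for discarded outcomes (non-deterministic
#: polyomino assemblies, degenerate HP folds); carries no encoded pattern
DISCARDED = "__discarded__"


@dataclass(frozen=True)
class Genotype:
    """Fixed-length sequence of integer symbols with per-position alphabets."""

    positions: tuple[int, ...]
    alphabet_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.alphabet_sizes):
            raise ValueError("positions and alphabet_sizes lengths differ")
        for i, (p, a) in enumerate(zip(self.positions, self.alphabet_sizes)):
            if a < 1 or not (0 <= p < a):
                raise ValueError(f"symbol {p} at position {i} outside alphabet [0, {a})")

    def __len__(self) -> int:
        return len(self.positions)


class MapContract(ABC):
    """A deterministic genotype-phenotype map.

    ``phenotype`` returns a hashable canonical phenotype key, or ``None``
    for discarded outcomes.  ``encode`` turns a phenotype key into the
    string pattern whose complexity is measured.  The same genotype always
    yields the same phenotype.
    """

    genotype_length: int
    alphabet_sizes: tuple[int, ...]

    @abstractmethod
    def phenotype(self, g: Genotype) -> Optional[Hashable]:
        ...

    @abstractmethod
    def encode(self, phenotype: Hashable) -> EncodedPattern:
        ...

    def phenotype_batch(self, genotypes: Sequence[Genotype]) -> list[Optional[Hashable]]:
        """Map a batch of genotypes; subclasses may vectorize."""
        return [self.phenotype(g) for g in genotypes]

    def random_genotype(self, rng: np.random.Generator) -> Genotype:
        positions = tuple(int(rng.integers(0, a)) for a in self.alphabet_sizes)
        return Genotype(positions, self.alphabet_sizes)

    def random_genotypes(self, n: int, rng: np.random.Generator) -> list[Genotype]:
        sizes = np.asarray(self.alphabet_sizes)
        draws = rng.integers(0, sizes[None, :], size=(n, len(sizes)))
        return [Genotype(tuple(int(v) for v in row), self.alphabet_sizes) for row in draws]


def read_genotypes(path, alphabet_sizes: tuple[int, ...]) -> list[Genotype]:
    """Read genotypes from a text file, one per line, comma-separated ints."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            positions = tuple(int(v) for v in line.split(","))
            out.append(Genotype(positions, alphabet_sizes))
    return out
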