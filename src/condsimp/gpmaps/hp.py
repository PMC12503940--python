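"""Two-dimensional hydrophobic/polar (HP) lattice protein map.

A genotype is a string over {H, P}; the phenotype is the unique
minimum-energy self-avoiding walk (SAW) of the chain on the square
lattice, represented as a string of step directions U/D/R/L.  The energy
of a conformation is minus the number of H-H pairs that are adjacent on
the lattice but not adjacent along the chain.  If two or more distinct
conformations (up to lattice symmetry) attain the minimum energy, the
sequence has no stable structure and is discarded.

SAWs are enumerated once per chain length, reduced to one canonical
representative per symmetry class (the lexicographically smallest UDRL
string over the 8 rotations/reflections; the chain is never reversed, as
it has an N-to-C orientation), and stored with their precomputed contact
pair lists.  An optional compact mode restricts candidate conformations
to those filling a maximally compact rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np

from ..complexity import EncodedPattern
from .base import Genotype, MapContract

__all__ = ["FoldResult", "SawIndex", "enumerate_saws", "hp_fold", "HPMap"]

_STEPS = {"U": (0, 1), "D": (0, -1), "R": (1, 0), "L": (-1, 0)}

# the 8 lattice symmetries as permutations of the direction alphabet
_SYMMETRY_MAPS = []
for _rot in range(4):
    for _ref in (False, True):
        m = {}
        for d, (dx, dy) in _STEPS.items():
            if _ref:
                dx = -dx
            for _ in range(_rot):
                dx, dy = -dy, dx
            m[d] = next(k for k, v in _STEPS.items() if v == (dx, dy))
        _SYMMETRY_MAPS.append(m)


def canonical_walk(walk: str) -> str:
    """Lexicographically smallest image of a UDRL walk under the 8 symmetries."""
    return min("".join(m[c] for c in walk) for m in _SYMMETRY_MAPS)


def _walk_sites(walk: str) -> list[tuple[int, int]]:
    x, y = 0, 0
    sites = [(0, 0)]
    for c in walk:
        dx, dy = _STEPS[c]
        x, y = x + dx, y + dy
        sites.append((x, y))
    return sites


def _contacts(walk: str) -> list[tuple[int, int]]:
    """Chain-non-adjacent lattice-contact monomer pairs of a walk."""
    sites = _walk_sites(walk)
    index = {s: i for i, s in enumerate(sites)}
    pairs = []
    for i, (x, y) in enumerate(sites):
        for dx, dy in ((0, 1), (1, 0)):
            j = index.get((x + dx, y + dy))
            if j is not None and abs(i - j) > 1:
                pairs.append((min(i, j), max(i, j)))
    return sorted(set(pairs))


@dataclass(frozen=True)
class SawIndex:
    """Canonical SAWs of a given chain length with contact lists."""

    length: int  # number of monomers
    walks: tuple[str, ...]
    contacts: tuple[tuple[tuple[int, int], ...], ...]
    compact: bool = False


@dataclass(frozen=True)
class FoldResult:
    """Outcome of folding: a UDRL direction string, or degenerate."""

    directions: Optional[str]
    energy: int

    @property
    def degenerate(self) -> bool:
        return self.directions is None


def enumerate_saws(L: int, compact: bool = False, max_walks: int = 20_000_000) -> SawIndex:
    """Canonical self-avoiding walks for an L-monomer chain.

    Walks are generated with the first step fixed (every symmetry class
    has such a representative), canonicalized and deduplicated.  Raises if
    the walk count would exceed ``max_walks`` (reduce L).
    """
    if L < 2:
        raise ValueError("chain needs at least 2 monomers")
    if 4 * 3 ** max(0, L - 3) > max_walks:
        raise ValueError(
            f"enumerating SAWs for L={L} exceeds the configured budget; reduce L"
        )
    canon: set[str] = set()
    # iterative DFS; first step fixed to 'R'
    stack = [("R", [(0, 0), (1, 0)])]
    while stack:
        walk, sites = stack.pop()
        if len(sites) == L:
            canon.add(canonical_walk(walk))
            continue
        x, y = sites[-1]
        occupied = set(sites)
        for d, (dx, dy) in _STEPS.items():
            nxt = (x + dx, y + dy)
            if nxt not in occupied:
                stack.append((walk + d, sites + [nxt]))
    walks = sorted(canon)
    if compact:
        walks = [w for w in walks if _is_compact(w, L)]
    return SawIndex(
        length=L,
        walks=tuple(walks),
        contacts=tuple(tuple(_contacts(w)) for w in walks),
        compact=compact,
    )


def _is_compact(walk: str, L: int) -> bool:
    """True if the walk fills a minimal-area bounding rectangle."""
    sites = _walk_sites(walk)
    xs = [s[0] for s in sites]
    ys = [s[1] for s in sites]
    area = (max(xs) - min(xs) + 1) * (max(ys) - min(ys) + 1)
    return area == L


def hp_fold(seq: str, saw_index: SawIndex) -> FoldResult:
    """Fold an H/P sequence to its unique minimum-energy conformation."""
    seq = seq.upper()
    if set(seq) - {"H", "P"}:
        raise ValueError(f"sequence contains symbols other than H/P: {seq!r}")
    if len(seq) != saw_index.length:
        raise ValueError("sequence length does not match the SAW index")
    is_h = [c == "H" for c in seq]
    best_e = 1
    best_walk: Optional[str] = None
    n_best = 0
    for walk, pairs in zip(saw_index.walks, saw_index.contacts):
        e = -sum(1 for i, j in pairs if is_h[i] and is_h[j])
        if e < best_e:
            best_e, best_walk, n_best = e, walk, 1
        elif e == best_e:
            n_best += 1
    if n_best != 1:
        return FoldResult(directions=None, energy=best_e)
    return FoldResult(directions=best_walk, energy=best_e)


class HPMap(MapContract):
    """HP map as a MapContract; genotype symbol 0 = H, 1 = P."""

    def __init__(self, L: int = 25, compact: bool = False, saw_index: SawIndex | None = None):
        self.genotype_length = L
        self.alphabet_sizes = (2,) * L
        self.saw_index = saw_index if saw_index is not None else enumerate_saws(L, compact=compact)
        # flattened contact arrays over all walks for vectorized folding
        lengths = [len(ps) for ps in self.saw_index.contacts]
        self._offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1].astype(np.int64)
        flat = [p for ps in self.saw_index.contacts for p in ps]
        self._flat_i = np.array([p[0] for p in flat], dtype=np.int64)
        self._flat_j = np.array([p[1] for p in flat], dtype=np.int64)
        self._n_pairs_total = len(flat)

    @staticmethod
    def sequence(g: Genotype) -> str:
        return "".join("HP"[b] for b in g.positions)

    def phenotype(self, g: Genotype) -> Optional[str]:
        result = hp_fold(self.sequence(g), self.saw_index)
        return result.directions

    def phenotype_batch(self, genotypes: Sequence[Genotype]) -> list[Optional[str]]:
        """Vectorized fold: contact energies for all walks at once.

        Matches the scalar path exactly (same minimum and tie rule); the
        chunking only bounds memory.
        """
        if not genotypes:
            return []
        walks = self.saw_index.walks
        n_walks = len(walks)
        out: list[Optional[str]] = []
        chunk = max(1, int(2e7 // max(1, self._n_pairs_total)))
        for start in range(0, len(genotypes), chunk):
            batch = genotypes[start : start + chunk]
            # genotype symbol 0 = H
            is_h = np.array([[b == 0 for b in g.positions] for g in batch], dtype=np.int32)
            contrib = is_h[:, self._flat_i] * is_h[:, self._flat_j]
            if self._n_pairs_total:
                energies = -np.add.reduceat(contrib, self._offsets, axis=1)
                # reduceat repeats entries for zero-length segments; mask them
                seg_len = np.diff(np.append(self._offsets, self._n_pairs_total))
                energies[:, seg_len == 0] = 0
            else:
                energies = np.zeros((len(batch), n_walks), dtype=np.int32)
            e_min = energies.min(axis=1)
            for row, e in zip(energies, e_min):
                winners = np.flatnonzero(row == e)
                out.append(walks[winners[0]] if len(winners) == 1 else None)
        return out

    def encode(self, phenotype: Hashable) -> EncodedPattern:
        return EncodedPattern(str(phenotype), alphabet_size=4)
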