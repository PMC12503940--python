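"""Polyomino self-assembly map: lattice tiles with colour-coded sticky edges.

A genotype is a 24-bit string encoding 2 tile types x 4 edges x 3 bits of
edge colour (8 colours).  Colour 0 is neutral, odd colour 2k-1 binds even
colour 2k for the three pairs (1,2), (3,4), (5,6), and the leftover
colour 7 is self-complementary (7 binds 7).  Assembly starts from a
single seed tile (type 0) and repeatedly attaches a uniformly chosen
(site, tile type, orientation) placement whose facing edge binds an open
edge, until no attachment is possible.

A genotype is kept only if every one of ``repeats`` independently ordered
assemblies terminates within the grid limit with the same oriented shape
(identified up to translation and 90-degree rotation); otherwise the
outcome is UND (non-deterministic or unbounded) and the genotype is
discarded.  The retained phenotype is the shape identified additionally
up to reflection, so a rule set and its mirror image share a phenotype.
Under these conventions the exhaustive enumeration of all 2^24 genotypes
yields 22 distinct shapes.

The assembled shape depends on the genotype only through which edges bind
which, so genotypes are reduced to a canonical interaction class (the
colour relabellings that preserve the binding pairs) and the determinism
check runs once per class, with a per-class seed stream.  This makes
exhaustive enumeration of the genotype space, and the mutant sweeps of
the transition pipeline, practical in pure Python.
"""

from __future__ import annotations

import itertools
import random
import zlib
from dataclasses import dataclass
from typing import Hashable, Iterable, Optional, Sequence

import numpy as np

from ..complexity import EncodedPattern
from .base import Genotype, MapContract

__all__ = [
    "PolyominoShape",
    "PolyominoMap",
    "polyomino_assemble",
    "site_occupation_encode",
    "perimeter_encode",
    "enumerate_polyomino_phenotypes",
]

# directions: 0=N(+y) 1=E(+x) 2=S(-y) 3=W(-x)
_DIRS = ((0, (0, 1)), (1, (1, 0)), (2, (0, -1)), (3, (-1, 0)))
_OPP = (2, 3, 0, 1)

# colour interaction table: 2k-1 binds 2k; 7 binds itself; 0 is neutral
_INTERACT = np.zeros((8, 8), dtype=bool)
for _k in (1, 3, 5):
    _INTERACT[_k, _k + 1] = _INTERACT[_k + 1, _k] = True
_INTERACT[7, 7] = True


def _relabel_tables() -> np.ndarray:
    """All 48 colour maps preserving the interaction structure.

    The three heterotypic bond pairs (1,2), (3,4), (5,6) can be permuted
    (3!) and each pair's two sides swapped (2^3); the neutral colour 0 and
    the self-complementary colour 7 are fixed.
    """
    tables = []
    pairs = ((1, 2), (3, 4), (5, 6))
    for perm in itertools.permutations(range(3)):
        for swaps in itertools.product((False, True), repeat=3):
            lut = np.zeros(8, dtype=np.uint8)
            lut[7] = 7
            for src_idx, dst_idx in enumerate(perm):
                a, b = pairs[src_idx]
                da, db = pairs[dst_idx]
                if swaps[src_idx]:
                    da, db = db, da
                lut[a], lut[b] = da, db
            tables.append(lut)
    return np.stack(tables)


_RELABEL = _relabel_tables()
_POW8 = (np.uint64(8) ** np.arange(8)).astype(np.uint64)


def canonical_interaction_key(colours: Sequence[int]) -> tuple[int, ...]:
    """Lexicographically minimal colour relabelling of an 8-edge tuple."""
    arr = np.asarray(colours, dtype=np.uint8)
    images = _RELABEL[:, arr]  # (48, 8)
    packed = images.astype(np.uint64) @ _POW8
    return tuple(int(v) for v in images[int(np.argmin(packed))])


def _canonical_keys_batch(colours: np.ndarray) -> np.ndarray:
    """Packed colour-canonical keys for an (n, 8) array of edge colours."""
    best = None
    for lut in _RELABEL:
        packed = lut[colours].astype(np.uint64) @ _POW8
        best = packed if best is None else np.minimum(best, packed)
    return best


def _unpack_key(packed: int) -> tuple[int, ...]:
    out = []
    for _ in range(8):
        out.append(int(packed % 8))
        packed //= 8
    return tuple(out)


@dataclass(frozen=True)
class PolyominoShape:
    """Canonical polyomino: occupied cells normalized to the bounding box.

    ``cells`` is the lexicographically smallest tuple over the four
    90-degree rotations of the cell set, each translated so min
    coordinates are (0, 0).  ``mirror_canonical`` additionally identifies
    the two mirror images; the map uses that as the phenotype.
    """

    cells: tuple[tuple[int, int], ...]

    @classmethod
    def from_cells(cls, cells: Iterable[tuple[int, int]]) -> "PolyominoShape":
        cset = {(int(a), int(b)) for a, b in cells}
        if not cset:
            raise ValueError("shape must contain at least one cell")
        if not _connected(cset):
            raise ValueError("shape cells must be edge-connected")
        return cls(_rot_canonical(cset))

    def mirror_canonical(self) -> "PolyominoShape":
        mirrored = _rot_canonical({(a, -b) for a, b in self.cells})
        return PolyominoShape(min(self.cells, mirrored))

    @property
    def grid(self) -> np.ndarray:
        h = max(a for a, _ in self.cells) + 1
        w = max(b for _, b in self.cells) + 1
        g = np.zeros((h, w), dtype=np.uint8)
        for a, b in self.cells:
            g[a, b] = 1
        return g

    def __len__(self) -> int:
        return len(self.cells)


def _rot_canonical(cset: set[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    best = None
    cur = cset
    for _ in range(4):
        mina = min(a for a, _ in cur)
        minb = min(b for _, b in cur)
        norm = tuple(sorted((a - mina, b - minb) for a, b in cur))
        if best is None or norm < best:
            best = norm
        cur = {(b, -a) for a, b in cur}
    return best


def _connected(cells: set[tuple[int, int]]) -> bool:
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    while stack:
        a, b = stack.pop()
        for da, db in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nb = (a + da, b + db)
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


def _assemble_once(
    colours: Sequence[int], n_tiles: int, rng: random.Random, grid_limit: int
) -> Optional[frozenset]:
    """One stochastic assembly; returns occupied cells or None if unbounded."""
    occupied = {(0, 0): (0, 0)}
    minx = maxx = miny = maxy = 0
    cand: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def recompute(pos: tuple[int, int]) -> None:
        if pos in occupied:
            cand.pop(pos, None)
            return
        lst = []
        nbs = []
        for d, (dx, dy) in _DIRS:
            tr = occupied.get((pos[0] + dx, pos[1] + dy))
            if tr is not None:
                nbs.append((d, colours[4 * tr[0] + (_OPP[d] - tr[1]) % 4]))
        if nbs:
            for t in range(n_tiles):
                base = 4 * t
                for r in range(4):
                    for d, nb_col in nbs:
                        if _INTERACT[colours[base + (d - r) % 4], nb_col]:
                            lst.append((t, r))
                            break
        if lst:
            cand[pos] = lst
        else:
            cand.pop(pos, None)

    for _, (dx, dy) in _DIRS:
        recompute((dx, dy))

    while cand:
        total = sum(len(v) for v in cand.values())
        k = rng.randrange(total)
        for pos, v in cand.items():
            if k < len(v):
                t, r = v[k]
                break
            k -= len(v)
        occupied[pos] = (t, r)
        x, y = pos
        minx, maxx = min(minx, x), max(maxx, x)
        miny, maxy = min(miny, y), max(maxy, y)
        if maxx - minx + 1 > grid_limit or maxy - miny + 1 > grid_limit:
            return None
        cand.pop(pos)
        for _, (dx, dy) in _DIRS:
            recompute((x + dx, y + dy))
    return frozenset(occupied)


def polyomino_assemble(
    g: Genotype | Sequence[int],
    n_tiles: int = 2,
    n_colours: int = 8,
    repeats: int = 20,
    grid_limit: int = 16,
    seed: int = 0,
) -> Optional[PolyominoShape]:
    """Assemble a genotype; canonical shape, or None for UND outcomes."""
    m = PolyominoMap(
        n_tiles=n_tiles, n_colours=n_colours, repeats=repeats,
        grid_limit=grid_limit, seed=seed,
    )
    if not isinstance(g, Genotype):
        g = Genotype(tuple(int(b) for b in g), (2,) * (3 * 4 * n_tiles))
    return m.phenotype(g)


class PolyominoMap(MapContract):
    def __init__(
        self,
        n_tiles: int = 2,
        n_colours: int = 8,
        repeats: int = 20,
        grid_limit: int = 16,
        seed: int = 0,
    ):
        if n_colours != 8:
            raise ValueError("only the 8-colour (3 bits/edge) encoding is supported")
        self.n_tiles = n_tiles
        self.repeats = repeats
        self.grid_limit = grid_limit
        self.seed = seed
        self.genotype_length = 3 * 4 * n_tiles
        self.alphabet_sizes = (2,) * self.genotype_length
        # packed colour-canonical interaction key -> phenotype or None
        self._cache: dict[int, Optional[PolyominoShape]] = {}

    # -- genotype decoding ------------------------------------------------
    def decode_colours(self, g: Genotype) -> tuple[int, ...]:
        bits = g.positions
        n_edges = 4 * self.n_tiles
        return tuple(
            bits[3 * e] * 4 + bits[3 * e + 1] * 2 + bits[3 * e + 2]
            for e in range(n_edges)
        )

    # -- assembly with determinism check ----------------------------------
    def _assemble_key(self, key: tuple[int, ...]) -> Optional[PolyominoShape]:
        base_seed = (zlib.crc32(bytes(key)) ^ (self.seed * 0x9E3779B1)) & 0x7FFFFFFF
        first: Optional[PolyominoShape] = None
        for rep in range(self.repeats):
            rng = random.Random(base_seed + rep)
            cells = _assemble_once(key, self.n_tiles, rng, self.grid_limit)
            if cells is None:  # unbounded growth
                return None
            shape = PolyominoShape.from_cells(cells)
            if rep == 0:
                first = shape
            elif shape != first:  # non-deterministic
                return None
        return first.mirror_canonical()

    def _phenotype_from_packed(self, packed: int) -> Optional[PolyominoShape]:
        if packed not in self._cache:
            self._cache[packed] = self._assemble_key(_unpack_key(packed))
        return self._cache[packed]

    def phenotype(self, g: Genotype) -> Optional[PolyominoShape]:
        colours = np.asarray(self.decode_colours(g), dtype=np.uint8)[None, :]
        return self._phenotype_from_packed(int(_canonical_keys_batch(colours)[0]))

    def phenotype_batch(
        self, genotypes: Sequence[Genotype]
    ) -> list[Optional[Hashable]]:
        if not genotypes:
            return []
        bits = np.asarray([g.positions for g in genotypes], dtype=np.uint8)
        colours = 4 * bits[:, 0::3] + 2 * bits[:, 1::3] + bits[:, 2::3]
        packed = _canonical_keys_batch(colours)
        return [self._phenotype_from_packed(int(p)) for p in packed]

    def encode(self, phenotype: Hashable) -> EncodedPattern:
        return site_occupation_encode(phenotype)


def site_occupation_encode(shape: PolyominoShape) -> EncodedPattern:
    """Binary encoding: bounding-box grid rows concatenated ('1' = block)."""
    g = shape.grid
    return EncodedPattern("".join("01"[v] for v in g.ravel()), alphabet_size=2)


# perimeter walk directions in (x, y) vertex space, cell kept on the right
_WALK = {"R": (1, 0), "D": (0, -1), "L": (-1, 0), "U": (0, 1)}
_RIGHT_TURN = {"R": "DRUL", "D": "LDRU", "L": "ULDR", "U": "RULD"}


def perimeter_encode(shape: PolyominoShape) -> EncodedPattern:
    """Quaternary encoding of the boundary of a polyomino.

    Every exposed unit edge is walked exactly once with the occupied cell
    kept on the right; the walk starts from the canonical top-left
    boundary vertex and emits one direction symbol (R/D/L/U) per unit
    edge.  Shapes with interior holes contribute one closed loop per hole
    after the outer loop, so the emitted length always equals the number
    of exposed unit edges.
    """
    cells = {(int(a), int(b)) for a, b in shape.cells}
    # directed exposed edges: start vertex -> list of directions
    edges: dict[tuple[int, int], list[str]] = {}

    def add(v: tuple[int, int], d: str) -> None:
        edges.setdefault(v, []).append(d)

    for a, b in cells:  # cell occupies [a,a+1]x[b,b+1] in (x, y)
        if (a, b + 1) not in cells:
            add((a, b + 1), "R")  # top edge, walked +x
        if (a + 1, b) not in cells:
            add((a + 1, b + 1), "D")  # right edge, walked -y
        if (a, b - 1) not in cells:
            add((a + 1, b), "L")  # bottom edge, walked -x
        if (a - 1, b) not in cells:
            add((a, b), "U")  # left edge, walked +y
    out: list[str] = []
    while edges:
        start = min(edges, key=lambda v: (v[0], -v[1]))
        d = sorted(edges[start], key="RDLU".index)[0]
        v = start
        incoming = None
        while True:
            if incoming is not None:
                options = edges[v]
                d = next(c for c in _RIGHT_TURN[incoming] if c in options)
            edges[v].remove(d)
            if not edges[v]:
                del edges[v]
            out.append(d)
            dx, dy = _WALK[d]
            v = (v[0] + dx, v[1] + dy)
            incoming = d
            # the start vertex is never a pinch point (it is the extreme
            # top-left corner), so first return closes the loop
            if v == start:
                break
    return EncodedPattern("".join(out), alphabet_size=4)


def enumerate_polyomino_phenotypes(
    repeats: int = 20,
    grid_limit: int = 16,
    seed: int = 0,
    gp_map: Optional["PolyominoMap"] = None,
) -> tuple[dict[Hashable, int], int]:
    """Exhaustively map all 2^24 two-tile/eight-colour genotypes.

    Enumerates the 8^8 edge colourings, reduces them to canonical
    interaction classes (colour relabellings), runs the seeded
    determinism-check assembly once per class and spreads the genotype
    multiplicities back.  Returns ({shape: genotype count}, discarded
    genotype count); counts are per 24-bit genotype, summing to 2^24.
    """
    m = gp_map if gp_map is not None else PolyominoMap(
        repeats=repeats, grid_limit=grid_limit, seed=seed
    )
    n = 8**8
    idx = np.arange(n, dtype=np.int64)
    colours = np.empty((n, 8), dtype=np.uint8)
    for e in range(8):
        colours[:, e] = (idx // (8**e)) % 8
    packed = _canonical_keys_batch(colours)
    del colours
    uniq, inv = np.unique(packed, return_inverse=True)
    mult = np.bincount(inv).astype(np.int64)
    del packed, inv
    counts: dict[Hashable, int] = {}
    discarded = 0
    for key_packed, weight in zip(uniq, mult):
        shape = m._phenotype_from_packed(int(key_packed))
        if shape is None:
            discarded += int(weight)
        else:
            counts[shape] = counts.get(shape, 0) + int(weight)
    return counts, discarded
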