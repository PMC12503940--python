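"""Neutral-set sampling, single-point-mutant enumeration and P(x->y) estimation.

The experimental protocol: sample genotypes uniformly, group them into
neutral sets by phenotype, choose focal test-case phenotypes with a
spread of complexity values, enumerate every single-point mutant of every
neutral genotype found, and count how often the focal phenotype x
transitions to each accessible phenotype y.  Each transition row carries
the raw conditional complexity C_LZ(xy) - C_LZ(x) and its rescaled value
K~(y|x), scaled with log2(Ny(x)) where Ny(x) is the number of accessible
phenotypes and with the min/max taken over the accessible set of x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd

from .complexity import (
    COMPLEXITY_TOL,
    EncodedPattern,
    ScalingParams,
    conditional_raw,
    lz_raw,
    scale_complexity,
)
from .gpmaps.base import DISCARDED, Genotype, MapContract

__all__ = [
    "PhenotypeSample",
    "TestCase",
    "TestCaseSet",
    "TransitionTable",
    "sample_phenotypes",
    "select_test_cases",
    "enumerate_mutants",
    "estimate_transitions",
]


@dataclass
class PhenotypeSample:
    """Frequency table of phenotypes from uniform genotype sampling."""

    counts: dict[Hashable, int]
    genotypes: dict[Hashable, list[Genotype]]  # unique genotypes per phenotype
    n_samples: int
    n_discarded: int
    seed: int

    def frequencies_sum(self) -> int:
        return sum(self.counts.values()) + self.n_discarded


@dataclass(frozen=True)
class TestCase:
    __test__ = False  # keep pytest from collecting this domain type

    phenotype: Hashable
    neutral_genotypes: tuple[Genotype, ...]


@dataclass
class TestCaseSet:
    cases: list[TestCase]
    n_samples: int
    seed: int
    strata: list[int] = field(default_factory=list)  # stratum index per case


@dataclass
class TransitionTable:
    """Estimated transitions from a focal phenotype x.

    ``rows`` has columns y, count, probability, raw_cond, scaled_cond; the
    discarded-outcome row (if the map has one) uses the reserved y key and
    NaN complexities.  Probabilities sum to 1 over all rows.
    """

    x: Hashable
    x_encoded: str
    rows: pd.DataFrame
    total_mutants: int
    n_neutral: int
    ny: int  # accessible-set size (rows with probability > 0, discarded excluded)
    c_min: float
    c_max: float
    degenerate_scaling: bool

    def assessable_points(self) -> np.ndarray:
        """(K~(y|x), log10 P) pairs for assessment; discarded rows excluded."""
        mask = self.rows["y"] != DISCARDED
        k = self.rows.loc[mask, "scaled_cond"].to_numpy(dtype=float)
        p = np.log10(self.rows.loc[mask, "probability"].to_numpy(dtype=float))
        return np.column_stack([k, p])

    def to_tsv(self, path: str | Path) -> None:
        df = self.rows.copy()
        df.insert(0, "x", self.x_encoded)
        df.to_csv(path, sep="\t", index=False)

    def sidecar(self) -> dict:
        return {
            "x": self.x_encoded,
            "total_mutants": self.total_mutants,
            "n_neutral": self.n_neutral,
            "ny": self.ny,
            "c_min": self.c_min,
            "c_max": self.c_max,
            "degenerate_scaling": self.degenerate_scaling,
        }


def sample_phenotypes(
    gp_map: MapContract, n_samples: int, seed: int
) -> PhenotypeSample:
    """Uniform i.i.d. genotype sample with per-phenotype genotype lists."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    genotypes = gp_map.random_genotypes(n_samples, rng)
    phenos = gp_map.phenotype_batch(genotypes)
    counts: dict[Hashable, int] = {}
    by_pheno: dict[Hashable, dict[tuple, Genotype]] = {}
    n_discarded = 0
    for g, p in zip(genotypes, phenos):
        if p is None:
            n_discarded += 1
            continue
        counts[p] = counts.get(p, 0) + 1
        by_pheno.setdefault(p, {})[g.positions] = g
    return PhenotypeSample(
        counts=counts,
        genotypes={p: list(d.values()) for p, d in by_pheno.items()},
        n_samples=n_samples,
        n_discarded=n_discarded,
        seed=seed,
    )


def select_test_cases(
    sample: PhenotypeSample,
    n_cases: int,
    seed: int,
    gp_map: MapContract,
) -> TestCaseSet:
    """Choose focal phenotypes with a spread of complexity values.

    Phenotypes are stratified into quartiles of raw C_LZ complexity and
    drawn round-robin across the strata (random order within each) until
    ``n_cases`` are selected or the table is exhausted.
    """
    if n_cases < 1:
        raise ValueError("need at least one test case")
    if not sample.counts:
        raise ValueError("empty phenotype sample")
    rng = np.random.default_rng(seed)
    phenos = list(sample.counts)
    raw = np.array([lz_raw(gp_map.encode(p)) for p in phenos])
    quartiles = np.quantile(raw, [0.25, 0.5, 0.75])
    stratum = np.searchsorted(quartiles, raw, side="right")
    pools: list[list[int]] = []
    for s in range(4):
        idx = np.flatnonzero(stratum == s)
        rng.shuffle(idx)
        pools.append(list(idx))
    chosen: list[int] = []
    chosen_strata: list[int] = []
    while len(chosen) < n_cases and any(pools):
        for s in range(4):
            if pools[s] and len(chosen) < n_cases:
                i = pools[s].pop()
                chosen.append(i)
                chosen_strata.append(s)
    cases = [
        TestCase(
            phenotype=phenos[i],
            neutral_genotypes=tuple(sample.genotypes[phenos[i]]),
        )
        for i in chosen
    ]
    return TestCaseSet(
        cases=cases, n_samples=sample.n_samples, seed=seed, strata=chosen_strata
    )


def enumerate_mutants(g: Genotype) -> list[Genotype]:
    """All single-point mutants of a genotype (no duplicates, g excluded)."""
    out = []
    for i, (sym, a) in enumerate(zip(g.positions, g.alphabet_sizes)):
        for alt in range(a):
            if alt != sym:
                pos = g.positions[:i] + (alt,) + g.positions[i + 1 :]
                out.append(Genotype(pos, g.alphabet_sizes))
    return out


def estimate_transitions(
    case: TestCase,
    gp_map: MapContract,
) -> TransitionTable:
    """Exhaustive 1-mutant transition estimate for one focal phenotype.

    Every single-point mutant of every stored neutral genotype is mapped;
    P(x->y) is the fraction of mutants yielding y.  Discarded outcomes
    enter the denominator (so probabilities sum to 1) but are excluded
    from the accessible set and the complexity scaling.
    """
    if not case.neutral_genotypes:
        raise ValueError("test case has no neutral genotypes")
    x_pattern = gp_map.encode(case.phenotype)
    mutants: list[Genotype] = []
    for g in case.neutral_genotypes:
        mutants.extend(enumerate_mutants(g))
    phenos = gp_map.phenotype_batch(mutants)
    counts: dict[Hashable, int] = {}
    n_discarded = 0
    for p in phenos:
        if p is None:
            n_discarded += 1
        else:
            counts[p] = counts.get(p, 0) + 1
    total = len(mutants)
    accessible = list(counts)
    ny = len(accessible)
    raw_cond = {
        y: conditional_raw(x_pattern, gp_map.encode(y)) for y in accessible
    }
    raws = np.array([raw_cond[y] for y in accessible], dtype=float)
    c_min = float(raws.min()) if len(raws) else float("nan")
    c_max = float(raws.max()) if len(raws) else float("nan")
    degenerate = ny < 2 or (c_max - c_min) <= COMPLEXITY_TOL
    if degenerate:
        scaled = {y: float("nan") for y in accessible}
    else:
        params = ScalingParams(n_phenotypes=ny, c_min=c_min, c_max=c_max)
        scaled = {y: scale_complexity(raw_cond[y], params) for y in accessible}
    recs = [
        {
            "y": _key_str(gp_map, y),
            "count": counts[y],
            "probability": counts[y] / total,
            "raw_cond": raw_cond[y],
            "scaled_cond": scaled[y],
        }
        for y in accessible
    ]
    if n_discarded:
        recs.append(
            {
                "y": DISCARDED,
                "count": n_discarded,
                "probability": n_discarded / total,
                "raw_cond": float("nan"),
                "scaled_cond": float("nan"),
            }
        )
    rows = pd.DataFrame.from_records(
        recs, columns=["y", "count", "probability", "raw_cond", "scaled_cond"]
    )
    return TransitionTable(
        x=case.phenotype,
        x_encoded=x_pattern.symbols,
        rows=rows,
        total_mutants=total,
        n_neutral=len(case.neutral_genotypes),
        ny=ny,
        c_min=c_min,
        c_max=c_max,
        degenerate_scaling=bool(degenerate),
    )


def _key_str(gp_map: MapContract, y: Hashable) -> str:
    return gp_map.encode(y).symbols


def write_case(
    table: TransitionTable, directory: str | Path, name: str, extra: dict | None = None
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.to_tsv(directory / f"{name}.tsv")
    meta = table.sidecar()
    if extra:
        meta.update(extra)
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=2))
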