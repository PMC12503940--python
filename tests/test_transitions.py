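"""Sampling, mutant enumeration and transition estimation."""

import numpy as np
import pytest

from condsimp.gpmaps.base import DISCARDED, Genotype
from condsimp.transitions import (
    TestCase,
    enumerate_mutants,
    estimate_transitions,
    sample_phenotypes,
    select_test_cases,
)


class TestEnumerateMutants:
    @pytest.mark.parametrize(
        "alphabet_sizes,expected",
        [
            ((8,) * 15, 105),  # 15 positions x 7 alternatives
            ((2,) * 15, 15),
            ((2,) * 24, 24),
        ],
    )
    def test_mutant_counts(self, alphabet_sizes, expected):
        g = Genotype((0,) * len(alphabet_sizes), alphabet_sizes)
        mutants = enumerate_mutants(g)
        assert len(mutants) == expected
        assert len({m.positions for m in mutants}) == expected

    def test_each_mutant_differs_at_exactly_one_position(self):
        g = Genotype((1, 0, 3), (2, 2, 8))
        for m in enumerate_mutants(g):
            diffs = sum(a != b for a, b in zip(g.positions, m.positions))
            assert diffs == 1


class TestSamplePhenotypes:
    def test_frequencies_sum_to_n_samples(self, small_matrix_map):
        s = sample_phenotypes(small_matrix_map, 500, seed=3)
        assert s.frequencies_sum() == 500

    def test_stored_genotypes_map_back_to_their_phenotype(self, toy_map):
        s = sample_phenotypes(toy_map, 300, seed=1)
        for p, genos in s.genotypes.items():
            for g in genos:
                assert toy_map.phenotype(g) == p

    def test_first_bit_map_is_binomial(self):
        from condsimp.gpmaps.base import MapContract
        from condsimp.complexity import EncodedPattern

        class FirstBit(MapContract):
            genotype_length = 4
            alphabet_sizes = (2,) * 4

            def phenotype(self, g):
                return str(g.positions[0])

            def encode(self, p):
                return EncodedPattern(str(p), 2)

        s = sample_phenotypes(FirstBit(), 10_000, seed=5)
        assert abs(s.counts["0"] - 5000) < 3 * 50  # 3 binomial sd


class TestSelectTestCases:
    def test_all_phenotypes_selected_when_few(self, toy_map):
        s = sample_phenotypes(toy_map, 2000, seed=2)
        cases = select_test_cases(s, 100, seed=3, gp_map=toy_map)
        assert len(cases.cases) == len(s.counts)

    def test_selection_spans_complexity_strata(self, small_matrix_map):
        s = sample_phenotypes(small_matrix_map, 2000, seed=4)
        cases = select_test_cases(s, 8, seed=5, gp_map=small_matrix_map)
        assert len(set(cases.strata)) >= 2

    def test_reproducible_under_seed(self, small_matrix_map):
        s = sample_phenotypes(small_matrix_map, 1000, seed=6)
        c1 = select_test_cases(s, 5, seed=7, gp_map=small_matrix_map)
        c2 = select_test_cases(s, 5, seed=7, gp_map=small_matrix_map)
        assert [c.phenotype for c in c1.cases] == [c.phenotype for c in c2.cases]


def brute_force_transitions(toy_map, focal, neutral):
    """Exhaustive oracle: count every mutant of every neutral genotype."""
    counts = {}
    total = 0
    for g in neutral:
        for m in enumerate_mutants(g):
            y = toy_map.phenotype(m)
            counts[y] = counts.get(y, 0) + 1
            total += 1
    return {y: c / total for y, c in counts.items()}, total


class TestEstimateTransitions:
    def test_probabilities_sum_to_one(self, toy_map, toy_genotypes):
        focal = toy_map.phenotype(toy_genotypes[5])
        neutral = [g for g in toy_genotypes if toy_map.phenotype(g) == focal]
        table = estimate_transitions(TestCase(focal, tuple(neutral)), toy_map)
        assert table.rows["probability"].sum() == pytest.approx(1.0)
        assert (table.rows["count"] >= 1).all()

    def test_matches_bruteforce_oracle_exactly(self, toy_map, toy_genotypes):
        by_pheno = {}
        for g in toy_genotypes:
            by_pheno.setdefault(toy_map.phenotype(g), []).append(g)
        for focal, neutral in by_pheno.items():
            table = estimate_transitions(TestCase(focal, tuple(neutral)), toy_map)
            oracle, total = brute_force_transitions(toy_map, focal, neutral)
            assert table.total_mutants == total
            got = dict(zip(table.rows["y"], table.rows["probability"]))
            oracle_enc = {toy_map.encode(y).symbols: p for y, p in oracle.items()}
            assert got == pytest.approx(oracle_enc)

    def test_order_and_duplication_invariance(self, toy_map, toy_genotypes):
        focal = toy_map.phenotype(toy_genotypes[9])
        neutral = [g for g in toy_genotypes if toy_map.phenotype(g) == focal]
        t1 = estimate_transitions(TestCase(focal, tuple(neutral)), toy_map)
        t2 = estimate_transitions(TestCase(focal, tuple(reversed(neutral))), toy_map)
        t3 = estimate_transitions(TestCase(focal, tuple(neutral * 2)), toy_map)
        for other in (t2, t3):
            a = t1.rows.sort_values("y").reset_index(drop=True)
            b = other.rows.sort_values("y").reset_index(drop=True)
            assert np.allclose(a["probability"], b["probability"])
            assert list(a["y"]) == list(b["y"])

    def test_ny_monotone_in_neutral_set_size(self, toy_map, toy_genotypes):
        focal = toy_map.phenotype(toy_genotypes[9])
        neutral = [g for g in toy_genotypes if toy_map.phenotype(g) == focal]
        if len(neutral) > 1:
            small = estimate_transitions(TestCase(focal, (neutral[0],)), toy_map)
            full = estimate_transitions(TestCase(focal, tuple(neutral)), toy_map)
            assert full.ny >= small.ny

    def test_identity_map_is_degenerate(self):
        from condsimp.gpmaps.base import MapContract
        from condsimp.complexity import EncodedPattern

        class Constant(MapContract):
            genotype_length = 4
            alphabet_sizes = (2,) * 4

            def phenotype(self, g):
                return "0101"

            def encode(self, p):
                return EncodedPattern(str(p), 2)

        m = Constant()
        g = Genotype((0, 0, 0, 0), m.alphabet_sizes)
        table = estimate_transitions(TestCase("0101", (g,)), m)
        assert table.ny == 1
        assert table.degenerate_scaling
        assert table.rows["probability"].iloc[0] == 1.0

    def test_empty_neutral_set_rejected(self, toy_map):
        with pytest.raises(ValueError):
            estimate_transitions(TestCase("00", ()), toy_map)

    def test_discarded_outcomes_kept_in_denominator(self):
        from condsimp.gpmaps.base import MapContract
        from condsimp.complexity import EncodedPattern

        class HalfDiscard(MapContract):
            """Mutants with odd parity are discarded."""

            genotype_length = 4
            alphabet_sizes = (2,) * 4

            def phenotype(self, g):
                if sum(g.positions) % 2:
                    return None
                return "".join(str(b) for b in g.positions[:2])

            def encode(self, p):
                return EncodedPattern(str(p), 2)

        m = HalfDiscard()
        g = Genotype((0, 0, 0, 0), m.alphabet_sizes)
        table = estimate_transitions(TestCase("00", (g,)), m)
        assert table.rows["probability"].sum() == pytest.approx(1.0)
        assert (table.rows["y"] == DISCARDED).sum() == 1
        # every 1-mutant of 0000 has odd parity -> all discarded
        assert table.rows.loc[table.rows["y"] == DISCARDED, "probability"].iloc[0] == 1.0
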