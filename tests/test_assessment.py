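"""Level I/II/III statistics: screens, upper bounds, bootstrap, aggregation."""

import math

import numpy as np
import pytest

from condsimp.assessment import (
    LevelReport,
    aggregate,
    assess_case,
    bound_model_slope,
    extract_upper_bound,
    level1_test,
    level2_test,
    level3_test,
)
from condsimp.nullmaps import (
    NullTransitionModel,
    make_phenotype_universe,
    sample_null_transitions,
)


def spearman_rank_oracle(x, y):
    """Closed-form rank formula 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = len(x)
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestLevel1:
    def test_perfectly_antimonotone(self):
        pts = np.array([[k, -k] for k in range(1, 8)], float)
        rho, p, passed = level1_test(pts)
        assert rho == pytest.approx(-1.0)
        assert passed

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        rho, _, _ = level1_test(np.column_stack([x, y]))
        assert rho == pytest.approx(spearman_rank_oracle(x, y))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            level1_test(np.array([[1.0, -1.0], [1.0, -2.0]]))
        with pytest.raises(ValueError):
            level1_test(np.array([[1.0, -1.0], [1.0, -2.0], [1.0, -3.0]]))

    def test_monotone_transform_of_probabilities_leaves_rho_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, _, _ = level1_test(np.column_stack([x, y]))
        r2, _, _ = level1_test(np.column_stack([x, np.exp(y)]))
        assert r1 == pytest.approx(r2)


class TestUpperBound:
    def test_max_per_unique_value(self):
        pts = np.array([[1.0, -1.0], [1.0, -2.0], [2.0, -3.0]])
        up = extract_upper_bound(pts)
        assert up.tolist() == [[1.0, -1.0], [2.0, -3.0]]

    def test_single_bin_rejected(self):
        pts = np.array([[1.0, -1.0], [1.0 + 1e-12, -2.0], [1.0, -3.0]])
        with pytest.raises(ValueError):
            extract_upper_bound(pts, mode="binned")

    def test_upper_points_dominate_their_value_class(self):
        rng = np.random.default_rng(9)
        pts = np.column_stack(
            [rng.integers(0, 12, 1000).astype(float), rng.normal(size=1000)]
        )
        up = extract_upper_bound(pts)
        for k, p in up:
            mask = np.abs(pts[:, 0] - k) <= 1e-9
            assert p == pts[mask, 1].max()

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        pts = np.column_stack([rng.integers(0, 6, 200).astype(float), rng.normal(size=200)])
        up1 = extract_upper_bound(pts)
        up2 = extract_upper_bound(pts[rng.permutation(200)])
        assert np.allclose(up1, up2)

    def test_binned_mode_uses_occupied_bins(self):
        pts = np.array([[0.0, -1.0], [0.1, -0.5], [9.9, -3.0], [10.0, -2.5]])
        up = extract_upper_bound(pts, mode="binned", n_bins=10)
        assert len(up) == 2
        assert up[0, 1] == -0.5 and up[1, 1] == -2.5


class TestLevel2:
    def test_collinear_points(self):
        up = np.array([[0.0, 0.0], [1.0, -0.3], [2.0, -0.6]])
        slope, intercept, r2, p, passed = level2_test(up)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-0.3)
        assert passed

    def test_matches_normal_equations_oracle(self):
        up = np.array([[0.0, -0.2], [1.0, -0.9], [3.0, -1.4]])
        X = np.column_stack([np.ones(3), up[:, 0]])
        beta = np.linalg.solve(X.T @ X, X.T @ up[:, 1])
        slope, intercept, r2, _, _ = level2_test(up)
        assert intercept == pytest.approx(beta[0])
        assert slope == pytest.approx(beta[1])
        # R^2 equals the squared Pearson correlation
        assert r2 == pytest.approx(np.corrcoef(up[:, 0], up[:, 1])[0, 1] ** 2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            level2_test(np.array([[0.0, 0.0], [1.0, -1.0]]))


class TestLevel3:
    def test_self_consistency_on_bound_slope_line(self):
        rng = np.random.default_rng(1)
        k = np.arange(8, dtype=float)
        up = np.column_stack([k, bound_model_slope() * k + 0.2])
        lo, hi, passed = level3_test(up, bound_model_slope(), seed=2)
        assert passed
        assert lo <= 0.0 <= hi

    def test_flat_upper_bound_fails(self):
        k = np.arange(8, dtype=float)
        rng = np.random.default_rng(5)
        up = np.column_stack([k, -1.0 + 0.01 * rng.normal(size=8)])
        lo, hi, passed = level3_test(up, bound_model_slope(), seed=3)
        assert not passed
        assert lo > 0.0  # slope diff ~ +0.301, decisively positive

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        up = np.column_stack([np.arange(6.0), rng.normal(size=6)])
        assert level3_test(up, -0.3, seed=42) == level3_test(up, -0.3, seed=42)


class TestAssessCase:
    def test_null_alpha1_recovers_all_levels_often(self):
        # strongly biased null transitions: Levels I and II should almost
        # always fire; the recovered slope is close to the bound slope
        n12 = 0
        slopes = []
        for r in range(20):
            uni = tuple(make_phenotype_universe(64, 20, seed=r))
            model = NullTransitionModel(
                universe=uni, alpha=1.0, x=uni[-1], n=100_000, seed=500 + r
            )
            rep = assess_case(sample_null_transitions(model), seed=900 + r)
            n12 += rep.level1 and rep.level2
            if np.isfinite(rep.fit_slope):
                slopes.append(rep.fit_slope)
        assert n12 >= 18
        assert np.mean(slopes) == pytest.approx(-math.log10(2), abs=0.02)

    def test_uniform_probability_table_rarely_passes_level1(self):
        n_pass = n_ok = 0
        for r in range(60):
            uni = tuple(make_phenotype_universe(64, 20, seed=r))
            model = NullTransitionModel(
                universe=uni, alpha=0.0, x=uni[-1], n=100_000, seed=700 + r
            )
            rep = assess_case(sample_null_transitions(model), seed=800 + r)
            if rep.assessable:
                n_ok += 1
                n_pass += rep.level1
        assert n_ok > 50
        assert n_pass <= 0.15 * n_ok  # nominal rate 2.5%

    def test_convex_upper_bound_passes_level1_fails_level2(self):
        # monotone-decreasing but strongly convex: rank screen fires,
        # linear fit of the upper bound does not
        k = np.linspace(0, 10, 40)
        logp = -1e-3 * np.exp(k / 0.8)
        from condsimp.transitions import TransitionTable
        import pandas as pd

        rows = pd.DataFrame(
            {
                "y": [f"y{i}" for i in range(40)],
                "count": np.ones(40, dtype=int),
                "probability": 10.0**logp / (10.0**logp).sum(),
                "raw_cond": k,
                "scaled_cond": k,
            }
        )
        rows["probability"] = 10.0 ** (logp - np.log10((10.0**logp).sum()))
        table = TransitionTable(
            x="x", x_encoded="x", rows=rows, total_mutants=40, n_neutral=1,
            ny=40, c_min=0.0, c_max=10.0, degenerate_scaling=False,
        )
        rep = assess_case(table, seed=0)
        assert rep.level1
        assert not rep.level2 and rep.fit_R2 < 0.5
        assert not rep.level3


class TestAggregate:
    def _report(self, rho, r2, l1, l2, l3, n_neutral=1):
        return LevelReport(
            rho=rho, fit_R2=r2, level1=l1, level2=l2, level3=l3,
            n_neutral=n_neutral, assessable=True,
        )

    def test_single_case(self):
        r = self._report(-0.5, 0.8, True, True, False, n_neutral=7)
        out = aggregate([r], weights="genotype")
        assert out["rho_mean"] == pytest.approx(-0.5)
        assert out["rho_sd"] == pytest.approx(0.0)

    def test_genotype_weighted_mean(self):
        r1 = self._report(-0.2, 0.9, True, True, True, n_neutral=1)
        r2 = self._report(-0.6, 0.7, True, True, False, n_neutral=3)
        out = aggregate([r1, r2], weights="genotype")
        assert out["rho_mean"] == pytest.approx((-0.2 + 3 * -0.6) / 4)
        phen = aggregate([r1, r2], weights="phenotype")
        assert phen["rho_mean"] == pytest.approx(-0.4)

    def test_chained_proportions(self):
        reports = [
            self._report(-0.5, 0.9, True, True, True),
            self._report(-0.4, 0.8, True, True, False),
            self._report(0.1, 0.2, False, False, False),
        ]
        out = aggregate(reports, weights="phenotype")
        assert out["level1_prop"] == pytest.approx(2 / 3)
        assert out["level2_prop"] == pytest.approx(1.0)  # among L1 passers
        assert out["level3_prop"] == pytest.approx(0.5)  # among L2 passers
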