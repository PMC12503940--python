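"""Three increasingly stringent tests of conditional simplicity bias.

For one focal phenotype the assessment consumes the scatter of
(K~(y|x), log10 P(x->y)) points and asks:

Level I   -- does log10 P decrease with conditional complexity?
             Spearman rank correlation over all points; pass if rho < 0
             with two-sided p < 0.05.
Level II  -- is the *upper bound* linear?  One point per unique
             conditional complexity value (or per equal-width bin), each
             the maximum log10 P; ordinary least squares; pass if
             R^2 > 0.5.
Level III -- is the slope the one the bound predicts?  The bound
             P <= 2^(-a*K~ - b) is a line of slope -a*log10(2) per bit in
             log10 space.  The upper points (never re-extracted) are
             resampled with replacement 1000 times; the 95% percentile CI
             of (bootstrap slope - bound slope) must contain 0.  Level III
             is only attempted when the Level II fit has R^2 > 0.5 and a
             significant linear fit (p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .complexity import COMPLEXITY_TOL
from .transitions import TransitionTable

__all__ = [
    "LevelReport",
    "level1_test",
    "extract_upper_bound",
    "level2_test",
    "level3_test",
    "assess_case",
    "aggregate",
    "bound_model_slope",
]


def bound_model_slope(a: float = 1.0) -> float:
    """Slope of the bound line in log10-probability per bit: -a*log10(2)."""
    return -a * math.log10(2.0)


@dataclass
class LevelReport:
    rho: float = float("nan")
    rho_p: float = float("nan")
    upper_points: Optional[np.ndarray] = None
    fit_slope: float = float("nan")
    fit_intercept: float = float("nan")
    fit_R2: float = float("nan")
    fit_p: float = float("nan")
    bound_slope: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level1: bool = False
    level2: bool = False
    level3: bool = False
    assessable: bool = True
    reasons: list[str] = field(default_factory=list)
    n_points: int = 0
    n_neutral: int = 1

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "rho", "rho_p", "fit_slope", "fit_intercept", "fit_R2",
                "fit_p", "bound_slope", "ci_low", "ci_high",
                "level1", "level2", "level3", "assessable",
                "n_points", "n_neutral",
            )
        }
        d["reasons"] = list(self.reasons)
        if self.upper_points is not None:
            d["upper_points"] = [list(map(float, p)) for p in self.upper_points]
        return d


def level1_test(points: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Spearman screen over all (K~, log10 P) points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3 or len(np.unique(pts[:, 0])) < 2:
        raise ValueError("need at least 3 points with at least 2 distinct complexities")
    if len(np.unique(pts[:, 1])) < 2:
        raise ValueError("all probabilities identical; rank correlation undefined")
    rho, p = stats.spearmanr(pts[:, 0], pts[:, 1])
    passed = bool(rho < 0 and p < alpha)
    return float(rho), float(p), passed


def extract_upper_bound(
    points: np.ndarray,
    mode: str = "unique",
    n_bins: int = 10,
    tol: float = COMPLEXITY_TOL,
) -> np.ndarray:
    """Maximum log10 P per unique complexity value or per equal-width bin."""
    pts = np.asarray(points, dtype=float)
    if mode == "unique":
        order = np.argsort(pts[:, 0])
        pts = pts[order]
        groups: list[list[int]] = []
        for i in range(len(pts)):
            if groups and pts[i, 0] - pts[groups[-1][0], 0] <= tol:
                groups[-1].append(i)
            else:
                groups.append([i])
        upper = np.array(
            [[pts[g, 0].mean(), pts[g, 1].max()] for g in groups]
        )
    elif mode == "binned":
        lo, hi = pts[:, 0].min(), pts[:, 0].max()
        if hi - lo <= tol:
            raise ValueError("all points fall in a single bin; case unassessable")
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.clip(np.searchsorted(edges, pts[:, 0], side="right") - 1, 0, n_bins - 1)
        upper_list = []
        for b in range(n_bins):
            mask = which == b
            if mask.any():
                sub = pts[mask]
                upper_list.append([sub[:, 0][np.argmax(sub[:, 1])], sub[:, 1].max()])
        upper = np.array(upper_list)
    else:
        raise ValueError(f"unknown upper-bound mode {mode!r}")
    if len(upper) < 2:
        raise ValueError("fewer than 2 upper-bound points; case unassessable")
    return upper


def level2_test(
    upper_points: np.ndarray, r2_threshold: float = 0.5
) -> tuple[float, float, float, float, bool]:
    """OLS fit of the upper-bound points; pass iff R^2 > 0.5."""
    up = np.asarray(upper_points, dtype=float)
    if len(up) < 3:
        raise ValueError("need at least 3 upper-bound points for the linear fit")
    res = stats.linregress(up[:, 0], up[:, 1])
    r2 = float(res.rvalue**2)
    return (
        float(res.slope),
        float(res.intercept),
        r2,
        float(res.pvalue),
        bool(r2 > r2_threshold),
    )


def _boot_slopes(
    up: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized bootstrap slopes; degenerate resamples are redrawn."""
    m = len(up)
    slopes = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        need = n_boot - filled
        idx = rng.integers(0, m, size=(need, m))
        x = up[idx, 0]
        y = up[idx, 1]
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = ((x - xm) ** 2).sum(axis=1)
        ok = sxx > 0
        sxy = ((x - xm) * (y - ym)).sum(axis=1)
        good = sxy[ok] / sxx[ok]
        slopes[filled : filled + len(good)] = good
        filled += len(good)
    return slopes


def level3_test(
    upper_points: np.ndarray,
    bound_slope: float,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float, bool]:
    """Percentile bootstrap CI of (fitted slope - bound slope); pass iff 0 inside."""
    up = np.asarray(upper_points, dtype=float)
    if len(up) < 2:
        raise ValueError("need at least 2 upper-bound points to bootstrap")
    rng = np.random.default_rng(seed)
    diffs = _boot_slopes(up, n_boot, rng) - bound_slope
    # exactly collinear input leaves only float rounding in the diffs;
    # snap those to zero so the CI check is not decided by rounding noise
    diffs[np.abs(diffs) < 1e-12] = 0.0
    q = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(diffs, [q, 1.0 - q])
    return float(ci_low), float(ci_high), bool(ci_low <= 0.0 <= ci_high)


def assess_case(
    table: TransitionTable,
    a: float = 1.0,
    b: float = 0.0,
    mode: str = "unique",
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    points_per_mutant: bool = False,
) -> LevelReport:
    """Run the three-level assessment on one transition table.

    ``points_per_mutant`` repeats each phenotype's point once per mutant
    event instead of once per phenotype (off by default).
    """
    report = LevelReport(bound_slope=bound_model_slope(a), n_neutral=table.n_neutral)
    if table.degenerate_scaling:
        report.assessable = False
        report.reasons.append("degenerate_scaling")
        return report
    points = table.assessable_points()
    if points_per_mutant:
        counts = table.rows.loc[table.rows["y"] != "__discarded__", "count"].to_numpy()
        points = np.repeat(points, counts, axis=0)
    report.n_points = len(points)
    if len(points) < 3 or len(np.unique(points[:, 0])) < 2:
        report.assessable = False
        report.reasons.append("too_few_points")
        return report
    if len(np.unique(points[:, 1])) < 2:
        report.assessable = False
        report.reasons.append("uniform_probabilities")
        return report
    report.rho, report.rho_p, report.level1 = level1_test(points)
    try:
        upper = extract_upper_bound(points, mode=mode, n_bins=n_bins)
        report.upper_points = upper
    except ValueError:
        report.reasons.append("no_upper_bound")
        return report
    if len(upper) < 3:
        report.reasons.append("too_few_upper_points")
        return report
    (
        report.fit_slope,
        report.fit_intercept,
        report.fit_R2,
        report.fit_p,
        report.level2,
    ) = level2_test(upper)
    if report.level2 and report.fit_p < 0.05:
        report.ci_low, report.ci_high, report.level3 = level3_test(
            upper, report.bound_slope, n_boot=n_boot, seed=seed
        )
    else:
        report.reasons.append("level2_prerequisites_unmet")
    return report


def _wmean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    w = weights / weights.sum()
    mean = float((w * values).sum())
    var = float((w * (values - mean) ** 2).sum())
    return mean, math.sqrt(var)


def aggregate(
    reports: Sequence[LevelReport], weights: str = "genotype"
) -> dict[str, float]:
    """Summary statistics across test cases.

    ``weights='genotype'`` counts each case once per neutral genotype (the
    expected outcome for a randomly drawn genotype); ``'phenotype'``
    counts each case once.  The R^2 statistics summarize the cases that
    achieve Level II (the Level II column of the summary table), the
    Level II proportion is among Level-I passers, and the Level III
    proportion is among Level-II passers (chained proportions).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    if weights not in ("genotype", "phenotype"):
        raise ValueError(f"unknown weighting {weights!r}")
    usable = [r for r in reports if r.assessable]
    n_unassessable = len(reports) - len(usable)
    if not usable:
        raise ValueError("no assessable cases")
    w = np.array(
        [r.n_neutral if weights == "genotype" else 1.0 for r in usable], dtype=float
    )
    rho = np.array([r.rho for r in usable])
    l1 = np.array([r.level1 for r in usable], dtype=bool)
    l2 = np.array([r.level2 for r in usable], dtype=bool)
    l3 = np.array([r.level3 for r in usable], dtype=bool)
    r2 = np.array([r.fit_R2 for r in usable])
    rho_mean, rho_sd = _wmean_sd(rho, w)
    level1_prop = float((w * l1).sum() / w.sum())
    out = {
        "n_cases": float(len(usable)),
        "n_unassessable": float(n_unassessable),
        "rho_mean": rho_mean,
        "rho_sd": rho_sd,
        "level1_prop": level1_prop,
    }
    mask1 = l2 & np.isfinite(r2)
    if mask1.any():
        r2_mean, r2_sd = _wmean_sd(r2[mask1], w[mask1])
        out["R2_mean"] = r2_mean
        out["R2_sd"] = r2_sd
    else:
        out["R2_mean"] = float("nan")
        out["R2_sd"] = float("nan")
    out["level2_prop"] = (
        float((w[l1] * l2[l1]).sum() / w[l1].sum()) if l1.any() else float("nan")
    )
    out["level3_prop"] = (
        float((w[l2] * l3[l2]).sum() / w[l2].sum()) if l2.any() else float("nan")
    )
    return out
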