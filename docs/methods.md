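# Methods

## The question

In a genotype–phenotype (GP) map, a single point mutation moves a
genotype to a neighbouring genotype, and possibly its phenotype x to a
different phenotype y. The transition probability P(x→y) — the chance
that a random point mutation applied to a random genotype of x produces
y — depends in general on the whole architecture of the map. The bound
tested here claims that much of it can be predicted from the phenotype
patterns alone:

    P(x→y) ≤ 2^(−a·K̃(y|x) − b),

where K̃(y|x) is an approximate conditional Kolmogorov complexity of y
given x (the extra description length needed for y when x is known),
with default constants a = 1, b = 0. Simple-given-x phenotypes may be
reached often; complex-given-x phenotypes must be rare.

## Complexity estimation

Phenotypes are canonical strings over finite alphabets. Complexity is
the Lempel–Ziv-1976 estimator used across the simplicity-bias
literature:

* W(s) = number of words in the LZ76 exhaustive-history parsing (the
  final, possibly reproducible, word is counted). The package computes W
  with the Kaspar–Schuster iteration; an independent naive parser serves
  as the test oracle.
* C_LZ(s) = log2(n) for uniform strings (and single symbols), otherwise
  log2(n)·(W(s) + W(reverse(s)))/2. Averaging with the reversed string
  symmetrizes the parse; the uniform-string base case anchors trivial
  patterns at the bottom of the scale.
* Affine rescaling to bits: K̃ = log2(N)·(C_LZ − c_min)/(c_max − c_min),
  where N is the number of phenotypes and c_min/c_max the extremes of
  C_LZ over the phenotype set, so 0 ≤ K̃ ≤ log2(N) on that set. Values
  outside [c_min, c_max] extrapolate linearly rather than clip, because
  mutants can fall outside the extremes of a finite accessible set.
* Conditional complexity: K̃(y|x) from the raw difference
  C_LZ(xy) − C_LZ(x), floored at 0 (concatenation can parse into
  marginally fewer words, and the bound needs a non-negative exponent).
  For transitions the scale factor is log2(Ny(x)) with Ny(x) the number
  of phenotypes accessible from x's neutral set, and c_min/c_max are the
  extremes of the raw conditional values over that accessible set. Note
  that ρ and the upper-bound R² below are invariant to this affine
  choice; only the Level III slope comparison depends on it.
* Two scaled complexities are treated as equal when within 1e-9 bits
  (floating point from the rescaling).

## Map simulators

**Matrix map.** x = H(D·g): genotypes are binary strings of length
L = 15, D is an L×L matrix with i.i.d. entries uniform on {−1, 0, 1}
(promotion/absence/suppression of regulation), and H sets component j to
1 exactly when (D·g)_j > 0. The map's information content (~L² table
entries) exceeds any genotype's (~L bits) but is far below a random
assignment's (~n_g·log2(n_p)), which is why conditional simplicity bias
can appear even though plain simplicity bias does not.

**Polyomino self-assembly.** 24-bit genotypes encode 2 tile types × 4
edges × 3-bit edge colours. Colour 0 is neutral; colours bind in the
pairs (1,2), (3,4), (5,6); colour 7 is self-complementary (7 binds 7).
Assembly seeds a tile of type 0 and repeatedly attaches a uniformly
random (empty site, tile type, orientation) placement whose facing edge
binds an adjacent open edge, until no placement remains. A genotype is
kept only when 20 independently ordered assemblies all terminate within
a 16×16 bounding box with the same oriented shape (translation- and
rotation-identified); any disagreement or unbounded growth is UND and
the genotype is discarded. The phenotype identifies shapes additionally
up to reflection, so a rule set and its mirror image share a phenotype.
Under these conventions the exhaustive enumeration of all 2^24 genotypes
yields exactly 22 distinct shapes, the phenotype count reported in
prior studies of this two-tile, eight-colour self-assembly family;
the alternative conventions we tested (colour 7 inert,
or reflections kept distinct, or self-binding for every colour) yield
16/15/2 shapes and were rejected on that ground. Shapes are encoded for
complexity by site occupation (bounding-box grid rows concatenated, '1'
for a block) and, as a secondary option, by a perimeter walk (one
direction symbol per exposed unit edge, each boundary loop walked with
the shape on the right — a reconstruction, since only the idea of a
perimeter-based measure is documented).

Because the assembled shape depends on the genotype only through which
edges bind which, genotypes reduce to canonical interaction classes
(48 colour relabellings preserving the binding structure), and the
determinism check runs once per class with a class-derived seed stream.
The determinism check is one-sided Monte Carlo: UND verdicts are proofs
(a disagreement or unbounded run was observed), while "deterministic"
verdicts are statistical at 20 repeats. Rule sets whose minority
assembly outcome is rare can therefore pass, and the phenotype count is
protocol-dependent at the margin; the per-class protocol with 20 repeats
is the one that reproduces the reported count of 22.

**HP lattice protein.** Genotypes are H/P strings of length L; the
conformation space is all self-avoiding walks (SAWs) of L monomers on
the square lattice, reduced to one representative per symmetry class
(lexicographically smallest UDRL string over the 8 rotations/
reflections; the chain is not reversed — it has an N-to-C orientation).
Energy = −(number of lattice-adjacent, chain-non-adjacent H–H pairs); a
sequence folds to the unique minimum-energy class or is discarded as
degenerate when two or more classes tie. L = 25 (the scale prior HP
studies use, ~10^9 walks) is supported by the data structures but not enumerable at
desk scale; the analysis driver uses L = 14 and tests use L ≤ 8–10,
where a naive depth-first enumeration is the oracle. A compact-rectangle
restriction (candidate walks filling a minimal bounding rectangle) is
available as a flag, untested at the L = 36 scale such studies use.

**Up–down discretizer.** Continuous time-series phenotypes (e.g. a
circadian activator concentration profile) are reduced to bits: across
consecutive windows of W samples, emit '1' when the end-to-end slope is
positive, '0' when negative or flat, giving floor((T−1)/W) bits — a
499,999-point series at W = 25,000 gives 19 bits. The differential
equation generating such profiles lives outside the package; the
discretizer accepts any externally supplied series, and tests use
synthetic ones. Consequently no circadian transition experiment is run
in-package.

## Transition estimation

100,000 genotypes are sampled uniformly; each phenotype's neutral set is
the unique genotypes found for it. Test cases (default 35) are chosen
with a spread of complexity: phenotypes are stratified into quartiles of
raw C_LZ and drawn round-robin across strata. For each case, every
single-point mutant of every neutral genotype is enumerated exhaustively
(Σ_i (A_i − 1) mutants per genotype; 105 for 15 positions × 8 letters,
15 for the binary matrix map, 24 for the polyomino map) and pushed
through the map. P(x→y) = count(y)/total mutants. The y = x row (the
robustness mass) is kept as an ordinary row. Discarded outcomes (UND
assemblies, degenerate folds) stay in the denominator — so probabilities
sum to 1 — but carry no encoded pattern and are excluded from the
accessible set, the scaling and the assessment points. Cases where all
probabilities are equal (rank correlation undefined) or where the
accessible set has a single complexity value (scaling degenerate) are
flagged unassessable and excluded from the level statistics.

The assessment scatter has one point per accessible phenotype
(K̃(y|x), log10 P̂(x→y)). A per-mutant-event weighting (each phenotype
repeated by its mutant count) is available as an option; on the
polyomino map it shifts the genotype-weighted mean ρ from ≈ −0.51 to
≈ −0.33, bracketing the −0.43 reported for this map in prior work, so the
treatment of this choice visibly matters and neither option
reproduces that reported value exactly.

## The three levels

* **Level I** — Spearman ρ over all points; pass when ρ < 0 with
  two-sided p < 0.05 (the conservative reading of "significant negative
  correlation").
* **Level II** — upper-bound extraction: the maximum log10 P̂ at each
  unique complexity value (tolerance 1e-9), or, in binned mode, in each
  of 10 equal-width bins over the observed range; then unweighted OLS;
  pass when R² > 0.5.
* **Level III** — bound-model slope −a·log10 2 ≈ −0.301 per bit at
  a = 1. The fixed upper points (never re-extracted) are resampled with
  replacement 1000 times; each resample's OLS slope minus the bound
  slope forms the difference distribution; pass when the 95% percentile
  CI contains 0. Attempted only when Level II holds with a significant
  fit (p < 0.05). Degenerate resamples (all one complexity) are redrawn;
  slope differences below 1e-12 are snapped to zero so exact collinearity
  is not decided by float rounding.

Aggregation over cases reports the mean ± sd of ρ, the Level I pass
proportion, the mean ± sd of R² among cases achieving Level II, the
Level II proportion among Level-I passers and the Level III proportion
among Level-II passers (chained proportions). Genotype weighting counts
each case once per neutral genotype — the expected outcome for a random
genotype — and phenotype weighting counts each case once. Summarizing R²
among Level-II achievers (rather than Level-I passers) is deliberate:
the two readings differ strongly on the matrix map (≈0.77 vs ≈0.50) and
only the former matches the values reported for this map family.

## Synthetic null models

`nullmaps` draws transition outcomes directly over a fixed universe of
64 distinct random binary phenotypes of length 20 (always including the
all-zero string, so the complexity range is non-trivial) with
P(y) ∝ 2^(−α·K̃(y|x)) — exactly the structure the bound assumes, with
tunable strength α. It samples phenotypes without a genotype layer, since
the assessment consumes transition tables; the 6-bit toy map (phenotype =
genotype with run lengths quantized to one or two symbols) covers the
genotype path and is small enough for exhaustive verification. What the
null model deliberately does not emulate: neutral-set structure,
correlated mutants, and discarded outcomes.

Calibration results (recomputed by `analysis/01_null_calibration.py` and
the test suite): at α = 0 the Level I screen fires in ≈2–3% of 400
replicates (nominal 2.5%); at α = 1, n = 10^5 the fitted upper-bound
slope recovers −log10 2 to within 0.01. A known bias of the prescribed
procedure: the upper bound takes the maximum of many phenotypes sharing
one complexity value, and a maximum over tied noisy estimates is biased
upward — more at high complexity where counts are low — flattening the
fitted slope from −0.3010 to ≈ −0.2955 at these sample sizes. The
bootstrap CI, which reflects only the scatter of the near-collinear
upper points, is much narrower than this bias, so the Level III check
fails in most α = 1 replicates even though the slope estimate is
accurate to 2%. Cell means are unbiased (≈ −0.3003); the max-based
estimator is kept because it is the procedure under test.

## Problem sizes and runtimes

Defaults follow the protocol standard in this literature: 100,000
genotype samples, 35
test cases, exhaustive 1-mutant enumeration, 1000 bootstrap resamples,
20 assembly repeats, 16×16 grid limit. The acceptance script averages
five full matrix-map replicates (each redrawing D and the sample) and
three polyomino replicates (one rule-set realization, three samples);
a full run takes ~7 minutes. The exhaustive polyomino enumeration
(~475k interaction classes for 2^24 genotypes) takes ~9 minutes. HP
analyses in-package run at L ≤ 14.

## Known limitations

* Circadian and tooth-development GP maps need external simulators
  (a delay-oscillator ODE, a 3-D developmental model) and are out of
  scope; HP at L = 25 is supported in code but not run at desk scale.
* The polyomino determinism check is Monte Carlo; its "deterministic"
  verdicts, and hence the marginal tail of the phenotype set, depend on
  the repeat count and seed protocol (see above).
* Estimated log10 P̂ has no pseudo-counts: a phenotype appears in a
  table only with count ≥ 1, so rare transitions below ~1/(total
  mutants) are invisible, which truncates the scatter from below.
* The genotype-weighted summary is dominated by the few largest neutral
  sets, making the per-run aggregate sensitive to which high-probability
  phenotypes the sample hits; the acceptance script averages replicates
  for this reason.
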