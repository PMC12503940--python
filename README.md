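# condsimp

Conditional simplicity bias in genotype–phenotype maps: estimating
phenotype transition probabilities under single-point mutations and
testing the information-theoretic bound

    P(x→y) ≤ 2^(−a·K̃(y|x) − b)

where K̃(y|x) is an approximate conditional Kolmogorov complexity — the
extra description length needed to produce phenotype y when phenotype x
is available, estimated from Lempel–Ziv-1976 compression of the
phenotypes' string encodings. The bound formalizes an old intuition:
random mutations mostly produce phenotypes that are simple, or similar
to what was already there; transitions to phenotypes that are complex
*given* the current one must be rare. Remarkably, it makes quantitative
predictions from the phenotype patterns alone, with no knowledge of the
underlying map.

The package is aimed at people studying GP map architecture, phenotype
bias, robustness and evolvability in silico. It provides:

* `condsimp.complexity` — C_LZ (LZ76 word counts, forward/reverse
  averaged), the affine rescaling to bits, conditional complexity
  K̃(y|x) = K̃(xy) − K̃(x), and the bound itself.
* `condsimp.gpmaps` — self-contained map simulators sharing one
  contract: the matrix-multiplication gene-regulation map x = H(D·g);
  two-tile/eight-colour polyomino self-assembly (24-bit genotypes, 22
  phenotype shapes over the full 2^24 space); the 2-D HP lattice protein
  model with exact self-avoiding-walk enumeration; and the up–down
  discretizer that turns continuous time-series phenotypes into bit
  strings.
* `condsimp.transitions` — neutral-set sampling, exhaustive single-point
  mutant enumeration, and estimation of P(x→y) with per-row conditional
  complexities.
* `condsimp.assessment` — the three-level test battery: Level I
  (negative Spearman rank correlation), Level II (linear upper bound,
  R² > 0.5), Level III (bootstrap CI of the slope difference against the
  bound model's −a·log₁₀2 per bit), plus genotype- and
  phenotype-weighted aggregation.
* `condsimp.nullmaps` — synthetic transition generators with tunable
  bias strength α (P(y) ∝ 2^(−α·K̃(y|x))) for validating the statistics
  by parameter recovery, and a hand-enumerable toy map.
* `condsimp.pipeline` / `condsimp.cli` — an end-to-end, manifest-
  reproducible pipeline (`condsimp run --map-name matrix ...`) with
  subcommands `sample`, `transitions`, `assess`, `run`, `discretize`,
  `null-validate`.

The numbered scripts under `analysis/` are the narrative drivers: null
calibration, the matrix-map and polyomino experiments, the exhaustive
polyomino enumeration, and a desk-scale HP run. Each writes its tables
under `results/`.

## A worked example

```python
import numpy as np
from condsimp.gpmaps import MatrixMap
from condsimp.transitions import sample_phenotypes, select_test_cases, estimate_transitions
from condsimp.assessment import assess_case, aggregate

m = MatrixMap(L=15, seed=42)                      # x = H(D·g), D in {-1,0,1}^(15x15)
s = sample_phenotypes(m, 100_000, seed=1)         # frequency table + neutral sets
cases = select_test_cases(s, 35, seed=2, gp_map=m)  # complexity-stratified focal x's
reports = [assess_case(estimate_transitions(c, m), seed=100 + i)
           for i, c in enumerate(cases.cases)]
print(aggregate(reports, weights="genotype"))
```

Running `python analysis/02_matrix_map.py` (which is exactly this
protocol plus artifact output) prints:

```
genotype-weighted: rho = -0.214 +/- 0.100, Level I 0.71, R2 = 0.737, Level II 0.90, Level III 0.81
phenotype-weighted: rho = -0.219 +/- 0.180, Level I 0.41, R2 = 0.740, Level II 0.55, Level III 0.31
```

Read: for a randomly chosen genotype of this map, the transition
probabilities out of its phenotype correlate negatively with conditional
complexity (mean Spearman ρ ≈ −0.21; Level I holds for 71% of the
genotype mass), the upper bound of log₁₀P against K̃(y|x) is usually
well fit by a line (mean R² ≈ 0.74 among linear cases), and where the
fit is sound the bootstrap often cannot distinguish its slope from the
predicted −log₁₀2 ≈ −0.301 per bit. `analysis/01_null_calibration.py`
shows the machinery is calibrated: with no bias the Level I screen fires
at 3.2% (nominal 2.5%), and with bias of exactly bound strength the
fitted upper-bound slope comes back as −0.296 per bit.

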