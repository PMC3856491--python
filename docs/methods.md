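# Methods

This note documents the models and procedures implemented in `gepess`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical conventions.

## Problem setting

Given an undirected simple PPI network, a gene-expression matrix, a
subcellular-localization table, a per-protein conservation score, and a
list of known essential proteins, the task is binary: rank proteins by
predicted essentiality. Evaluation follows the ranked protocol common in
this literature: the top k proteins (k = number of known essentials) are
called essential, and confusion-based rates plus ROC/AUC summarize the
ranking. With k equal to the number of actual positives, TP+FP = TP+FN
forces SN = PPV and SP = NPV identically; reported metric rows always
show this pairing, and the test suite asserts it.

## Features

Seven centralities are computed per protein. DC, BC (unnormalized,
over unordered pairs), CC and SC are delegated to networkx; two are
implemented directly because their conventions here differ from the
library's normalizations:

- **EC**: the nonnegative principal eigenvector of the adjacency matrix
  of the *largest connected component*, scaled to unit Euclidean norm;
  all other nodes score 0. Computed by shifted power iteration (A + I),
  which has the same eigenvectors but cannot oscillate on bipartite
  components; convergence tolerance 1e-12, iteration cap 10,000,
  failure is an error.
- **IC**: per connected component of size n, with C = (L + J)⁻¹,
  pairwise resistances r_ij = c_ii + c_jj − 2c_ij and
  IC(i) = n / Σ_j r_ij. Isolated nodes score 0.

Closeness is component-restricted, (n_comp − 1)/Σ d(v,u), because real
interaction networks are not guaranteed connected; isolated nodes score
0. ECC uses the convention ECC = 0 when either endpoint has degree 1 (a
pendant edge participates in no triangle).

Composite features:

- **PeC** floors negative co-expression at 0 (anti-correlated neighbours
  contribute nothing); **WDC** keeps the signed correlation. Both
  behaviours are exposed in `FeatureConfig`.
- **PCC is defined as 0** for protein pairs lacking expression rows or
  with constant profiles — a neutral contribution, consistent with
  partial expression coverage.
- **ION** iterates S ← (1−α)O + αWᵀS from S = O, with W row-stochastic
  (each protein distributes a unit of influence across its neighbours in
  proportion to ECC; uniformly when all of its incident ECCs vanish).
  Because rows of W sum to 1, the map is an α-contraction in L1 and
  converges geometrically; we stop when the L1 change drops below 1e-6
  or after 100 iterations (then warn and return the last iterate).
  Defaults α = 0.85 and λ = 0.5 (WDC) are configuration values, not
  facts about the source method descriptions, which leave them open.

All features are max-abs normalized into [−1, 1]; all-zero columns stay
zero with a warning; localization indicators are 0/1 and unaffected.
The orthology input is deliberately a generic nonnegative per-protein
score (e.g. the number of reference organisms with an ortholog); how
such a score is derived from a raw orthology database is out of scope.

## The GEP classifier

**Encoding.** One gene per chromosome by default; head length h = 20
over functions ∪ terminals, tail of t = h·(a_max − 1) + 1 = 21 terminals,
so the structural chromosome length is 41. A configuration table for
this method circulating in the literature lists a chromosome length of
60 with one gene and head 20; that is structurally inconsistent with a
Karva gene at maximum arity 2 (possibly an unstated constant domain),
so the package derives the length from the head instead of accepting a
free length parameter. Multigenic chromosomes are supported with
addition linking only.

**Protected evaluation.** div(a,b) = a/b if |b| > 1e-12 else 1.0;
sqrt(x) = √|x|; log(x) = ln(|x| + 1e-12); exp(x) = exp(min(x, 30));
eq(a,b) = 1 iff |a−b| ≤ 1e-9; every node's output is clamped to finite
values (±1e150), so any chromosome scores any protein without error.
The "=" operator's semantics are not standard anywhere; the approximate
equality indicator is this package's choice.

**Fitness.** Rank-based binarization at k = number of training
positives, ties at the cutoff broken by lexicographic protein ID so
fitness is a pure function of the chromosome; then SSPN = SN·SP·PPV·NPV,
each factor 0 when its denominator vanishes. SSPN ∈ [0,1], equals 1 iff
the split is perfect with both classes present.

**Rates.** The configuration table prints "Mutation rate% 0.25" and
"Cross rate% 0.1"; the package reads these as probabilities 0.25
(per position) and 0.1 (per pair). The literal percent reading
(0.0025/0.001) produces almost no variation at population sizes a
desktop can afford and can be had by simply setting those config values.
Transposition rates are not printed anywhere; defaults 0.1/0.1.

**Reproduction.** Per generation: evaluate all chromosomes; carry the
single best unchanged (elitism — added so the best-so-far fitness is
provably non-decreasing); truncate to the top 30% as parents; refill by
pairing parents cyclically in fitness order and applying one-point
recombination, per-position mutation (head resamples from functions ∪
terminals, tail from terminals only), then IS/RIS transposition
restricted to the head. Cyclic pairing rather than random parent
sampling was chosen so that with all operator rates at zero and a
selection fraction of 1 the population is exactly invariant — a useful
steady-state contract that random refill cannot satisfy; truncation
selection already supplies the selection pressure. All operators
preserve chromosome length and head/tail domains by construction, so
every offspring decodes.

**Determinism.** A single seeded `numpy` generator is threaded through
initialization and all operators; identical configs give bit-identical
runs.

**Scale profiles.** `GepConfig()` defaults to the full-scale settings
(population 12,000, 500 generations). `GepConfig.desk()` (population
200, 50 generations) is the profile used by the test-suite fixtures and
the acceptance script; at 500 proteins one desk-scale fit takes about a
second, which makes the multi-seed recovery experiment and the 10-fold
cross-validation affordable on one core.

## Evaluation machinery

Stratified k-fold assignment shuffles each class and deals members
round-robin, so per-class fold sizes differ by at most one and each
fold's class ratio matches the global ratio up to rounding. Classes
smaller than k are allowed (some folds then hold no positive); only an
empty class is an error. The ROC sweep uses every distinct score as a
cutoff (ties grouped into single steps) and the trapezoidal rule, which
equals the Mann–Whitney statistic with half tie credit; the test suite
checks this equivalence exactly against an independent rank-sum oracle.
Model selection across folds picks the classifier whose held-out AUC is
closest to the mean, ties to the lower fold index.

## The published yeast classifier

The final classifier expression reported for the DIP yeast network ends
in a malformed fragment (`Abs(Min(cytoplasm-vacuole,0.1),1))` — a
two-argument Abs with unbalanced parentheses). The package stores a
canonical interpretation, reading the fragment as the absolute deviation
from 1:

```
Min(lysosome, WDC - 0.5) + (ION - 0.9)
  + Max(0.4, Max(endoplasmic_reticulum, nucleus) - Min(0.5, SC))
  - Abs(Min(cytoplasm - vacuole, 0.1) - 1.0)
```

This is flagged as an interpretation in `karva.PUBLISHED_CLASSIFIER`.
Two of its properties are hand-derivable and kept under test: it scores
−2.0 on an all-zero feature vector, and it is strictly increasing in
ION with other features held fixed.

The four constants {0.1, 0.2, 0.5, 1.0} described as feature-adjusting
coefficients are implemented as terminal symbols available to evolution,
not as fixed per-feature multipliers: the published expression contains
free constants (0.4, 0.9, …) that arise naturally from arithmetic over
such terminals, which is strong evidence for this reading.

## Synthetic data

The generator produces desk-scale datasets with the qualitative
structure the method assumes, emulating the yeast setting (essential
fraction 0.229 ≈ 1167/5093, 36 expression samples, ~5% of proteins
without expression rows) at n = 500:

- **Network**: modular preferential-attachment growth from a complete
  seed clique of m = 3 nodes. Each new node joins one of 20 modules and
  adds exactly m edges: the first by global sublinear preferential
  attachment (degree exponent 0.75 — attachment in real interaction
  networks is weaker than linear, and sublinear growth keeps the degree
  tail heavy without letting one hub dwarf the network), the rest inside
  its module or by triangle closure with the module's cohesion
  probability (spread over [0.05, 0.95]). This yields a connected graph
  with exactly (n−m)·m + m(m−1)/2 edges, a heavy-tailed degree
  distribution, and triangle-rich modules — the structure that gives
  ECC, NC, PeC, WDC and ION their signal in real PPI data.
- **Expression**: module members share a latent per-sample factor
  (loading U(0.7, 1.3), residual noise sd 0.5), so within-module
  correlation is high and between-module correlation near zero —
  complex members are co-expressed.
- **Localization/orthology**: sampled against provisional essentials
  with enrichment in the direction reported for real data — nucleus
  membership 0.80 vs 0.08, endoplasmic reticulum 0.40 vs 0.10,
  cytoplasm and vacuole depleted, ortholog counts Binomial(20, 0.95) vs
  Binomial(20, 0.03). The separations are deliberately strong: the
  planted signal must survive feature normalization and the 0.2-sd
  labelling noise for the fixture to remain solvable.
- **Labels**: the two-pass scheme breaks the circularity that ION's
  input is keyed to essentiality. Provisional essentials are the top
  fraction by NC (topology only); the biology tables are sampled against
  them; the final feature table is assembled; final labels are the top
  fraction of `0.6*ION + 0.3*NC + 0.4*nucleus` plus Gaussian noise
  (sd 0.2). The noise-free planting score is exposed separately so the
  generator's self-consistency can be measured.

Everything is deterministic under the seed, to the byte in the written
files.

**What passing tests do and do not show.** The fixture has an exactly
known generative link between features and labels, realistic qualitative
structure, and an irreducible noise floor (the labelling noise is
unlearnable, which bounds the achievable held-out AUC). Recovering the
planted signal demonstrates that the feature computations, the encoding,
the fitness, and the evolutionary loop work together as designed. It
does not certify performance on real yeast data: the generator matches
neither the real degree distribution quantitatively, nor expression
dynamics, nor annotation error patterns, and the real feature-label
relationship is far messier than a three-term planted expression.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run on random graphs of ≤ 25 nodes (50 graphs,
tolerance 1e-8 against brute-force path enumeration, BFS distance sums,
dense matrix exponential/eigendecomposition, and Laplacian-pseudoinverse
resistances). The recovery experiment evolves desk-scale classifiers
(population 200, 50 generations) for five seeds on the 500-protein
fixture, each judged on a held-out stratified third, alongside a 10-fold
cross-validation. These sizes were chosen so the entire suite and the
acceptance script each complete in well under a minute on a single core
while leaving the conclusions qualitatively unchanged at larger scale.

## Known limitations

- Unweighted, undirected networks only; no confidence scores on edges.
- Single-gene chromosomes by default; multigenic linking is addition
  only; no separate random-constant domain (the four fixed coefficient
  terminals stand in for it).
- The centrality oracle agreement is verified on graphs up to 25 nodes;
  beyond that we rely on the underlying library implementations.
- Fitness at desk scale has large plateaus (many chromosomes tie), so
  evolved expressions vary across seeds even when their held-out AUCs
  are similar; interpretation of any single evolved expression should
  respect that degeneracy.
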