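# Methods

## Karyotype divergence

A karyotype is summarised by its diploid number `2n` and karyotype formula
pooling chromosomes into bi-armed (meta-/submetacentric, "m-sm") and
uni-armed (subtelo-/acrocentric, "st-a") classes.  The fundamental number
counts arms with the pooled-class convention `FN = 2n + biarmed`: a finer
arm convention (e.g. subtelocentrics as two arms) is not expressible when
the source data pool "m-sm" vs "st-a".  The divergence index

    D(a, b) = |2n_a − 2n_b| / 2 + |FN_a − FN_b| / 2

is reported in raw units of chromosome-pair changes, not normalised to a
percentage: no defensible normalisation reproduces published percentage
figures for non-zero pairs, while raw units reproduce the zero results
exactly.  `D` is a semimetric (non-negative, symmetric, zero iff the
(2n, FN) pairs coincide) but not a metric — the triangle inequality holds
trivially here but distinct karyotypes can be at distance zero.

Species with multiple sex chromosome systems (X₁X₁X₂X₂ / X₁X₂Y) have
sex-dependent diploid numbers; interspecific comparisons default to the
female complement, which is even and homomorphic, with a flag to select
the male complement.  Constitutive-heterochromatin (CH) band sites are
encoded as `(pair, arm, position)` triples at the granularity of published
tables ("centromeric region of all chromosomes" is one whole-karyotype
band, pair index 0); band comparison is set intersection on those triples.

UPGMA clusters the divergence matrix directly, merging at height `d/2`
with average linkage, ties broken by the lexicographically smallest taxon
pair so the dendrogram is deterministic.  Zero-distance merges are kept as
binary nodes with zero-length internal edges.  An optional mode first
converts matrix rows to feature vectors and clusters their Euclidean row
distances; it is off by default because the divergence matrix is itself
already a distance.

## Tree preparation

Analyses accept any rooted newick topology.  Tips without trait data are
pruned (never imputed), collapsing unary nodes with summed edge lengths.
Branch lengths are assigned by Grafen's method with exponent ρ = 1: node
height `((k − 1)/(n_leaves − 1))^ρ` for a node with `k` descendant leaves,
giving leaf heights 0 and root height exactly 1.  The fixture topology
ships without branch lengths on purpose — the published source tree's
lengths are not available — so every run states its lengths explicitly.

## Brownian-motion ancestral states and signal

Under Brownian motion with rate σ² and root state μ, tip values are
multivariate normal, covariance σ²C with `C_ij` the shared root-to-tip
path length.  Ancestral states are the ML/GLS predictions, computed by the
linear-time two-pass message recursion (equivalent to re-rooting at each
node and taking the precision-weighted tip average); the test suite checks
it against an explicit O(n³) covariance-inversion oracle at 1e-8.  Node
variance is the conditional variance of that weighted average times the ML
rate estimate `σ̂² = (x − μ̂)ᵀC⁻¹(x − μ̂)/n`; 95 % intervals use the
0.975 normal quantile.  Zero-length branches are replaced by 1e-8 of tree
height with a logged warning.

Pagel's λ rescales the off-diagonal of C; λ̂ maximises the profile
likelihood on `[0, λ_max]` with `λ_max = min_i C_ii / max_{j≠i} C_ij`
(the largest multiplier keeping every pair's shared path below both tip
depths — slightly above 1 on trees with short terminal branches, which is
why empirical λ̂ can exceed 1).  The search uses bounded scalar
minimisation (tolerance 1e-8) over five interval segments plus both
endpoints.  The p-value is a 1-df likelihood-ratio test against λ = 0;
the null at λ = 1 would test the opposite question (departure from pure
Brownian motion) and is not used.

Blomberg's K is the observed `MSE0/MSE` ratio over its closed-form
Brownian expectation `(tr C − n/(1ᵀC⁻¹1))/(n − 1)`; K = 1 under Brownian
motion, K > 1 when close relatives are more similar than Brownian motion
predicts.  The p-value is a one-tailed permutation test on the
phylogenetic MSE with the add-one rule `(b + 1)/(m + 1)`; 1000
permutations by default, seed mandatory.

## Chromosome-number Markov model

The haploid number evolves on a bounded window `[n_min, n_max]`,
defaulting to `[max(1, min_obs − 10), 2·max_obs + 10]` so that
duplications of any observed state stay inside the window.  Generator
entries: gain `n → n+1`, loss `n → n−1`, duplication `n → 2n`,
demi-duplication `n → 1.5n` with odd-`n` rate split equally between
`floor(1.5n)` and `ceil(1.5n)`.  Linear families use
`rate(n) = const + linear·(n − n_min)` clamped at zero.  Transitions
leaving the window are truncated.  Eight families (constant/linear ×
duplication treatment; DEMI ties the demi rate to the duplication rate,
DEMI_EST frees it) have 2–6 free parameters.

Likelihoods use Felsenstein pruning with `P(t) = expm(Qt)`, computed via
one eigendecomposition per rate evaluation (expm fallback when the
factorisation does not reproduce Q to 1e-9).  The root is handled by
weighting root states by their normalised conditional likelihoods (the
ML-style convention; a flat prior is available and both are recorded in
output metadata).  Fitting is multi-start L-BFGS-B on log₁₀ rates (linear
slope terms on a linear scale, since they may be negative), Latin-
hypercube starts, 10 restarts by default, seeded.  `AIC = 2k − 2 logL`
selects the model; ties go to fewer parameters, then family name.

Two ancestral reconstructions are provided and both are reported:

* **marginal** — per-node posterior over states from the standard up/down
  pass; best state is the posterior argmax.  Neighbouring states are often
  nearly tied (the fixture's genus ancestor has p(25) ≈ 0.34 vs
  p(24) ≈ 0.33), which is why published chromosome-number reconstructions
  sometimes print paired states.
* **joint** — the single assignment of states to all internal nodes
  maximising the whole-history posterior (max-product dynamic
  programming).  Branch-event narratives and the reported per-node
  ancestral numbers use the joint states, because a per-branch event story
  must be internally consistent — adjacent marginal argmaxes need not be.

Reported diploid values are exactly twice the haploid states.  In the
output vocabulary gains are fissions and losses are fusions.

Per-branch expected event counts come from stochastic mapping: joint node
states are backward-sampled from the posterior, then each branch's history
is drawn conditional on its endpoints by rejection sampling (forward
simulation until the endpoint matches, up to 2000 tries per draw); 300
maps by default, Monte-Carlo error `std/√n_maps`, and an error is raised
if more than 99.9 % of draws are rejected.

## Rearrangement inference

Fusions are modelled as Robertsonian: two uni-armed pairs join into one
bi-armed pair, so `fusions = (2n_parent − 2n_child)/2` on a decreasing
branch (fissions symmetric; a branch is net one direction).  Between two
observed karyotypes, the lower-2n side's expected bi-armed pairs are the
higher side's pairs plus the fusions; pericentric inversions (which toggle
one pair between uni- and bi-armed without changing 2n) make up the
absolute discrepancy.  This convention reproduces the published 17
(brevirostris–hendersoni) and 3 (beebei–hamiltoni) counts; for
regani–batesi it computes 13 where 11 was published — no single convention
tested reproduces all three printed counts, so the computed value is
reported and the convention stated here.  Inversions and CH changes are
evaluated only between sister tips (internal karyotype formulas are not
reconstructed).

## Synthetic data

The generators exist so that every estimator has a no-download test
surface with known truth:

* **Yule trees** — pure-birth, scaled to root height 1 to match
  Grafen-prepared empirical trees.  They lack the imbalanced shapes and
  rate heterogeneity of real phylogenies.
* **Brownian traits** — one multivariate-normal draw on the
  λ-transformed covariance.  Real chromosome numbers are integers with
  bounded range; the Gaussian emulation tests the estimators'
  statistical behaviour, not the discreteness.
* **CTMC histories** — Gillespie simulation using exactly the truncated
  generator of the likelihood machinery, with per-branch random streams
  spawned from one root `SeedSequence` (keyed by preorder index) so
  draws on one branch are independent of traversal order.  Event logs
  replay to the simulated tips exactly.
* **Karyotype tables** — random records in the teleost-typical 2n = 30–50
  range satisfying all invariants; they carry no phylogenetic signal and
  are for format/pipeline tests only.

Passing tests on these generators show the estimators recover known
generating processes; they do not validate the biological realism of the
fixture assumptions (outgroup diploid numbers, Grafen branch lengths).

## Problem sizes and numerical choices

The packaged analysis uses 16 tips (11 ingroup + 5 outgroup).  Simulation
tests use 50–100-tip Yule trees with 100–200 replicates for parameter
recovery (λ monotonicity at generating λ ∈ {0, 0.5, 1}; loss-rate median
within 50 % relative error), and exhaustive-enumeration oracles on ≤4-leaf
trees with ≤6 states.  Divergence indices are exact halves stored as
floats and compared at 1e-9; pruning likelihoods scale per-node to avoid
underflow; posterior vectors renormalise at 1e-9 drift.

## Known limitations

* Branch lengths are Grafen heights, not time-calibrated; rates are "per
  unit tree height" and only rate ratios are comparable across trees.
* No within-species polymorphism, B chromosomes, tandem fusions,
  translocations or centromere repositioning; the rearrangement model sees
  only events that change 2n or arm counts.
* The CTMC has no branch-specific rate variation and no Bayesian variant.
* Outgroup diploid numbers are fixture assumptions from the literature;
  quantities that sum over the whole tree (e.g. total expected fusion
  counts) are sensitive to the taxon set and should be read as
  clade-relative, not absolute.
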