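# karyoevol

Comparative cytogenetics of chromosome-number evolution on phylogenies,
built around the karyotype data of the Neotropical electric knifefish genus
*Brachyhypopomus* (Gymnotiformes: Hypopomidae).

For fish cytogeneticists and comparative biologists, the package answers
four questions about a set of karyotyped species on a known species tree:

1. **How divergent are the karyotypes?**  The divergence index between two
   karyotypes is `D(a,b) = |Δ2n|/2 + |ΔFN|/2`, where `2n` is the diploid
   number and `FN = 2n + (bi-armed chromosome count)` the fundamental
   number (arm count).  All-pairs matrices are clustered with UPGMA into an
   ultrametric phenogram.
2. **Is chromosome number phylogenetically structured?**  Diploid number is
   treated as a continuous trait under Brownian motion: tip values are
   multivariate normal with covariance `σ²·C`, `C_ij` the shared
   root-to-tip path length.  Maximum-likelihood ancestral states (with
   variances and 95 % CIs) come from the GLS/re-rooting recursion; signal
   is quantified by Pagel's λ (profile ML, likelihood-ratio test vs λ = 0)
   and Blomberg's K (permutation test).
3. **What process drives chromosome-number change?**  Haploid chromosome
   number evolves by a continuous-time Markov chain with gains (fissions,
   `n → n+1`), losses (fusions, `n → n−1`), duplications (`n → 2n`) and
   demi-duplications (`n → 1.5n`).  Eight model families (constant vs
   linear state-dependent rates, with/without duplication) are fitted by
   maximum likelihood (Felsenstein pruning + matrix exponentials) and
   compared by `AIC = 2k − 2 logL`.  Ancestral haploid states (marginal
   posteriors and the jointly most probable assignment) are doubled to
   diploid numbers; stochastic mapping gives per-branch expected event
   counts.
4. **Which rearrangements happened where?**  Robertsonian fusions/fissions
   are read off parent→child diploid changes in pair units; pericentric
   inversions between karyotypes are the bi-armed-pair discrepancy left
   after crediting fusions.

## Worked example

The packaged fixtures carry the published karyotype compilation for eleven
*Brachyhypopomus* species and the species-tree topology with five outgroup
tips (see `src/karyoevol/data/`).

```bash
$ karyoevol divergence --out out/
wrote divergence matrix for 11 taxa to out/
```

The phenogram in `out/upgma_phenogram.nwk` contains two zero-height
cherries — *B. bennetti* + *B. walteri* and *B. pinnicaudatus* +
*B. gauderio* — the two sister pairs whose karyotypes are identical at the
2n/FN level (divergence index exactly 0).

```bash
$ karyoevol asr --out out/ --seed 1
root estimate 46.616 (sigma2=26.846); lambda=1.022 (p=1.89e-05), K=1.841 (p=0.0010)
```

The Brownian-motion root estimate of the diploid number is ≈ 46.6
chromosomes; λ̂ ≈ 1 with a highly significant likelihood-ratio test and
K > 1 mean the trait is at least as phylogenetically structured as pure
Brownian motion predicts — close relatives have similar chromosome
numbers.

```bash
$ karyoevol chromevol --out out/ --seed 1 --restarts 5
best model: CONST_RATE_NO_DUPL (AIC 59.63)
total expected fusions 32.67 (fissions 0.00)
```

Model selection picks the constant-rate, no-duplication family: the fitted
fission rate is ~0 and the fusion rate ≈ 5.2 events per unit tree height,
i.e. chromosome numbers in this clade evolved by fusions alone.  The joint
ancestral reconstruction places 2n = 48 at the *Brachyhypopomus* ancestor,
and `out/branch_events.tsv` carries the per-branch story: one fusion into
clade A, five into clade T, three into node M, two into node K, two on the
*B. hamiltoni* branch, with 17 pericentric inversions separating
*B. brevirostris* from *B. hendersoni* and 3 separating *B. beebei* from
*B. hamiltoni*.

All stages are plain library calls too (`karyoevol.divergence_matrix`,
`karyoevol.bm_ancestral_states`, `karyoevol.select_model`, …); see
`docs/methods.md` for the models, conventions and their assumptions.

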