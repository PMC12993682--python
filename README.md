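# ecoassembly

Null-model inference of microbial community assembly processes, with the
succession statistics used in time-resolved metagenome studies and a
synthetic community simulator that validates the whole stack end to end.

The package was built around a question that arises in engineered
ecosystems such as batch anaerobic digesters: as a community reassembles
after a disturbance (secondary succession), is its trajectory driven by
deterministic selection or by stochastic processes (dispersal and drift)?

## What it computes

For every pair of samples `k`, `m` with relative abundances `f` over a
shared, phylogeny-harmonized taxon set:

**βMNTD** (abundance-weighted beta mean nearest taxon distance), with
`Δ_ij` the cophenetic (patristic) distance between taxa `i` and `j`:

```
βMNTD(k,m) = 1/2 [ Σ_{i: f_ik>0} f_ik · min_{j: f_jm>0} Δ_ij
                 + Σ_{j: f_jm>0} f_jm · min_{i: f_ik>0} Δ_ij ]
```

**βNTI** standardizes βMNTD against a null ensemble obtained by shuffling
taxon labels across the tips of the phylogeny (equivalently, jointly
permuting rows and columns of the cophenetic matrix), by default 999
shuffles:

```
βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)
```

**RC_bray** (abundance-based Raup–Crick Bray–Curtis) ranks the observed
Bray–Curtis dissimilarity within a null ensemble that fixes each sample's
richness and total abundance while drawing membership ∝ occupancy and
individuals ∝ mean relative abundance across the metacommunity:

```
RC_bray = 2·[ (#{null < obs} + ½·#{null = obs}) / reps − ½ ]  ∈  [−1, 1]
```

**Process classification** per sample pair:

| condition                      | process                 |
|--------------------------------|-------------------------|
| βNTI > +2                      | variable selection      |
| βNTI < −2                      | homogeneous selection   |
| \|βNTI\| ≤ 2, RC_bray > +0.95  | dispersal limitation    |
| \|βNTI\| ≤ 2, RC_bray < −0.95  | homogenizing dispersal  |
| otherwise                      | undominated             |

Around this core the package provides: readers for plain TSV abundance
tables and MetaPhlAn-style merged profiles, Newick trees, taxon/tree
harmonization, Hellinger transform, alpha diversity (Shannon, Simpson,
inverse Simpson, Fisher's α), one-way ANOVA + Tukey HSD, per-feature
phase-peak tests with Benjamini–Hochberg FDR control, PERMANOVA/ANOSIM,
PCoA, UPGMA clustering, and a simulator that assembles communities under
each of the five processes (Yule tree, Brownian niche trait, Gaussian
environmental filtering, mass-effect dispersal, pool restriction,
multinomial drift).

## Worked example

```python
from ecoassembly import (
    generate_scenario, cophenetic_distances, infer_assembly, CommunityMatrix,
)

bundle = generate_scenario("variable_selection", seed=3, n_samples=2)
rel = bundle.matrix.data.div(bundle.matrix.data.sum(axis=1), axis=0)
rel_m = CommunityMatrix(rel, mode="relative")
dm = cophenetic_distances(bundle.tree)
res = infer_assembly(rel_m, bundle.matrix, dm, reps=999, seed=3)
print(res[["sample_a", "sample_b", "beta_nti", "rc_bray", "process"]])
```

prints

```
  sample_a sample_b  beta_nti  rc_bray             process
0       S1       S2  9.471236      1.0  variable_selection
```

The two samples were assembled under strong selection toward opposite
environments, so their phylogenetic turnover is far larger than the
taxon-shuffle null expects (βNTI ≈ 9.5 ≫ 2) and the pair is correctly
classified as variable selection.  RC_bray = 1.0 merely confirms the
compositional difference; it is not consulted once |βNTI| > 2.

The same chain runs from the shell:

```
ecoassembly simulate --regime variable_selection --seed 3 --out scenario1/
ecoassembly run --abundance scenario1/abundance.tsv --tree scenario1/tree.nwk \
    --meta scenario1/meta.csv --reps 999 --seed 17 --out results/
```

`results/` then holds per-pair assembly calls, phase-pair aggregates,
diversity tables, phase-peak tests, ordination, a dendrogram, and a run
manifest.

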