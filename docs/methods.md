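# Methods

## Model and procedure

The package infers, for each pair of microbial community samples, which
ecological assembly process dominates the compositional difference between
them.  The inference rests on two null models.

**Phylogenetic null (βMNTD → βNTI).**  The observed statistic is the
abundance-weighted beta mean nearest taxon distance: for each taxon present
in one sample, the patristic distance to its closest relative present in
the other sample, averaged with relative-abundance weights, symmetrized
over the two samples.  Its interpretability rests on one assumption —
*phylogenetic niche conservatism*: closely related taxa have similar
environmental requirements, so communities filtered by similar
environments are phylogenetically closer than chance and communities
filtered by different environments are farther.  The null randomizes
taxon identities across the tips of the tree ("taxa-labels" shuffle).
Because the shuffle is equivalent to jointly permuting rows and columns of
the cophenetic matrix, distances are computed once per analysis and each
null replicate is an index permutation; 999 replicates (the conventional
choice, giving 0.001 resolution) take milliseconds per pair.  βNTI is the
z-score of the observed βMNTD in this ensemble, with the sample (n−1)
standard deviation.

**Compositional null (RC_bray).**  The abundance-based Raup–Crick
procedure asks whether two communities are more or less similar in
composition than expected if membership and abundance were assembled at
random from the metacommunity.  Each null community fixes the observed
richness S and total abundance N of its sample; S species are drawn
without replacement with probability proportional to occupancy (number of
samples containing the species), seeded with one individual each, and the
remaining N−S individuals are drawn multinomially with probability
proportional to the species' mean relative abundance over all samples.
The weighted sampling without replacement is implemented by Gumbel top-k
(exponential races), which is exact and vectorizes.  RC_bray rescales the
rank of the observed Bray–Curtis value to [−1, 1]; ties (|null − obs| ≤
1e-12) count half.  Ties matter in degenerate corners: for two disjoint
richness-1 samples every null pair is again a pair of singletons, so the
null mass sits exactly at the observed value of 1 and RC_bray ≈ 0 — the
index is uninformative there, and the package reproduces that behavior
rather than the intuitive "+1".

**Classification.**  βNTI > +2 → variable selection; βNTI < −2 →
homogeneous selection; otherwise RC_bray > +0.95 → dispersal limitation,
RC_bray < −0.95 → homogenizing dispersal, else undominated.  Boundary
values count as the weaker category (|βNTI| = 2 is stochastic, |RC| = 0.95
is undominated); the boundaries are measure-zero so the convention only
fixes determinism.  When the βNTI null is degenerate — every shuffle gives
the same βMNTD, as happens on a star phylogeny or when two samples contain
exactly the same taxa — `beta_nti` raises by default; the pipeline-level
`infer_assembly` instead records NaN and lets RC_bray partition the pair,
since a configuration equal to every null draw carries no evidence of
selection either way.

**Aggregation.**  Phase-level summaries average βNTI and RC_bray over all
cross-phase sample pairs (9 for three replicate digesters) and classify
the means; per-pair values and labels are always emitted so any other
aggregation can be recomputed.  Within-phase pairs are reported but
excluded from the aggregates.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `reps` | 999 | null replicates for both nulls; p-resolution 1/reps |
| βNTI threshold | 2 | two-sided z-score cutoff for selection |
| RC threshold | 0.95 | rank cutoff for dispersal processes |
| `fdr_q` | 0.05 | Benjamini–Hochberg level for phase-peak tests |
| abundance filters | 0.001 / 0.0002 | relative-abundance cutoffs used in similarity analyses |
| pseudo-count depth | 10 000 | conversion of relative profiles to count-like data; keeps 0.02 % taxa ≥ 2 counts |

One root seed drives everything; each (operation, sample-pair) derives its
own child stream, so results are independent of iteration order and of
which pairs are requested.

## Synthetic community generator

The generator produces the conditions under which the inference stack is
validated: a pure-birth (Yule) tree rescaled to height 1; a niche trait
evolving by Brownian motion along branches (variance σ²·branch length),
which supplies exactly the phylogenetic niche conservatism βNTI assumes; a
lognormal metacommunity abundance distribution (σ = 2.0) giving a
realistic dominance structure with a rare tail; Gaussian environmental
filtering `w_i = exp(−(trait_i − e)² / 2σ_sel²)`; and multinomial sampling
of N individuals per sample (drift).

Dispersal is modelled as mass effects on *realized* individuals: a single
immigrant draw `z ~ multinomial(m·N, p_meta)` is shared by all samples in
a scenario and each sample adds its own local draw `multinomial((1−m)·N,
p_local)`.  The expected composition is the mixture `(1−m)·p_local +
m·p_meta`, but high `m` also correlates the realizations themselves.  This
distinction is essential: two samples drawn *independently* from the same
expected composition are exactly as similar as the Raup–Crick null's own
sampling noise, so no level of expectation-mixing can push RC_bray below
−0.95.  Homogenizing dispersal in the Raup–Crick sense is a statement
about realized individuals being shared, and the generator encodes it
that way.

Regime defaults (sd = standard deviation of tip traits; n = 500 taxa,
depth as given):

| regime | n | σ_sel | environments | mix | depth | pools |
|---|---|---|---|---|---|---|
| variable selection | 500 | 0.2 sd | −sd / +sd alternating | 0 | 5000 | — |
| homogeneous selection | 800 | 0.15 sd | +sd everywhere | 0 | 5000 | n/2 per sample; even SAD (σ=0.5) |
| homogenizing dispersal | 500 | ∞ | — | 0.95 | 5000 | — |
| dispersal limitation | 500 | ∞ | — | 0 | 200 | n/4, disjoint-leaning |
| undominated | 500 | 2 sd | −sd / +sd | 0.3 | 5000 | — |

Two of these defaults deserve explanation.  The pool sizes of 500–800
taxa reflect a statistical fact about pairwise βNTI: its magnitude is
bounded by roughly the square root of the number of independently
weighted non-shared taxa, so on very small trees (~150 tips) the
homogeneous-selection signature (βNTI < −2) is unreachable no matter how
strong the filtering — the negative tail needs the largest pool, and
hundreds of taxa are in any case closer to the species richness of real
metagenomes.  Second, homogeneous selection requires membership turnover
*within* a shared niche: two samples with identical filtering and full
access to the pool converge on the same taxa, which collapses both the
observed and the null βMNTD through shared-taxon zeros.  The regime
therefore gives each sample an independent half-pool (an immigration
lottery) over an even metacommunity, so communities differ in membership
while remaining phylogenetically confined.

### What the generator does and does not emulate

It emulates: phylogenetically conserved habitat filtering of tunable
strength, mass-effect dispersal, species-pool restriction, demographic
drift at finite depth, and a realistic rank-abundance curve.  It does not
emulate: time-series succession dynamics, digester chemistry, explicit
spatial structure, taxon interactions, or profiler/database noise in taxon
assignment.  Passing recovery tests therefore shows that the inference
machinery responds correctly to the processes as defined — not that real
digester data will be classified with the same accuracy, since real data
add measurement noise and violate niche conservatism to unknown degrees.

## Succession statistics

Alpha diversity follows the classical definitions (Shannon in nats;
Fisher's α as the root of S = α·ln(1 + N/α), bracketed root-finding to
|f| < 1e-10, undefined and flagged when S = N).  ANOVA is the classical
sums-of-squares decomposition with explicit contracts for degenerate
inputs (zero within-group variance with between-group spread → F = ∞,
p = 0; all values identical → F = 0, p = 1).  Tukey HSD uses the
studentized range with Tukey–Kramer standard errors.  Phase-peak tests run
per-feature ANOVA across phases (digesters as replicates) on
Hellinger-transformed abundances by default, with BH adjustment across
features.  PERMANOVA and ANOSIM are delegated to scikit-bio, which uses
the (1 + #{perm ≥ obs})/(1 + permutations) p-value.  PCoA is Gower
double-centering with negative eigenvalues reported but excluded from
axes and from the proportion-explained denominator.  UPGMA heights are
recorded as raw average-linkage distances (not halved).  Reported
percentages (e.g. chemical-oxygen-demand reduction) round half-up to the
integer.

For physicochemical phase tables the only replicate structure available is
the three digesters per phase (n = 3 per group); published F statistics
from studies with unprinted repeated measurements are not reproducible
from such tables and are not asserted anywhere in the package.

## Numerical choices

- Taxon matching is exact string equality after whitespace trimming; no
  fuzzy matching (silent fuzzy joins corrupt null models).
- Rows are renormalized after taxon pruning by default (configurable).
- Conspecifics are included in nearest-taxon minima (a shared taxon
  contributes 0); switchable.
- Zero-length branches are allowed; nearest-taxon ties resolve by
  taxon-id order, deterministically.
- RC equality tolerance 1e-12; βNTI degenerate-null threshold sd < 1e-12.
- CSV output at 6 significant digits; all randomness from
  `numpy.random.Generator` seeded per (operation, pair).

## Validation suite sizes

The shipped validation runs use 100 instances for each null-calibration
experiment (150-taxa trees, 999 replicates), 20 two-sample scenarios per
regime for parameter recovery at the regime defaults, and 200 runs of 8
samples for permutation-test type-I error — sizes chosen so the complete
suite runs in a few minutes on one core while leaving the binomial
uncertainty of each estimated rate well inside its acceptance band.

## Known limitations

- Pairwise βNTI is weakly powered for homogeneous selection on small
  trees; aggregate (phase-level) means are more stable than single pairs.
- RC_bray inherits the discreteness of Bray–Curtis at very low richness;
  values for richness ≤ 2 samples should not be over-interpreted.
- The incidence-based Raup–Crick variant is not implemented; the
  abundance-based form is the one consistent with partitioning drift vs
  dispersal on abundance data.
- MetaPhlAn parsing covers merged profiles at a single rank; BIOM files
  and taxonomy-aware aggregation beyond one rank are out of scope.
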