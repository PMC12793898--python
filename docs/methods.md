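# Methods

## What the package computes

`epimsap` analyses Methylation-Sensitive Amplified Polymorphism (MSAP)
fingerprints — the AFLP-like, reference-free assay in which genomic DNA
is digested in parallel with the isoschizomers HpaII and MspI. Both
enzymes cut 5′-CCGG-3′, but they are blocked by different CpG
methylation configurations, so the joint presence/absence of an
amplified fragment across the two digests encodes the methylation state
of its CCGG site:

| HpaII | MspI | state | reading |
|-------|------|-------|---------|
| 1 | 1 | NMT | non-methylated |
| 1 | 0 | HMM | hemimethylated (one strand) |
| 0 | 1 | ICM | internal cytosine (CpG) methylation |
| 0 | 0 | HPM | hypermethylated (conservative reading of double absence) |

Any unscored digest cell yields MISSING. The four non-missing states
partition {0,1}² exactly, and the classification is a total function —
this is asserted, not assumed, by the test suite.

## Scoring pipeline and its thresholds

1. **Peak filtering** (`binarize_peaks`): fragments between 50 and
   1500 bp with intensity strictly above 40 RFU are kept. Loci are
   fixed-width 1 bp fragment-size bins anchored at integer sizes; the
   bin width is configurable because capillary sizing precision varies
   by instrument.
2. **Prevalence filter** (`filter_prevalence`): loci present (in either
   digest) in ≥ 15 % of samples are retained, inclusive at the
   boundary. Pooled-across-digests presence is the default; a
   per-digest variant exists. Note a consequence that matters for
   interpretation: loci that are hypermethylated in almost every sample
   produce almost no fragments and are removed by this filter, so the
   retained HPM fraction is bounded by the prevalence threshold.
3. **State classification** (`classify_states`): the truth table above.
4. **MSL partition** (`partition_msl`): a locus is methylation-
   susceptible (MSL) when its methylated-state frequency (HMM, ICM or
   HPM among scored samples) exceeds 5 %, the conventional error
   threshold for MSAP scoring; loci are flagged polymorphic when ≥ 2
   distinct states are observed. Only MSL feed the statistics.
5. **Encoding** (`encode_matrix`): `METH_BINARY` (default; 1 =
   methylated state) or `ONEHOT4` (four indicators per locus in the
   fixed order NMT, HMM, ICM, HPM). MISSING cells are mean-imputed at
   encoding time only — never during state counting or diversity
   estimation, which would bias frequencies.

## Diversity

Shannon's index per MSL, H = −Σ p_s ln p_s over the four state
frequencies among scored samples, bounded by [0, ln 4]. The summary is
the mean ± SD across loci (a per-sample reduction is available, since
either aggregation is found in the MSAP literature). Natural log is the
default base and configurable.

## Distance-based statistics

All multivariate machinery is implemented in `multivariate` on one
algebraic backbone, the Gower-centered inner-product matrix
G = −½ J D² J with J = I − n⁻¹11′:

- **PERMANOVA** — sequential (Type-I) partition of tr(G) over design
  projectors; pseudo-F per term = (SS/df)/(SS_res/df_res); p by free
  permutation of sample identities with the add-one convention
  p = (1 + #{F* ≥ F})/(1 + n_perm). Permuted statistics that tie the
  observed F (within 1e-12) count as exceedances, which makes the
  sampled p converge to the exhaustive-enumeration p; an
  `exhaustive=True` mode enumerates all n! relabelings (n ≤ 9) and is
  tested against a brute-force oracle.
- **PCoA** — eigendecomposition of G; negative eigenvalues from
  non-Euclidean dissimilarities are dropped by default, kept for
  inspection with `correction="NONE"`, or removed by the Lingoes
  additive constant. Explained fractions are relative to the sum of
  positive eigenvalues.
- **PERMDISP** — distances to group centroids in the PCoA embedding,
  with negative-eigenvalue axes entering the squared distance with a
  minus sign (the standard dispersion construction); one-way F on the
  distances, permutation p by shuffling distances across groups.
- **dbRDA** — regression of the positive-axis PCoA coordinates on
  centered predictors; constrained fraction = constrained inertia /
  total inertia; overall and marginal (leave-one-predictor-out) tests
  by permutation of samples (default) or of reduced-model residuals.
- **RDA partitioning** — sequential projection of a response matrix
  onto term subspaces, reported as fractions of total variance.

The default dissimilarity for methylation matrices is Euclidean on the
`METH_BINARY` encoding: it keeps PCoA exact (no negative eigenvalues)
and matches common MSAP practice. Jaccard and simple matching are
available for binary data.

## DAPC and influential loci

PCA reduction to k − 1 components (k = number of a-priori groups; the
grouping factor is always passed explicitly, following the significant
PERMANOVA terms — there is no unsupervised k selection), then linear
discriminant axes from the generalized eigenproblem S_b w = λ S_w w,
ridge-stabilised when the within scatter is singular. Two discriminant
axes are retained by default. Discriminant directions are
back-projected through the PCA rotation; loadings are reported as
squared contributions normalised to sum to 1 per axis, making the
percentile rule scale-free. Influential loci are those whose maximum
per-axis loading reaches the empirical 90th percentile (ties at the
boundary all included); a threshold-free "above mean loading" rule is
provided as an alternative, since percentile and fraction-reported
conventions both occur in the DAPC literature and select very
different set sizes (~10 % vs roughly half of the loci).

## Plasticity coupling

For each pair of sample groups (same site across seasons, transplant
phases within a destination, or all pairs), the statistic takes the
Euclidean distance between group centroids in PCoA space of the
methylation profiles (all positive axes by default; the axis count is
configurable) and the absolute difference of group mean
log(x+1)-transformed righting times, then rank-correlates the two
lists with Spearman's ρ (average ranks for ties). For ≤ 8 pairs the
two-sided p comes from the exact permutation distribution (all n!
rank permutations); otherwise the t-approximation is used. Fewer than
3 pairs yields an explicitly flagged undefined result, never a silent
NaN. The phenotype space is univariate (righting time) by default; a
righting + diameter variant exists but is off by default.

## Field metrics

Sedimentation rate = dry mass / (π r² · days) for a trap of 6.4 cm
aperture; N:P status with the Redfield 16:1 and P-limitation 22:1
boundaries (≤ 16 nitrogen-limited, (16, 22] transition, > 22
P-limited); dry season January–April, wet May–November (December is
outside the sampling design and rejected); urchin size classes
small < 40 mm ≤ medium ≤ 60 mm < large; belt-transect density
count/area with mean ± SD over replicate transects; chained monthly
survival SR_t = N_t/N_{t−1}, whose product telescopes to the terminal
fraction — an identity the tests verify.

## The synthetic generator

`synthetic_data` emulates the structure of the field survey so every
stage has known ground truth:

- **States.** Each locus has a dominant state drawn from an HPM-heavy
  prior (0.10, 0.20, 0.12, 0.58 over NMT, HMM, ICM, HPM) at a
  Beta(20, 3)-distributed frequency, the remaining mass spread over the
  minor states. This dominant-state model — rather than a symmetric
  Dirichlet — produces the strongly skewed per-locus profiles of real
  MSAP fingerprints (per-locus Shannon diversity ≈ 0.48 ± 0.18 before
  filtering) and leaves hypermethylation the most frequent state after
  the prevalence filter, then hemimethylation.
- **Group structure.** Each design cell (site × season or site ×
  transplant phase) receives a latent displacement score v = season
  main effect (±1) + site effect (±0.1, i.e. an order of magnitude
  weaker) + N(0, 0.5) jitter. 20 % of loci are "responsive": their
  prior is blended toward a locus-specific target state with weight
  0.3·|v| (capped at 1), toward one target for v > 0 and another for
  v < 0, the two targets always differing in methylation class so the
  shift is a gain or loss of methylation.
- **Digest bits.** States are mapped back through the exact inverse of
  the classification table and digest bits are flipped independently
  at a 2 % error rate, so generated data exercises the scoring stage
  rather than bypassing it. At zero noise, scoring recovers the truth
  matrix exactly.
- **Phenotypes.** Log righting time = log(20 s baseline) +
  0.4·c·v(group) + 0.01·sedimentation + γ·(diameter − 55 mm) +
  N(0, 0.25), with diameter ~ N(55, 10) mm and γ tuned analytically
  (via the Gaussian rank-correlation identity r = 2 sin(πρ/6)) so the
  realized Spearman correlation with diameter approaches the target
  0.3 at large n. The coupling strength c (default 0.9) scales how
  strongly the group's mean phenotype shift follows the same latent
  that displaced its methylation profile. Uncoupled phenotypic
  variation is individual-level by default; an optional
  `pheno_group_noise_sd` adds uncoupled group-level heterogeneity.
  This choice is deliberate: if uncoupled *group-level* noise is drawn
  at the latent's own scale, the rank correlation between the two
  pairwise-distance lists is capped near 0.7–0.8 even with perfectly
  measured epigenetic distances, because |pairwise differences| of a
  contaminated 1-d latent are rank-unstable for close pairs. With
  individual-level noise the coupling is recoverable, and at c = 0 the
  group phenotype shifts carry no epigenetic signal, so the null
  calibration of the coupling test is still exercised.
- **Transplant cohorts.** Binomial thinning of caged cohorts
  (default 14 per cage) with per-month survival probabilities; the
  survival-series estimator applied to the output recovers the product
  of the monthly probabilities within binomial error.

What the generator does **not** emulate: linkage or shared restriction-
site structure between loci (loci are independent given the group),
fragment-size co-migration artifacts, PCR competition between
fragments, and population-genetic (non-methylation) sources of 0/0
patterns. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the declared generative
model, not robustness to those artifacts in field data.

## Problem sizes and numerical choices

Simulation-based checks use the study-scale defaults: 20 samples per
group, 300 loci, 999 permutations, 100 seeds for power/recovery rates
and 500 replicates for type-I-error rates — sizes at which all checks
complete in well under a minute each on one CPU. Permutation p-values
use the add-one convention and an explicit integer seed everywhere;
permuted-vs-observed ties count as exceedances (1e-12 slack). Hat
matrices are pseudo-inverse based, so rank-deficient (collinear)
design blocks contribute zero added rank rather than failing.
Eigenvalues below 1e-10 of the leading eigenvalue are treated as null
axes in PCoA; DAPC ridge-stabilises a singular within-group scatter
with a warning. Degenerate inputs (empty peak tables, all-zero
distance matrices, all-missing loci, singleton groups) warn and
degrade explicitly rather than raising, except where a result would
be meaningless (fewer than 3 coupling pairs, a single-level factor,
a zero-variance predictor — each a named error).

## Known limitations

- The influential-locus rule reproduces the *procedure* (90th loading
  percentile), not any particular published selected fraction; the
  two implemented rules bracket the plausible conventions.
- PERMANOVA permutation is free exchange only; restricted/strata
  schemes are out of scope.
- dbRDA has no conditioning (partial) matrices.
- The exact Spearman p is enumerated only up to n = 8 pairs; beyond
  that the t-approximation applies.
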