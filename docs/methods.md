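# Methods

## The problem

Environmental DNA surveys of microbial communities read a mixture of two
pools: DNA inside intact cells (a proxy for the living community) and
extracellular "relic" DNA released by lysis or secretion, which can
persist sorbed to the matrix long after its source population is gone.
In slowly changing habitats such as decaying deadwood, the relic pool
carries a memory of earlier successional states, so a total-DNA extract
over-reports richness and blurs stage-to-stage community turnover — the
*masking effect*.  `relicdna` analyses amplicon (ASV) count tables
stratified by an ordered decay-stage factor and three DNA fractions per
sample (intracellular, extracellular, total), and tries to identify taxa
whose extracellular DNA has outlived their populations.

## Detection model

The unit of presence is the *sample group*: one (stage, DNA type)
combination observed in replicate logs.  An ASV is detected in a group
when it is present in at least `min_samples` (default 2) of the group's
samples **and** its reads summed over the group reach `min_reads`
(default 5).  The read floor is applied to the group sum rather than per
sample: the rule is paired with a prevalence clause, which a per-sample
floor would make redundant at small counts.  Filtering retains ASVs
detected in ≥1 group but never alters their counts — detection is a
separate boolean layer, so sub-threshold reads remain visible to the
abundance-based statistics.

An ASV counts as present in a *stage* when it is detected in at least
one of that stage's DNA-type groups.  Within a stage the three DNA-type
groups give 8 detection patterns mapped to 7 Venn labels (`intra`,
`extra`, `total`, `in/ex`, `in/tot`, `tot/ex`, `core`) plus `absent`.

## Persistence detection

Because decay stages cannot be followed through time on one log,
persistence is inferred cross-sectionally.  Candidates are ASVs whose
stage set is exactly one *adjacent* pair (earlier, later); restricting
to adjacent pairs keeps the direction of time unambiguous at the cost of
missing events whose carryover stays detectable beyond the next stage
(an `all_pairs` option relaxes the adjacency requirement but not the
exactly-two rule).  Per candidate, three flags:

* **intra decline** — median per-sample read proportion in the
  intracellular fraction strictly lower in the later stage (ties are not
  a decline);
* **intra extinct, extra present** — not detected in the later stage's
  intracellular group while detected in its extracellular group;
* **extra exceeds intra** — later-stage extracellular relative abundance
  above the intracellular one.

Relative abundance is the per-sample proportion over retained ASVs,
summarised as the group median (mean available via `agg="mean"`); the
median matches how replicate-level read proportions are conventionally
reported and is robust to one aberrant log.

## Synthetic communities

The generator plants a known truth to validate the machinery:

| parameter | meaning | default |
|---|---|---|
| `n_asvs` | founding richness (held constant by balanced colonisation) | 300 |
| `n_stages`, `n_logs` | design size | 3, 3 |
| `depth_range` | uniform per-sample read depth (reads) | 4,608–11,715 |
| `succession_rho` | stage-to-stage log-abundance correlation | 0.5 |
| `turnover_tau` | per-stage extinction probability | 0.3 |
| `retention_lambda` | per-stage extracellular carryover factor | 0.5 |
| `mix_mu` | extracellular share of the total pool | 0.5 |
| `overdispersion_theta` | Dirichlet concentration of replicate noise | 50 |

Stage-one log-abundances are standard normal; later stages follow the
AR(1) update `x' = ρx + √(1−ρ²)ε` with absorbing extinction at rate τ,
each realised extinction balanced by a fresh colonising ASV (new
identifier, never a revival), so richness is exactly stable and planted
extinctions are unambiguous.  Proportions are a softmax over extant
ASVs.  The extracellular pool is a geometric superposition
`u[d] = Σ_{k≤d} λ^{d−k} p[k]` (normalised); carryover decays with stage
index, not calendar time, because decay classes are ordinal.  The total
pool is the convex mixture `(1−μ)p + μe`; μ = 0.5 reflects comparable
intra- and extracellular DNA yields.  Reads are Dirichlet-multinomial:
a replicate composition from Dirichlet(θ·p) restricted to the support
of p (structural zeros are never resampled, so planted extinctions
cannot leak reads), then a multinomial at the drawn depth.  A planted
extinction is a *persistence event* when its expected extracellular
signal at the stage of death clears the 5-read detection floor at the
median drawn depth.

What the generator does not emulate: taxonomic structure in the
dynamics (lineages are assigned independently of abundance), chimeras
and primer artifacts, spatial heterogeneity within a log, and
fraction-specific extraction biases.  Passing tests therefore show that
the algebra and statistics behave as specified under a plausible noise
model — not that real deadwood data meet these assumptions.

## Community statistics

Implemented from first principles and cross-checked against independent
implementations in the test suite:

* **Distances**: Bray–Curtis on counts, Jaccard on presence/absence,
  Euclidean on CLR coordinates (Aitchison geometry).  Two all-zero
  samples get distance 0 with a warning.
* **CLR**: `z = log(x+c) − mean log(x+c)` per sample, default
  pseudocount c = 0.5; c = 0 is accepted only for strictly positive
  tables.  CLR is used as the working compositional coordinate system;
  ilr coordinates are an orthonormal rotation of it and lead to the same
  distances, R² and test statistics wherever they are used here.
* **PERMANOVA**: Gower-centered inner-product matrix; sequential
  (Type-I) sums of squares via nested orthogonal projectors
  (QR-based, rank-aware, so aliased terms are reported by name); free
  permutation of sample labels with `p = (1+exceedances)/(1+n_perm)`
  (never zero); exact enumeration of all n! permutations for tiny
  designs, where p = exceedances/n! includes the identity.  Restricted
  (within-log) permutation is deliberately not used.
* **Variance partitioning**: redundancy-analysis R² of multivariate CLR
  data on dummy predictors; Ezekiel adjustment
  `1 − (1−R²)(n−1)/(n−p−1)`; unique fractions from nested-model
  differences, so `R²_{A∪B} = unique_A + unique_B + shared` holds to
  machine precision.  Adjusted R² is reported as undefined when
  `n ≤ p+1`.
* **Procrustes/PROTEST**: both configurations column-centered, scaled
  to unit sum of squares, zero-padded to equal width;
  `m² = 1 − (Σ singular values of XᵀY)²`, correlation `√(1−m²)`;
  p by row permutation of one configuration.
* **PCoA**: eigendecomposition of the Gower matrix; all eigenvalues
  (including negative ones) reported, coordinates built only from
  positive axes.  PCoA replaces non-metric MDS as the ordination:
  deterministic and testable through closed-form identities, while
  ordination concordance is itself monitored via Procrustes.
* **Richness**: bias-corrected Chao1,
  `S_obs + f₁(f₁−1)/(2(f₂+1))`, with its classic variance, on per-group
  pooled counts.  This replaces model-based richness estimation;
  richness comparisons are treated as qualitative.
* **Differential abundance**: per-ASV least squares of CLR values on
  stage dummies, per-coefficient t tests, Holm step-down across the
  full ASV × coefficient family (family-wise error control);
  zero-variance ASVs get p = 1.  This is a deliberately transparent
  substitute for Monte-Carlo Dirichlet GLM frameworks; an effect is a
  mean CLR shift, interpretable as a log-fold change relative to the
  sample's geometric mean.

## Numerical and degenerate-case conventions

Proportion vectors must sum to 1 within 1e-9; λ = 0 and μ = 0 reduce to
exact identities (no renormalisation round-off).  Rank decisions in
projector construction use a relative 1e-10 threshold on QR diagonals.
Permutation p-values are reproducible under a fixed seed; the pipeline
derives per-stage seeds from one master seed by hashing the stage name,
so stages can be re-run in isolation.  Fold changes with a zero
denominator are reported as NaN, never raised as errors; Kruskal–Wallis
on identical richness values returns p = 1.

## Validation design and known limitations

Planted-truth recovery is scored on the candidate scope: sensitivity is
the fraction of planted persistence events that fall within the
adjacent-pair candidate definition and are flagged extinct-with-extra
(the candidate rule itself is a scoping choice that knowingly misses
events whose carryover persists beyond the next stage).  Precision is
the fraction of extinct-with-extra flags matching planted events.  At
the validation settings (300 ASVs, θ = 50), the per-ASV Dirichlet
concentration θ·p is ≈ 0.17 for a median-abundance ASV, which makes
single-replicate presence nearly a coin flip even for ASVs with
expected double-digit read counts; a substantial share of flags
therefore lands on extant-but-undetected ASVs, and precision is
intrinsically limited by replicate overdispersion rather than by the
algebra.  This is a real property of group-level detection at n = 3
replicates, worth bearing in mind when interpreting extinct-with-extra
counts on field data.

Problem sizes used in the routine validation runs (chosen to exercise
the statistics at the study's own design scale): 27-sample designs
(n = 300 ASVs) for pipeline runs, 1000 and 500 simulated datasets for
the PERMANOVA and PROTEST null calibrations, 500 replicates for the
family-wise-error check, and 10–20 generator seeds per condition for
recovery and monotonicity checks.
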