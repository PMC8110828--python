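# relicdna

Analysis of amplicon (16S ASV) count tables stratified by an ordered
habitat-succession factor and three DNA fractions per sample —
**intracellular** (intact cells, proxying the living community),
**extracellular** ("relic" DNA persisting outside cells) and the
**total** DNA pool.  The motivating system is bacterial succession in
decaying deadwood, where extracellular DNA can outlive its source
populations and *mask* the living community in total-DNA surveys.

The package provides:

* the group-level detection rule (present in ≥2 of a group's replicate
  samples, ≥5 reads summed over the group) and dataset filter;
* Venn set algebra across decay stages and DNA types (`intra`, `extra`,
  `total`, `in/ex`, `in/tot`, `tot/ex`, `core`), sample-group occurrence
  distributions and taxon-class frequency comparisons;
* extracellular-persistence detection: for ASVs confined to one adjacent
  stage pair, flags for intracellular decline, intracellular extinction
  with extracellular carryover, and extracellular excess;
* community statistics from first principles: Bray–Curtis/Jaccard/
  Aitchison distances, PERMANOVA (McArdle–Anderson sequential SS, free
  label permutation, exact enumeration on tiny designs), redundancy
  variance partitioning, Procrustes/PROTEST, PCoA, bias-corrected Chao1,
  and CLR-based differential abundance with Holm family-wise control;
* a Dirichlet-multinomial community generator with planted succession,
  extinction and carryover — the ground truth the detection machinery is
  validated against.

The core quantities: detection `D[a, g] = 1{#{s ∈ g : x_as > 0} ≥ 2 ∧
Σ_{s∈g} x_as ≥ 5}`; extracellular carryover `u_d = Σ_{k≤d} λ^{d−k} p_k`
(geometric retention λ), total pool `t_d = (1−μ) p_d + μ e_d`; PERMANOVA
pseudo-F from the Gower-centered matrix of squared distances; Procrustes
`m² = 1 − (Σ σ_i(XᵀY))²` with correlation `√(1−m²)`; Chao1
`S_obs + f₁(f₁−1)/(2(f₂+1))`.  See `docs/methods.md` for the full model
description and `docs/replication.md` for mapping the original deposited
reads (SRA BioProject PRJNA682981) into the pipeline.

## Worked example

```python
from relicdna import (GeneratorConfig, generate_dataset, filter_table,
                      venn_assignment, candidate_asvs, assess_persistence,
                      masking_summary, jaccard, permanova)

table, meta, taxonomy, truth = generate_dataset(GeneratorConfig(seed=1))
filtered, det = filter_table(table, meta)
print(table.n_asvs, "->", filtered.n_asvs)            # 486 -> 358

res = permanova(jaccard(filtered),
                {"stage": meta.table["stage"].astype(str),
                 "dna_type": meta.table["dna_type"]},
                interaction=True, n_perm=999, seed=1)
print(res.table.round(3))

venn = venn_assignment(det, filtered, meta)
report = assess_persistence(candidate_asvs(venn, meta.stages),
                            filtered, det, meta)
print(masking_summary(report, det, meta))
```

Output (seed 1):

```
486 -> 358
                   SS  df  pseudo_F     R2      p
term
stage           2.339   2     7.254  0.359  0.001
dna_type        0.474   2     1.469  0.073  0.071
stage:dna_type  0.796   4     1.234  0.122  0.121
                               value
quantity
n_candidates                      85
n_intra_decline                   47
n_intra_extinct_extra_present     39
n_extra_exceeds_intra             52
richness_inflation_I               2
richness_inflation_III            23
richness_inflation_V               1
```

Of 486 simulated ASVs, 358 survive the detection filter.  Decay stage
explains ~36 % of the Jaccard-distance variance (p = 0.001) while DNA
type explains ~7 % — succession dominates, with the DNA fractions of one
stage remaining similar, as expected when half the total pool is a
carryover-smoothed copy of the living community.  The masking summary
counts candidate ASVs, intracellular decliners, and ASVs whose DNA
persists extracellularly after the population is no longer detected.

A command-line interface mirrors the stages
(`relicdna simulate|filter|setanalysis|persistence|stats|run`); `run`
executes the whole pipeline from a YAML config with one master seed and
writes a content-hash manifest.

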