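# Replicating the original deadwood bacteriome analysis

The pipeline's design follows a field study of bacterial communities in
decaying European beech logs, sampled across three decay classes (I, III,
V) with three DNA fractions per log (intracellular, extracellular, total)
and three replicate logs per class.  The raw 16S rRNA gene amplicon reads
of that study are deposited in the NCBI Sequence Read Archive as
BioProject **PRJNA682981**
(<https://www.ncbi.nlm.nih.gov/bioproject/PRJNA682981/>).

This recipe documents how to feed those reads through an external
denoiser into `relicdna`.  It is documentation, not an automated test:
read download and denoising are outside the package's scope, and the
numbers quoted below are the values reported for the original dataset —
what each stage *would* emit given faithful upstream processing, not
values this repository recomputes.

## 1. Obtain and denoise the reads (external)

```bash
# fetch runs for the BioProject (requires sra-tools)
prefetch PRJNA682981 && fasterq-dump --split-files SRR*

# denoise with DADA2 (R/Bioconductor) into an ASV table:
#   filterAndTrim -> learnErrors -> dada -> mergePairs ->
#   makeSequenceTable -> removeBimeraDenovo
# assign taxonomy against SILVA v.138, then export:
#   counts.tsv   ASV x sample integer matrix
#   taxonomy.tsv asv_id + domain..genus columns
```

Build `metadata.tsv` from the SRA run annotations: columns `sample_id`,
`log_id` (replicate log), `stage` (`I`/`III`/`V`), `dna_type`
(`intra`/`extra`/`total`); 27 samples, 9 sample groups of 3.

After denoising, the original dataset comprises 1,946 ASVs with
per-sample depths spanning roughly 4,6k-23k reads.

## 2. filter — group-level detection

```bash
relicdna filter --counts counts.tsv --meta metadata.tsv \
    --min-samples 2 --min-reads 5 --out out/
```

Expected for the original dataset: **1,946 -> 623 retained ASVs** in
`filtered_counts.tsv`, with the boolean layer in `detection.tsv`.

## 3. setanalysis — set algebra

```bash
relicdna setanalysis --counts out/filtered_counts.tsv \
    --meta metadata.tsv --taxonomy taxonomy.tsv --out out/
```

Expected stage-Venn counts (`venn_stage.tsv`): **17 core ASVs** detected
in all three decay classes; **15, 2 and 77 ASVs** unique to classes I,
III and V.  Expected occurrence histogram
(`occurrence_histogram.tsv`): **285 ASVs in exactly one sample group,
126 in two, 114 in three**; of the two-group ASVs, **74/126**
intra+extra of the same class, **22/126** total+extra, **15/126**
total+intra, **15/126** across classes; of the three-group ASVs,
**98/114** all DNA types of one class.

## 4. persistence — extracellular carryover

```bash
relicdna persistence --counts out/filtered_counts.tsv \
    --meta metadata.tsv --out out/
```

Expected (`masking_summary.tsv`): **40 candidate ASVs** (24 detected in
classes I+III, 16 in III+V), **19** with declining intracellular
relative abundance, **5** undetected intracellularly in the later class
while present extracellularly, **16** with extracellular exceeding
intracellular relative abundance in the later class; candidate overall
rank positions between 10 and 234.

## 5. stats — community statistics

```bash
relicdna stats --counts out/filtered_counts.tsv --meta metadata.tsv \
    --perms 999 --seed 1 --out out/
```

Expected orders of magnitude on the original dataset (permutation-based,
so approximate): decay class explaining ~48% of Jaccard-distance
variance, DNA type ~10%, interaction ~21% (`permanova.tsv`), and a
CLR-PCA vs Bray-Curtis-PCoA Procrustes correlation near 0.95
(`procrustes.tsv`).  Exact agreement is not expected: the original
analysis used NMDS rather than PCoA and a different richness estimator,
and permutation p-values are stochastic.
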