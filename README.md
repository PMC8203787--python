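# yloss

Lung cancer kills more men than women, and men fare worse even after
accounting for stage, age and histology. One candidate mechanism is somatic
loss of the Y chromosome (LOY) in tumour cells — in particular loss of the
Y-encoded H3K4me3 demethylase **KDM5D** — which co-occurs with genome-wide
autosomal DNA hypomethylation and marks a male patient group with markedly
worse survival.

`yloss` re-implements the full inference chain behind that finding as a
tested, reusable pipeline for paired tumour/normal expression cohorts:

1. **Co-expression networks.** Unsigned weighted networks from the biweight
   midcorrelation: adjacency `a_ij = |bicor(x_i, x_j)|^β` (β = 5), the
   topological overlap matrix
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   quantile-matched TOM scaling (q = 0.95) with an entrywise-minimum
   **consensus** across tissues, adaptive (dynamic) tree cut of the
   average-linkage 1 − TOM dendrogram, module eigengenes (PC1), module
   merging below eigengene dissimilarity 0.25, module–trait `bicor`
   (robustY = FALSE, maxPOutliers = 0.05), kME module membership, and
   Fisher-exact tissue-specificity of single-tissue modules against the
   consensus.
2. **Loss of chromosome Y.** A low-Y expression cluster among male tumours
   (threshold + dendrogram-branch call on the sex module's Y panel:
   DDX3Y, EIF1AY, KDM5D, RPS4Y1, TXLNGY, USP9Y, UTY); read-depth
   quantification `d = reads / (kb × library size) × 10⁹` with
   `%LOY = 100·max(0, 1 − median_g d_T/d_N)`; Wilcoxon/Hodges–Lehmann
   paired depth tests; PCR amplification **Y-index** summaries; rank-based
   two-group location tests.
3. **Methylation.** Per-sample median CpG methylation restricted to
   autosomes, Shapiro–Wilk-gated paired/unpaired comparisons, a
   single-replicate-capable smoothed Wald **DMR caller**
   (|Δ| > 20 points, P < 0.001), and 1-kb-promoter intersection.
4. **Survival.** KDM5D deficiency (tumour expression ≥ 1.5 SD below the
   male mean), multivariate Cox proportional hazards (Efron ties) over age,
   sex, histology, smoking, stage and the deficiency indicator,
   Kaplan–Meier curves, and a variance-weighted (Vuong-type) likelihood
   ratio comparison of non-nested Cox models.
5. **Synthetic cohorts.** A generator that plants every effect above — a
   39-transcript gonosomal sex module, a module degraded in tumour tissue,
   a 28% low-Y male-tumour subset with cell fraction *f* of Y loss,
   coincident autosomal hypomethylation, and exponential survival with a
   planted deficiency hazard — and returns the truth labels, so every
   stage can be validated by recovery rather than by eye.

## Worked example

```python
from yloss import pipeline
from yloss.simulate import SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(seed=1))   # 237 samples, 126 patients
filtered_t = pipeline.stage_filter(cohort["tumour"])
filtered_n = pipeline.stage_filter(cohort["normal"])
common = filtered_t["expression"].transcripts.intersection(
    filtered_n["expression"].transcripts)
tumour = filtered_t["expression"].subset_transcripts(common)
normal = filtered_n["expression"].subset_transcripts(common)

nets = pipeline.stage_network(tumour, normal, cohort["metadata"])
module = pipeline.sex_module_transcripts(
    nets["trait_association"], nets["normal"].labels, normal.annotation)
loy = pipeline.stage_loy(tumour, normal, cohort["metadata"], module,
                         cohort["coverage"])
meth = pipeline.stage_methylation(cohort["methylation"], cohort["metadata"],
                                  loy["low_y_calls"])
surv = pipeline.stage_survival(cohort["tumour"], cohort["metadata"],
                               loy["low_y_calls"])
```

prints (via the stage tables) on this seed:

```
sex-associated module: ME1 (bicor 0.81, P 2.43e-27, nObs 113)
low-Y male tumours: 18/65 (27.7%)
median %LOY in flagged tumours: 80.3
paired autosomal methylation change (low-Y): -10.48 [-10.82, -10.26] percentage points, wilcoxon P 2.77e-04
KDM5D deficiency hazard ratio: 4.88 [2.16, 11.01], P 0.000
```

Reading this: the normal-tissue network contains one module strongly
associated with biological sex; 18 of the 65 male tumours (27.7%) lose
coordinated Y-panel expression; their sequencing depth over Y genes implies
~80% of tumour cells lack the Y (the planted cell fraction); their autosomal
methylation drops by ~10 percentage points relative to paired normal
tissue; and KDM5D-deficient tumours carry a ~5-fold hazard of death after
covariate adjustment (the planted hazard ratio is 3.8; a 126-patient cohort
estimates it with a wide CI).

The same chain runs from the shell:

```bash
yloss run-all --seed 1 --out-dir out/        # simulate + all stages
yloss simulate --seed 1 --out-dir sim/       # or stage by stage
yloss network --tumour sim/tumour_expression.tsv \
              --normal sim/normal_expression.tsv \
              --metadata sim/metadata.csv --out-dir net/
```

Identical config and seed reproduce byte-identical result tables.

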