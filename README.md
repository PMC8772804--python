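# gutpipe

Analysis pipeline for gut-microbiome studies of weight-loss cohorts, centred
on the **Bacteroides 2 (Bact2) dysbiosis enterotype**: from per-read
taxonomic assignments to rarefied abundance tables, Dirichlet-multinomial
mixture (DMM) enterotyping, diversity and ordination statistics, clinical
association models, longitudinal enterotype-transition analysis, pan-genome
functional aggregation, and propensity-matched supplement comparison.

It is written for microbiome researchers who have species-level taxonomic
profiles (e.g. from long-read shotgun classification) plus per-subject
clinical covariates at one or two visits, and who want the complete
baseline + follow-up statistical workflow behind Bact2 epidemiology in a
tested, reproducible form. Because cohort data of this kind are rarely
deposited, the package ships a first-class synthetic-cohort generator with
planted effects, so every stage is verifiable end to end without any
download.

## The model

Genus-level count vectors \(x_i\) (after rarefaction to a common depth
\(d\)) are modelled as a \(K\)-component mixture of Dirichlet-multinomial
distributions:

\[ P(x_i) = \sum_{k=1}^{K} \pi_k \, \mathrm{DirMult}(x_i \mid \alpha_k), \qquad \alpha_k \in \mathbb{R}_{>0}^{J}. \]

Fitting is by EM with responsibility-weighted fixed-point updates of
\(\alpha_k\); the number of components is selected by a Laplace
approximation of the model evidence (weak log-normal prior on
\(\log\alpha\), flat Dirichlet on \(\pi\); BIC-style fallback). Components
are mapped to the canonical enterotype names from their fitted mean
compositions \(\alpha_k / \sum_j \alpha_{kj}\): highest *Faecalibacterium*
share → **Rum**, highest *Bifidobacterium* share → **Bif**, and of the
remaining *Bacteroides*-dominated components the one with the lower expected
Shannon diversity → **Bact2** (the dysbiotic, low-richness configuration),
the other → **Bact1**.

Around the mixture model sit the standard cohort statistics: observed
richness and Shannon entropy on rarefied tables; genus-level Bray-Curtis
dissimilarity with PCoA; univariate and forward-stepwise dbRDA effect sizes
(permutation-tested, Ezekiel-adjusted R²); PERMANOVA with optional
within-subject permutation strata; adjusted linear/logistic regressions with
Benjamini-Hochberg control (logistic `exp(β)` reported on the relative-risk
scale, see `gutpipe.association`); Kruskal-Wallis + Dunn + Cliff's delta
enterotype enrichment; random-intercept mixed models for paired features;
median-split diversity stratification and enterotype transition tests; KO
and metabolic-module aggregation from species pan-genomes; and greedy 1:1
propensity matching with balance diagnostics.

## Worked example

```python
from gutpipe import (AnalysisConfig, GeneratorConfig,
                     generate_cohort, run_baseline_analysis)

cohort = generate_cohort(GeneratorConfig(n_subjects=263, seed=42))
config = AnalysisConfig(seed=42, n_permutations=199)
report = run_baseline_analysis(config, cohort.abundance_v1, cohort.clinical)

print("best K:", report.best_k)
print(report.enterotypes["label"].value_counts().to_string())
row = report.bact2_assoc.set_index("covariate").loc["BMI"]
print(f"Bact2 ~ BMI: RR per unit = {row.rr:.3f} "
      f"(95% CI {row.rr_ci[0]:.3f}-{row.rr_ci[1]:.3f}), p = {row.p_value:.3g}")
```

prints

```
best K: 4
label
Rum      84
Bact1    69
Bact2    58
Bif      52
Bact2 ~ BMI: RR per unit = 1.034 (95% CI 0.966-1.106), p = 0.339
```

The evidence-based model selection recovers the four planted community
archetypes, and the per-sample labels split the cohort into the four
enterotypes (58/263 ≈ 22% Bact2 here, near the 19.4% planted mixture
weight). The logistic association of Bact2 status with BMI is adjusted for
age, sex and recruitment centre; its point estimate sits near the planted
per-BMI-unit relative risk of 1.08, but a single 263-subject cohort is
underpowered for an effect this small — the confidence interval spans 1, and
recovery of the coefficient is demonstrated at N = 2000 in the acceptance
checks. Covariates with no planted link (e.g. the Bristol stool score) carry
uniform p-values, so at ~200 permutations an occasional small p-value in
`report.dbrda` is expected noise.

The same workflow is scriptable from the shell:

```bash
gutpipe generate --seed 42 --n-subjects 263 --outdir cohort/
gutpipe baseline --abundance cohort/abundance_v1.tsv \
    --clinical cohort/clinical.csv --taxonomy cohort/taxonomy.tsv \
    --seed 42 --outdir baseline_out/
gutpipe longitudinal --abundance cohort/abundance_v1.tsv \
    --abundance-v2 cohort/abundance_v2.tsv \
    --clinical cohort/clinical.csv --seed 42 --outdir longi_out/
```

Every written artifact embeds the configuration hash and master seed in a
leading comment line; reruns with identical configuration are bit-identical.

## Input formats

* **Abundance TSV** — taxa × samples (or transposed; declare with
  `--orientation`), integer counts or relative abundances.
* **Clinical CSV** — one row per subject × visit (`V1`/`V2`) with the cohort
  schema (age in years, weight kg, BMI kg/m², waist cm, fat mass %, glycemia
  g/L, insulinemia mIU/L, HOMA-IR, HbA1c %, lipids nmol/L, ASAT/ALAT/GGT
  IU/L, creatinine and uricemia mg/L, Bristol score 1–7, SAS/CPAP/LMP flags);
  the 4-level obesity class is derived from BMI.
* **Taxonomy TSV** — `species_id`, `species_name`, `genus`.
* **Read-assignment TSV** — one row per read with candidate taxon,
  classifier score, confirmation identity, aligned fraction, human flag.
* **Pan-genome TSV** — binary species × KO matrix; **module definitions** in
  a plain-text format (`MODULE<tab>id<tab>name` header, one comma-separated
  KO-alternative step per line, blank-line separated records).

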