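# Methods

This note documents the statistical machinery implemented in `gutpipe`, the
design choices made where the design was genuinely open, what the
synthetic-cohort generator does and does not emulate, and the package's known
limitations.

## Taxonomic consolidation (`gutpipe.taxprofile`)

The pipeline starts from per-read candidate taxonomic assignments — the
tabular output of a long-read classifier plus a per-read alignment
confirmation (identity = fraction of matching bases; aligned fraction =
aligned length / read length). The classifier and aligner themselves are out
of scope.

* **Two-step confirmation filter.** Human-flagged reads are removed
  unconditionally; remaining reads must reach `min_identity` (default 0.80)
  and `min_aligned_fraction` (default 0.50). The defaults are permissive
  enough for long-read error profiles while cleanly separating genuine
  assignments from the low-identity distribution that misassigned reads
  produce; both are configurable. Multi-candidate reads are first collapsed
  to the single highest-scoring candidate, ties broken by lowest taxon id,
  so the filter is deterministic and idempotent.
* **Rarefaction.** Each sample is subsampled *without replacement* to a
  common depth (default 10,000 reads) with one multivariate-hypergeometric
  draw; subsampling without replacement is unbiased for composition and
  standard practice. Samples below depth are excluded and logged rather than
  carried through unrarefied — mixing depths would bias richness.
* **Genus collapse** sums species counts within genus and conserves
  per-sample totals exactly.
* **Feature filter.** A feature is kept iff it reaches 5×10⁻⁴ relative
  abundance in at least 20% of samples (both bounds inclusive). Retained
  features keep their original relative abundances (no renormalization);
  the container marks such tables as `filtered` because their rows no longer
  sum to 1.

## Dirichlet-multinomial mixture enterotyping (`gutpipe.enterotype`)

Genus counts \(x_i\) with depth \(n_i\) follow
\(P(x_i)=\sum_k \pi_k\,\mathrm{DirMult}(x_i\mid\alpha_k)\).

* **EM.** E-step responsibilities
  \(\gamma_{ik}\propto\pi_k\,\mathrm{DirMult}(x_i|\alpha_k)\); M-step sets
  \(\pi_k=\bar\gamma_{\cdot k}\) and updates each \(\alpha_k\) by
  responsibility-weighted fixed-point iterations
  \(\alpha_{kj}\leftarrow\alpha_{kj}
  \frac{\sum_i\gamma_{ik}[\psi(x_{ij}+\alpha_{kj})-\psi(\alpha_{kj})]}
       {\sum_i\gamma_{ik}[\psi(n_i+A_k)-\psi(A_k)]}\)
  (five inner passes per EM step, floor 10⁻¹⁰ for numerical safety with
  empty genera). The fixed point is not provably monotone, so the M-step
  carries a damped safeguard — the step is halved in log space until the
  observed log-likelihood does not decrease — making the trace monotone by
  construction. Convergence: relative log-likelihood change < 10⁻⁶ (default),
  max 500 iterations, followed by a fixed-point polish at the converged
  responsibilities (kept only if the likelihood does not drop), which
  tightens \(\hat\alpha\) on the flat ridge where the likelihood criterion
  trips first.
* **Initialization.** The first restart seeds responsibilities from k-means
  on row-normalized abundances (the DMM likelihood is multimodal and a
  composition-aware start is markedly more reliable than random); the
  remaining restarts (default 5 total) use random responsibilities. Best
  restart by final log-likelihood wins.
* **Model-order selection.** For each K the log evidence is approximated by
  Laplace's method at the fitted optimum:
  \(\log Z \approx \ell(\hat\theta) + \log p(\hat\theta) + \tfrac d2\log 2\pi
  - \tfrac12\log|H|\), with \(d = KJ + (K-1)\) free parameters and \(H\) the
  negative Hessian of the log posterior, assembled analytically: one
  Dirichlet-multinomial block per component (responsibility-weighted,
  evaluated in \(\log\alpha\) space, determinant via the matrix-determinant
  lemma) plus the multinomial block for \(\pi\). The prior is weakly
  informative — \(\log\alpha_{kj}\sim N(0,2^2)\), flat Dirichlet on \(\pi\).
  The prior matters: with a flat (improper) prior the "evidence" lacks an
  Occam factor, over-prefers extra components, and its Hessian becomes
  near-singular for barely-occupied components; the log-normal prior both
  supplies the complexity penalty and regularizes those flat directions. Its
  scale σ = 2 covers Dirichlet parameters from ~0.02 to ~50 within two SDs,
  the plausible range for genus-level mixtures. If a block still fails
  positive definiteness the model falls back to a BIC-style penalty
  \(\ell - \tfrac d2\log N\). Evidence-based and BIC-based selections agree
  on well-separated fixtures; disagreements are logged, not failed.
* **Labeling.** From fitted mean compositions: max *Faecalibacterium* →
  Rum; max *Bifidobacterium* among the rest → Bif; of the remaining
  *Bacteroides*-dominated components, lower expected Shannon → Bact2, other
  → Bact1. A single remaining *Bacteroides*-dominated component is Bact2
  only if its expected Shannon is the minimum across all components.
  Components the rule cannot place, or with tied parameter vectors, become
  `Other_i` with a warning. Marker genus names are configurable. The same
  machinery runs unchanged on species-level tables for robustness checks.

## Diversity and ordination (`gutpipe.ecology`)

* Alpha diversity: observed richness and Shannon entropy (natural log) on
  rarefied tables only — the module refuses unequal row sums.
* Beta diversity: Bray-Curtis on relative genus abundances,
  \(D_{xy}=1-\sum_j\min(p_{xj},p_{yj})\).
* PCoA: classical scaling of the Gower-centered \(-D^2/2\); coordinates for
  positive-eigenvalue axes, negative-eigenvalue mass reported. No
  Lingoes/Cailliez correction by default — constrained analyses use the
  positive axes only, which keeps R² in [0,1] and mirrors common dbRDA
  practice (a correction hook is the natural extension point).
* dbRDA: R² = constrained / total inertia of the positive-axis coordinates
  regressed on the (centered, indicator-expanded) covariate design;
  permutation p against pseudo-F, floored at 1/(n\_perm+1); adjusted R² by
  the Ezekiel formula. Forward selection adds, per step, the candidate with
  the highest cumulative adjusted R² whose partial permutation p ≤ α_in,
  provided the cumulative adjusted R² stays at or below the full-model
  adjusted R² (the standard double stopping rule). Note a real property of
  that ceiling: when the non-selected scope covariates are pure noise, the
  full-model adjusted R² fluctuates symmetrically around the best single
  covariate's value and the ceiling halts selection roughly half the time —
  reference dbRDA implementations behave identically. The rule protects
  against overfitting in scopes whose full model genuinely explains more.
* PERMANOVA: Anderson's partition of squared distances,
  \(F=(SS_A/(a-1))/(SS_W/(n-a))\), permutation p with optional
  within-stratum permutation (used for paired designs, where permutations
  are restricted within subjects — the natural scheme when the question is
  the visit effect net of subject identity). Default 999 permutations
  throughout.

## Association statistics (`gutpipe.association`)

OLS and maximum-likelihood logistic fits (via statsmodels) with
treatment-coded categorical expansion, pairwise missing-data deletion (the
dropped n is logged and `n_used` reported), rank-deficiency detection that
names the collinear columns, and an optional z-scored standardized β.
Logistic `exp(β)` per covariate unit is reported as a **relative risk**,
matching how such coefficients are conventionally communicated in the Bact2
literature; formally it is an odds ratio, and at ~20% outcome prevalence the
two diverge — this is documented rather than silently "corrected".
Quasi-complete separation produces a flagged result, never a silent
estimate. Obesity-class contrasts run against the non-obesity (BMI < 30)
reference. Enterotype-feature enrichment: Kruskal-Wallis with tie
correction, Dunn z-tests for Bact2-vs-other pairs, Cliff's delta
\((\#\{x>y\}-\#\{x<y\})/(n_x n_y)\); BH families are one analysis table per
test type (all features × one contrast). BH adjustment is the classic
step-up.

## Longitudinal analyses (`gutpipe.longitudinal`)

* **Median stratification.** The richness threshold is computed on the full
  baseline cohort and applied to the paired subset (the cohort median is a
  property of all baseline samples, while the paired analyses run on the
  follow-up subset); subjects at or below the median are "low".
* **Fold changes** are ratios V2/V1 (a log option exists); zero baselines
  are excluded with a log entry. Between-stratum comparison uses the
  two-sample rank-sum test — two independent strata cannot be compared by a
  paired signed-rank test, whatever figure captions sometimes say — and
  within-stratum change uses the Wilcoxon signed-rank test; all two-tailed.
* **Transitions.** V1→V2 label counts per stratum; the default test is a
  chi-square on the 2×K visit-by-label prevalence table (treating the two
  visits' margins as the compared distributions); a Stuart-Maxwell
  marginal-homogeneity test on the paired K×K table is available for
  stricter paired inference. Switch fractions are reported as
  numerator/denominator with a rounded percent.
* **Per-feature mixed models.** \(y = \beta_0+\beta_1\,\text{visit}
  + u_{\text{subject}} (+ v_{\text{LMP}}) + \varepsilon\) with random
  intercepts, REML variance components (non-negativity enforced), Wald test
  on \(\beta_1\), BH across the feature family. The optional LMP intake
  factor enters as a second variance component; with fewer than two LMP
  levels the model silently reduces to subject-only (logged). When the
  subject variance collapses to zero the REML solution is the OLS boundary;
  the implementation detects the singular fit and refits by OLS, which is
  the exact profiled solution there (flagged `boundary-ols`).
* **Paired clinical summaries.** Two-tailed paired t-tests per variable
  with star coding (ns/*/**/***/****) at 0.05/0.01/0.001/0.0001; variables
  with fewer than three complete pairs are skipped.

## Functional aggregation (`gutpipe.functional`)

KO abundance is the presence-weighted sum
\(KO[s,k]=\sum_j A[s,j]P[j,k]\) over a binary species × KO pan-genome
matrix; unmapped species are excluded and logged. Modules are scored by the
median-of-steps convention — step abundance = sum over deduplicated
alternative KOs, coverage = fraction of steps with positive abundance,
module abundance = median step abundance if coverage ≥ 2/3 else 0 —
following the established gut-metabolic-module framework; cutoff and
aggregation (median/sum) are configurable. Curated module databases are not
redistributed; definitions are user-supplied in the plain-text format
described in the README, and a generated fixture ships for tests.

## Propensity matching (`gutpipe.matching`)

Logistic propensity scores on the stated covariates (default age, sex,
weight); greedy 1:1 nearest-neighbor matching on the logit-PS scale,
*without replacement*, treated units processed in descending PS order, ties
broken by subject id, optional caliper as a multiple of the logit-PS SD.
Without-replacement semantics are forced by the design this reproduces —
equal-sized exhaustive matched groups (47 per arm from a 47/116 split) are
only possible without replacement. Balance is reported as standardized mean
differences before/after. A caveat of the fixed greedy order: when the
treated arm is the larger one and no caliper is set, the matched treated
subset is the highest-PS half and group balance can worsen; balance
improvement is guaranteed-by-construction only in the canonical
treated ≤ control layout or with a caliper.

## The synthetic cohort (`gutpipe.synthetic`)

The generator emulates the statistical structure the analysis assumes, at
the study's own scale (263 subjects, 163 with a paired visit, 71.5% in the
supplement arm):

* **Community.** 45 species across 16 genera; four Dirichlet-multinomial
  archetypes with mixture weights (0.28, 0.194, 0.33, 0.196) for
  (Bact1, Bact2, Rum, Bif). Bact2 is Bacteroides-heavy with the lowest
  concentration ΣαΒ (25), Bact1 Bacteroides-heavy at 80, Bif
  Bifidobacterium-enriched at 100, Rum Faecalibacterium-enriched at 160.
  Low Σα yields low expected richness and evenness at fixed depth, so the
  dysbiosis-richness link is planted structurally rather than by
  conditioning on realized richness — avoiding circularity when downstream
  stages test that link.
* **Covariates** follow the cohort's published marginal distributions
  (age 50.6 ± 9.9 y, weight 90.5 ± 16.3 kg, BMI 32.8 ± 4.9 kg/m², etc.),
  truncated to physical ranges and the BMI ≥ 25 inclusion criterion; five
  recruitment centers (a 64-center design would exhaust synthetic cell
  counts). Correlations beyond the planted ones are zero — only marginals
  are published.
* **Membership model.** Multinomial logit with planted links: log(1.08) per
  BMI unit toward Bact2; −0.05 per year and +0.8 for women toward Bif.
  Intercepts are calibrated numerically so the cohort-average membership
  probabilities equal the mixture weights despite the covariate links,
  keeping the marginal Bact2 prevalence exactly at its configured value.
* **Paired visit.** V2 labels are drawn from stratum-specific transition
  matrices (supplement consumers leave Bact2 more often); V2 compositions
  apply per-species log-shifts (A. muciniphila +0.5, P. distasonis +0.4,
  M. smithii +0.3, E. rectale −0.5, S. thermophilus −0.4, Bifidobacterium
  lineages −0.3) and a +0.4 concentration log-shift for baseline-Bact2
  subjects (the planted diversity improvement). Clinical V2 rows apply a
  −10% weight change and published mean shifts for the other variables with
  proportional noise; no richer within-subject covariate evolution model is
  attempted because none is published.
* **Reads and pan-genome.** Per-read tables plant false positives at a
  configurable rate with low identity/coverage distributions
  (N(0.60, 0.08) / N(0.40, 0.10)) against true-read distributions
  (N(0.92, 0.04) / N(0.80, 0.10)), plus human-flagged reads; the pan-genome
  is Bernoulli presence with a module-definition fixture.
* **Truth channel.** Component labels, per-read flags and planted
  coefficients are returned separately and never consumed by analysis
  stages.

**What passing tests do and do not show.** The generator's components are
well separated and its covariates clean; recovery results (model order,
prevalence, coefficients) demonstrate correctness of the machinery under the
model's own assumptions, not robustness to real-data features the generator
omits: compositional zero-inflation beyond the DM's, taxonomic
misannotation, batch/run effects, covariate measurement error and
missingness structure, and within-subject covariate dynamics.

## Reproducibility and problem sizes

All randomness flows from one master seed, split deterministically per
pipeline stage (rarefaction, enterotyping, permutations, generator, ...);
identical configurations give bit-identical outputs, and every artifact
embeds the configuration hash and seed. The test suite and acceptance script
size their simulations for interactive desk use: model-order recovery runs
20 trials at 250 samples, prevalence recovery one cohort at N = 5000,
coefficient recovery 100 logistic replicates at N = 2000, and the
permutation-null calibrations use hundreds of small-n trials; these sizes
give comfortable margins for every planted-recovery bound asserted.

## Known limitations

* No variational or MCMC DMM fitting, and no projection of new cohorts onto
  external reference enterotype centroids.
* No UniFrac or other phylogeny-aware beta diversity (no tree is used).
* dbRDA retains positive-eigenvalue axes only; Lingoes/Cailliez corrections
  are not yet wired in.
* The logistic "relative risk" is exp(β) (see above); no marginal
  risk-ratio estimators (g-computation) are provided.
* Matching implements greedy 1:1 without replacement only — no optimal or
  full matching, no IPTW.
* Real sequencer output (FAST5/POD5), base-calling and demultiplexing are
  out of scope; the pipeline starts at tabular read assignments.
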