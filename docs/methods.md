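# Methods

`laterec` implements a discovery-and-validation pipeline for gene
signatures of *late* breast-cancer recurrence — relapse five or more years
after treatment, the clinical proxy for escape from tumor dormancy — in
multi-study expression compendia, together with a synthetic cohort
generator that reproduces the statistical structure each stage relies on.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Pipeline model

### Harmonization

Merged probe-level matrices from several studies carry technical
study/batch structure. The model assumes a designated set of control
probes is biologically invariant, so any systematic variation they display
is artifact. The first `n_components` principal components of the
control-probe submatrix (probes centered across samples; defaults 40 for a
large bulk compendium, 15 for a smaller multi-tissue set) estimate that
artifact subspace, and each probe is replaced by its least-squares residual
after regression on the component scores — a deterministic factor
regression. Probe means are preserved so values stay on the log-expression
scale. Removal is idempotent for a fixed fitted model; re-estimating
components on residuals would always find fresh noise directions, so
"repeated harmonization" is not a meaningful operation. Mixing is
quantified as the one-way variance ratio (eta-squared) of the leading
expression PC explained by study label.

### Receptor calls and subtypes

ER/PR/HER2 status is needed for every sample but IHC labels exist only for
a subset. For each marker, Gaussians are fitted by maximum likelihood to
the IHC-positive and IHC-negative samples and the decision cutoff is the
expression value where the prior-weighted class densities cross (posterior
0.5), solved from the quadratic obtained by equating log densities. With
unequal variances two real roots can exist: the root between the class
means is used, else the root nearest the pooled mean. Priors default to
the labeled prevalence (equal priors by option). IHC labels always
override mRNA calls; a sample exactly at the cutoff is called negative
(conservative positivity; measure-zero event). Subtypes follow the
receptor rules: Luminal A = hormone-receptor positive, HER2−; Luminal B =
hormone-receptor positive, HER2+; HER2 type = ER−PR−HER2+; TNBC = triple
negative. These four rules partition all eight call combinations.

### Time-window survival screen

Three views of the same (time, event) data separate prognostic windows at
a boundary (default 5 years): *overall* (no extra censoring), *late*
(events before the boundary censored at their event time) and *early*
(events at or after the boundary censored). An event at exactly the
boundary belongs to the late window. Every event is retained by exactly
one of the early/late transforms.

Each probe is screened by a univariable Cox proportional-hazards fit of
the (continuous) expression value under each scheme. The fitter is a
vectorized Newton–Raphson maximizer of the Efron-tied partial likelihood
(all probes fitted simultaneously against the shared risk-set structure),
with Wald p-values; it agrees with lifelines to ~1e-4 and is fast enough
for genome-scale screens. Probes with zero variance or non-convergent
fits (monotone likelihood) are flagged and categorized `neither`, never
dropped silently. Discovery uses a raw p-value threshold (default 0.001)
per the screen design; BH q-values are reported alongside for information.
Direction is the sign of the overall-scheme coefficient: *direct* =
overexpression associated with poor outcome.

Covariate-adjusted confirmation (size, grade, nodal status, age, HER2, ER,
PR) uses a multivariable Cox fit via lifelines; constant or collinear
covariates are dropped with a warning, and when all covariates drop the
fit reduces exactly to the univariable model. Clinical-parameter
associations are binary-covariate Cox models with the conventional
dichotomizations (size ≥2 cm, grade 3 vs others, age ≥50).

### Subgrouping and enrichment

Screen-selected probes are clustered two ways by agglomerative *centroid
linkage* under correlation distance (1 − Pearson between cluster mean
profiles), the metric of the classic expression-clustering tools; scipy's
centroid linkage is Euclidean-only, so the merge loop is implemented
directly and verified against a quadratic-time full-recompute oracle.
Probes are mean-centered before the sample-wise clustering — otherwise
sample-to-sample correlation is dominated by per-probe baseline
differences rather than sample-specific patterns. Centroid linkage can
produce inversions (non-monotone merge heights); they are recorded, and
trees are cut to exactly k groups by merge order, not height. Both trees
default to k = 4 (sample subgroups G1–G4, probe clusters C1–C4, labeled in
dendrogram leaf order). The late-recurrence-like target subgroup is the
one with the highest share of late events among groups holding at least
`target_min_group_fraction` (default 2%) of samples — the size floor
screens out the outlier singletons centroid linkage tends to split off.

Subtype-by-subgroup and screen-category-by-cluster composition is
summarized by 2×2 tables: cross-product odds ratio, Woolf logit 95% CI
`exp(ln OR ± 1.96·sqrt(1/a+1/b+1/c+1/d))`, and the two-sided Fisher exact
test (sum of hypergeometric probabilities no larger than the observed
table's). A zero cell yields OR 0 or infinity with a Haldane–Anscombe
0.5-corrected CI and a flag. Subgroup survival differences use
Kaplan–Meier estimates and the k-group log-rank test under each censoring
scheme.

### Stromal and epithelial signatures

For tumors with paired microdissected epithelium and stroma, the stroma of
the target subgroup (assigned from the epithelium) is compared with all
other stroma per probe by Welch's unequal-variance t-test (pooled-variance
by option) with Benjamini–Hochberg FDR control (default 0.05). The
selected probes define SPC1: the first principal component of the
standardized probe subset across stroma samples, oriented to correlate
nonnegatively with the mean standardized expression of the upregulated
probes (an unanchored PC sign is arbitrary and would break cross-run
comparisons). Scores are zero-mean over the defining cohort; a
fixed-loadings projection mode supports prospective scoring of new
cohorts.

The epithelial signature is the three-filter cascade: probes whose
epithelial expression (a) correlates with the paired-stroma SPC1 above
`r_min` (default 0.25), (b) is upregulated in the target subgroup's
epithelium at BH q below 0.05, and (c) carries a direct (positive) Cox
coefficient at p < 0.01 in the discovery screen (overall scheme by
default; the late scheme by option). The filters commute (pure
intersection) and the selection is monotone in each threshold. EPC1 is the
first PC of the selected probes, refit on whichever cohort is being
scored.

Validation partitions patients by metastasis timing: events before the
boundary (early), events at or after it (late), and an event-free
reference with at least `long_followup` (default 15) years of follow-up;
patients event-free with shorter follow-up are excluded rather than
pooled, because the reference group must be genuinely late-event-free.
Group comparisons use exact Mann–Whitney tests (normal approximation with
tie correction above 25 per group or in the presence of ties, recorded per
comparison) and one-way ANOVA across time-of-metastasis bins (default bin
edges 2, 5, 10 years, with the event-free group as reference bin).
Concordance between the late-enriched probe cluster's metagene and the
cascade signature is the Pearson correlation of the two anchored PC
scores.

## Synthetic cohort generator

The generator emulates the data structure above, not any particular
dataset. Defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_studies` × `samples_per_study` | 4 × 200 | bulk tumors across studies |
| `n_probes` / `n_control_probes` | 1000 / 69 | probe universe / invariant controls |
| `n_batch_factors` | 3 | latent technical factors |
| `batch_loading_sd`, `batch_score_sd`, `batch_within_sd` | 0.5 / 1.0 / 0.3 | per-probe loadings, per-study factor means, within-study jitter |
| `subtype_proportions` | 0.70/0.07/0.06/0.17 | LumA/LumB/HER2type/TNBC mix |
| `n_early_genes`, `n_late_genes` | 40 / 40 | direct-association planted programs |
| `n_early_inverse_genes`, `n_late_inverse_genes` | 20 / 20 | good-prognosis (inverse) programs |
| `early_loghr`, `late_loghr` | 0.8 | log hazard ratio per SD of latent risk |
| `risk_group_fraction`, `risk_group_shift`, `risk_background_sd` | 0.25 / 2.2 / 0.5 | mixture latent risk (discrete high-risk subgroup) |
| `signal_loading` | 0.9 | probe loading on the latent risk factors |
| `boundary_years`, `followup_max_years` | 5 / 15 | window boundary, administrative censoring |
| `early_base_hazard`, `late_base_hazard` | 0.045 / 0.035 per yr | piecewise-exponential baseline |
| `stroma_pairs`, `stroma_coupling`, `stromal_loading` | 46 / 0.8 / 1.2 | paired compartments and their latent link |
| `noise_sd` | 0.5 | iid measurement noise (log scale) |

Key constructions:

* **Batch structure.** Each factor has one loading vector over all probes
  (controls included, with no biological term) and per-sample scores drawn
  around per-study means — so the controls' principal components recover
  the planted factor span, which is what the harmonization stage assumes.
* **Latent risk.** Per-tumor early and late risk factors are independent
  two-component mixtures (background plus a shifted high-risk subgroup,
  standardized to unit variance). The mixture makes the late-recurrence
  subgroup a *discrete cluster*, as observed in real subgrouping analyses;
  a purely Gaussian latent produces only angular gradients that
  correlation-distance clustering cannot segment reliably. Planted direct
  probes load `+signal_loading`, inverse probes `−signal_loading` on the
  corresponding factor; inverse programs also give low-risk samples a
  coherent correlated profile, as in real prognostic probe sets.
* **Survival.** Piecewise-exponential hazard: before the boundary the
  hazard is `early_base_hazard · exp(early_loghr · u_early)`; at and after
  it, `late_base_hazard · exp(late_loghr · u_late)`. Early genes therefore
  act only inside the first window and late genes only after it — the
  dichotomy the screen is built to detect. Censoring is administrative at
  `followup_max_years`. Recurrences are distant with probability 0.75
  (DMFS events); local recurrences are DMFS-censored (competing risks out
  of scope). Death follows distant recurrence after an exponential lag.
* **Markers and IHC.** Marker probes are drawn from per-status Gaussians
  given hidden receptor truth consistent with the sampled subtype; IHC
  labels reveal the truth for a configurable fraction (default 0.5),
  exercising the cutoff-transfer logic. The planted cutoff is the analytic
  prior-weighted density crossing.
* **Paired compartments.** Each of the `stroma_pairs` tumors contributes
  an epithelium and a stroma profile sharing a latent stromal-activation
  factor `v = c·u_late + sqrt(1−c²)·ε` with `c = stroma_coupling`; the
  stromal program probes load on `v` only in stroma, so the cascade's
  target (epithelial late-program genes tracking stromal activation) is
  planted with known identity.
* **Clinical covariates.** Grade and size correlate with the early risk
  factor (so they are prognostic for early recurrence only, as in the
  motivating clinical tables); age is independent. Node-positive and
  treated fractions default to 0 so the full bulk cohort is the discovery
  cohort; the discovery filter (node-negative, untreated, bulk) is applied
  regardless.

All randomness flows from a single `SeedSequence`; per-component
sub-generators keep the draws stable under parameter changes that do not
touch a component.

### What the generator does not emulate

Probe-level microarray artifacts (CEL-level effects, probe saturation,
platform-specific summarization), non-administrative censoring, competing
risks, copy-number/mutation structure, correlated noise beyond the planted
factors, and real gene identities. Passing recovery tests therefore shows
the pipeline's statistical machinery behaves correctly under the assumed
data-generating structure — not that the biological conclusions of any
real-data analysis are reproduced.

## Numerical choices

* Cox Newton iterations are damped (step clipped to 1), run on
  standardized covariates, and stop at a 1e-10 step tolerance; estimates
  with |standardized beta| > 20 are flagged non-convergent.
* The Woolf CI uses the literal 1.96 multiplier (the convention of the
  published tables it mirrors).
* PCA everywhere is via SVD of the centered matrix; metagene probes are
  standardized before the SVD so each contributes on equal scale.
* Centroid-linkage ties break toward the smallest cluster-id pair;
  dendrogram leaf order resolves group labels deterministically.
* Mann–Whitney tests are exact only when both groups are ≤ 25 samples and
  tie-free; otherwise the tie-corrected normal approximation is used and
  recorded.
* Empty selections (cascade, stromal DE) are warnings that propagate an
  explicitly empty signature through the pipeline, not errors.

## Problem sizes

Tests and the acceptance script run the pipeline at the default study
conditions (800 bulk + 46 paired samples, 1000 probes) and smaller
calibration cohorts (e.g. 200 planted-null cohorts of 200 samples × 100
probes for type-I calibration; 2000 null probes for the late-screen level
check). These sizes were chosen so each check exercises the full code
path at adequate statistical resolution.

## Known limitations

* Centroid linkage's outlier-singleton behavior means the k-group cut can
  occasionally isolate one or two stray samples; the size floor in target
  selection mitigates but cannot remove this.
* With only 46 pairs, stromal discovery power is marginal when the joint
  clustering assigns few pairs to the late-like subgroup; for some cohort
  draws the stromal DE finds nothing at FDR < 0.05 and the run reports an
  empty signature (the honest outcome under those draws).
* The screen's Wald p-values rely on asymptotics; with very few events in
  a window they become conservative/anticonservative in the usual ways.
* Receptor-call accuracy depends on mixture separation; strongly
  overlapping components make any cutoff-based caller inaccurate (the
  concordance-vs-separation property test documents the monotonicity).
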