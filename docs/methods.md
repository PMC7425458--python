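# Methods

`methmort` re-creates, end to end and on synthetic data, the statistical
workflow of a consortium-scale epigenome-wide association study (EWAS) of
blood DNA methylation and all-cause mortality: per-cohort per-CpG Cox
screening, inverse-variance fixed-effects meta-analysis with multiplicity
control, and the downstream causal and interpretive layers (attributable
fraction, two-sample Mendelian randomization, leukocyte deconvolution,
meQTL/eQTM scans, enrichment, epigenetic-clock adjustment). This note
records the models, the defaults and why they were chosen, and what the
synthetic studies do and do not demonstrate.

## Synthetic cohorts

Each cohort is simulated independently from `default_rng(seed + cohort_index)`.

**Methylation.** A reference matrix of seven leukocyte profiles (CD4T, naive
CD8T, memory/effector CD8T, NK, B cells, monocytes, granulocytes) is built
with per-type marker CpGs (the marked type near beta 0.9, all others near
0.1), so the deconvolution design is full rank by construction. Sample
cell fractions are Dirichlet-distributed around adult whole-blood means
(granulocytes ~0.55, concentration 60). A sample's beta value at a CpG is
the fraction-weighted mixture of reference profiles, perturbed by Gaussian
noise on the logit scale (default sd 0.3) and mapped back through the
inverse logit — noise on the logit scale respects the [0,1] support without
truncation artifacts. Optionally, designated causal CpGs receive an
additional logit shift of ±delta/2 from a latent biallelic factor
(Bernoulli(0.5)), emulating meQTL-driven bimodal sites; delta ~3.5 gives
modes near 0.15/0.85 and cross-sample sd ~0.35.

**Covariates.** Age uniform on [50, 89) (kept continuous internally, binned
to decades for the covariate table), sex, education, smoking status and
pack-years, BMI, physical activity, alcohol, hypertension, diabetes,
cancer and CHD history, and technical plate/chip/row/column factors.

**Survival.** Exponential proportional hazards: the death rate is
`baseline_hazard_scale * exp(lp)` with
`lp = sum(causal log-HR x beta) + sum(covariate effects)`. Covariate
effects are specified on centered scales (age centered at 65, BMI at 27).
Censoring is the minimum of administrative follow-up (default 15 y) and a
uniform dropout time on (0, 30 y). Defaults (baseline 0.02/y) give ~20%
deaths over a ~10-year mean follow-up, the regime typical of the cohorts
this emulates. A secondary incident-disease outcome is drawn from the same
linear predictor with its own baseline. Missing beta entries are masked
completely at random (`missing_rate`, default 2%); cohort-specific QC is
not simulated mechanistically.

What the generator does **not** emulate: familial correlation, batch- or
chemistry-specific artifacts, probe cross-hybridization signal, non-MCAR
missingness, or population structure. Tests passing on these data show the
estimators behave as designed under their own assumptions, not that the
pipeline is robust to every pathology of real arrays.

## Probe QC

Probes are excluded in a fixed cascade (control, non-CpG, allosomal,
cross-reactive, SNP within 10 bp, non-varying, ≥10% missing,
non-converging, available in too few cohorts); each probe is tallied under
the first rule that removes it, so counts partition the input and the
cascade is idempotent. "Non-varying" means pooled IQR < 0.001 computed over
all sample values pooled across cohorts (a per-cohort-medians variant
degenerates when only a few cohorts exist). The availability threshold
defaults to 4 cohorts ("more than three"), with 3 supported.

## Survival screening

The Cox partial likelihood is maximized by a damped Newton method compiled
with numba (the screen runs ~10^5 single-CpG fits in the validation
studies). Efron tie handling is the default, Breslow an option; the
implementation is checked against lifelines (Efron) and statsmodels PHReg
(Breslow) to 1e-6 and against a closed-form three-subject example to 1e-6.
Convergence requires a vanishing relative log-likelihood change with a
small gradient; |beta| > 50 or numerical failure flags `converged=False`
(never an exception). Wald p-values are two-sided normal.

Covariate sets: *basic* = age-decade indicator contrasts (youngest decade
reference), sex, plate/chip/row/column contrasts, plus estimated cell
fractions with the largest-mean compartment dropped (sum-to-one
collinearity); *full* adds education, smoking status, pack-years, BMI,
physical activity, alcohol, hypertension, diabetes, cancer and CHD
history. The two-step residual variant (OLS of each probe on the
covariates, then a single-predictor hazard fit on the residuals) is
auto-selected below 50 events — it is deliberately conservative (null z sd
~0.9 in our simulations), which is the accepted price of stability in
low-death cohorts. The step-2 fit uses the residual as the sole predictor.

The proportional-hazards diagnostic is a Grambsch–Therneau-style score
test correlating Breslow-form scaled Schoenfeld residuals with (identity-
transformed) event time; it is calibrated under PH (~5% rejection) and
detects crossing hazards in construction tests. It reports a p-value only;
no automatic exclusion.

## Meta-analysis

Fixed-effects inverse-variance pooling throughout: `w = 1/se^2`,
`se_pooled = (sum w)^(-1/2)`; Cochran's Q and `I^2 = max(0, (Q-(k-1))/Q)`
are computed from the same weights and used descriptively. Genomic
inflation is `median(chi2)/0.4549364`. Bonferroni and Benjamini–Hochberg
are applied at 5% with m = the number of CpGs actually pooled. Leave-one-
out re-pools k times; the sensitivity exclusion drops cohorts with death
proportion ≥ 0.30 or cohort λ strictly > 1.5 (a cohort at exactly 1.5 is
retained). The pooled estimate is verified against a grid-search minimizer
of the weighted least-squares loss.

## Attributable fraction

Exposure is "beta strictly above the cohort mean" at a CpG. The case-based
(Miettinen) form `PAF = pc (RR-1)/RR` uses the exposure prevalence among
deaths and the covariate-adjusted hazard ratio of the dichotomized
exposure — the form that remains consistent under confounder adjustment.
The validation study compares it against counterfactual elimination
(re-simulating the same cohort with the causal effect removed under common
random numbers) at ~20% mortality; the two agree to O(event fraction), so
agreement to 0.03 is expected at that event rate but would not hold at very
high mortality. No variance is attached to PAF.

## Mendelian randomization

Harmonization aligns alleles (sign-flipping swapped effect/other alleles),
drops strand-ambiguous palindromic SNPs (A/T, C/G with EAF in (0.42,
0.58)) with a tally, and orients instruments so exposure effects are
nonnegative. Estimators: Wald ratio (first-order delta SE, the strong-
instrument convention), MR-Egger (WLS with intercept, weights 1/se_y^2),
weighted median (weights (bx/sy)^2, cumulative-weight interpolation at
50%, parametric bootstrap SE), weighted mode (weighted Gaussian KDE over
ratio estimates, modified-Silverman bandwidth
`0.9 min(sd, MAD) n^(-1/5)` times a user factor, argmax on a grid over the
ratio hull). Binary outcomes are treated as log-odds and exponentiated to
odds ratios. Bootstrap replicates default to 1000 and are fully seeded.

## Deconvolution and NLR

Houseman-style constrained projection: minimize `||R^T w - beta||^2` over
`w ≥ 0, sum(w) ≤ 1`, solved as penalty-augmented NNLS with a slack
compartment (exact for noiseless mixtures; cross-checked against SLSQP),
then renormalized to sum 1. Cohort-level estimation uses the reference's
discriminating marker CpGs, the standard practice. NLR = granulocyte
fraction / (CD4T + naive CD8T + memory/effector CD8T + NK + B); the
granulocyte compartment proxies neutrophils because whole-blood references
do not resolve neutrophils specifically; a zero lymphoid sum yields NaN.

## meQTL / eQTM

meQTL: per SNP–CpG pair, a linear model adjusted for age, sex, BMI and
cell proportions, computed exactly by Frisch–Waugh residualization for the
all-pairs scan; by default the SNP dosage is the *dependent* variable, an
orientation some consortium analysis plans specify (the conventional
methylation-on-dosage regression is available as an option, since the
unusual orientation may well be a description slip). Pairs survive at
p < 1e-4;
genome-wide significance is flagged at 1e-14. A genotype pre-filter
removes SNPs with call rate < 0.98, HWE p < 5e-6 or MAF < 0.01.

eQTM: expression regressed on methylation with covariates and a random
intercept for RNA amplification batch (statsmodels MixedLM; fixed
intercept with a warning if only one batch). Distance is the gap between
the CpG position and the nearest gene-interval edge (0 inside); pairs
within 500,000 bp (inclusive) are cis, beyond are trans; only same-
chromosome pairs are modeled.

## Enrichment, clocks, risk scores

Enrichment is the one-sided (greater) hypergeometric tail per category
(island relation, gene region, or user sets) against the post-QC
background, BH-corrected across categories; it is verified against
exhaustive tail summation for all 2x2 tables with total ≤ 20. Clocks are
user-supplied linear coefficient tables (`cpg_id<TAB>weight`, special row
`INTERCEPT`); published coefficient sets are not bundled, and the
pipeline's demonstration clock is synthetic and labeled as such. Scores
require ≥50% of clock CpGs observed, with cohort-mean imputation below
that per sample. Acceleration defaults to the clock-minus-age difference
("discrepancy"), with the age-regression residual as an option.
Score-adjusted mortality models append the acceleration/risk scores to
the fully-adjusted Cox fit. Cross-CpG correlations are pooled within
cohort by inverse-variance Fisher-z.

## Validation study designs (and why these sizes)

The canonical studies in `methmort.simstudy` are the package's evidence
that the machinery is calibrated; their designs were fixed by power and
bias analysis:

* **Null calibration** — 4 cohorts x 250 subjects, 500 null CpGs, 20
  replicates, basic model, ~68% mortality (within the 3–70% span such
  consortia report). The event rate matters: with 16 covariate columns,
  cohorts with only ~60–90 events show the classic small-sample Wald
  overdispersion (z sd ~1.05–1.08); at ~170 events per cohort the screen
  is calibrated (pooled z sd ~1.04, mean λ ~1.04). The λ criterion is
  evaluated on the mean over replicates because a single 500-CpG λ has
  Monte-Carlo sd ~0.10.
* **Effect recovery** — 10 bimodal causal CpGs (log-HR 0.5 per unit beta)
  among 500, 4 cohorts x 3600 subjects, ~22% deaths. Per-CpG Cox fits omit
  the other nine causal sites, and Cox coefficients are non-collapsible
  over omitted signal: attenuation grows with the omitted linear-predictor
  variance and the event fraction (measured at up to −20% in high-variance
  high-event designs, while a single-causal design is unbiased). The
  chosen separation (delta 1.8, causal sd ~0.22, omitted-lp variance
  ~0.11) and ~22% mortality keep that bias below Monte-Carlo resolution
  (measured −0.002 ± 0.008) while cohort size holds the per-site z near 6,
  making full BH recovery of all ten sites the expected outcome.
* **PAF** — 5,000 subjects, one strongly bimodal exposure CpG, exposed-vs-
  unexposed HR ~2, ~20% mortality (see above for why moderate mortality).
* **MR** — 200 replicates x 50 strong instruments (exposure SE 0.005,
  outcome SE 0.02), no pleiotropy for the unbiasedness check; a 10-
  instrument set with one ratio-5 outlier for the median's breakdown
  property; estimator means only (bootstrap SEs exercised separately).

## Numerical choices and degenerate inputs

Newton convergence: relative log-likelihood drop < 1e-10 with gradient
check; step halving (32 halvings max); divergence bound |beta| > 50.
Constant predictors, < 2 events, singular information: `converged=False`.
P-values are clipped into (0, 1]. I^2 is zeroed when Q < 1e-12 (float fuzz
of an exact fit). The weighted-mode KDE grid spans exactly the hull of the
ratio estimates (the mixture's argmax cannot lie outside), which keeps the
large-bandwidth limit (→ weighted mean) numerically stable. Deconvolution
uses penalty weight 1e6 on the simplex row.

## Known limitations

* Exponential baseline hazard only (Weibull would need one more parameter;
  the Cox layer is baseline-agnostic regardless).
* No familial/cluster variance (family-structured cohorts in the emulated
  design used cluster terms; out of scope here).
* The two-step screen is conservative by construction; its results are
  pooled with direct-fit cohorts without reweighting, as in the emulated
  workflow.
* PAF carries no uncertainty interval.
* MR assumes exact SNP-id matching (no LD proxies) and strong instruments.
* The eQTM mixed model fits pair-by-pair and is not optimized for
  transcriptome-wide scans.
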