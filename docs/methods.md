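# Methods

`salivadx` implements a complete analysis chain for case/control
salivary-metatranscriptome studies: quantification of active microbial
species and KEGG-ortholog (KO) functions from ambiguous read mappings,
compositional descriptive statistics, a univariate differential-activity
screen, and a multivariate diagnostic classifier with bootstrap stability
selection. This note records the models, the defaults and why they were
chosen, and what the synthetic cohorts do and do not establish.

## EM quantification (`emquant`)

Reads mapping to several references (strains, or genes sharing sequence)
are reduced to *read classes* — groups of reads compatible with the same
reference set at the same weights. Classes are sufficient statistics for
the mixture likelihood

    L(a) = Σ_c n_c log Σ_j w_cj a_j ,

maximised by the standard EM recursion: distribute each class across its
compatible references proportional to `w_cj · a_j`, renormalise the
expected counts. The log-likelihood is non-decreasing per iteration (a
property test exercises 1,000 random instances) and the update is checked
against the same recursion iterated in exact rational arithmetic.

Choices:

* **class-level, not read-level** — the class counts carry the full
  likelihood information and keep instances desk-scale;
* **uniform initialisation**, deterministic; when every counted class is
  shared the likelihood has flat directions, and the result is flagged
  `identifiable=False` (the heuristic requires each reference to own at
  least one uniquely mapping counted class — sufficient, not necessary);
* **convergence**: log-likelihood or max activity change < `tol`
  (default 1e-8), `max_iter` 1000; non-convergence sets a flag rather
  than raising;
* **weights** default to 1 and can carry alignment quality.

Aggregation to genus/phylum or from genes to KOs is group-by summation;
mass is conserved, and genes with no KO annotation are dropped with their
per-sample mass reported explicitly.

## Compositional statistics (`compstats`)

Relative activities are compositions, so all ratio work happens in
centered log-ratio (CLR) coordinates, `clr(x)_i = ln(x_i / g(x))`. The
natural log is fixed, not configurable: a twofold ratio must correspond
to a CLR difference of `ln 2 ≈ 0.69`, which is the effect threshold used
downstream. Zeros are imputed first by multiplicative replacement (zeros
→ δ, nonzeros scaled by `1 − zδ`); δ defaults to 0.65 × the smallest
observed nonzero relative activity of the table, a common convention
for multiplicative replacement. Species and KO tables are closed
and transformed as **separate** compositions — mixing them in one
closure would distort both geometries — and are concatenated only after
transformation, as the classifier's input.

Diversity descriptors per sample: richness (positive entries), Shannon
`−Σ p ln p` in nats, inverse Simpson `1/Σ p²`, Pielou
`shannon / ln(richness)` (undefined below richness 2, reported as NaN).
These are direct formulas; scikit-bio's implementations serve as an
independent oracle in the tests.

## Differential-activity screen (`diffexpr`)

Per feature: two-sided Mann–Whitney U on the CLR values (exact when both
groups ≤ 8 without ties, tie-corrected normal approximation with
midranks otherwise; identical pooled values give p = 1 by convention),
Benjamini–Hochberg adjustment applied **within** each feature table
(species and KOs are two separate screens), and a significance call that
requires both `q < α` (default 0.05) and an absolute difference of CLR
means ≥ `ln 2`. The mean difference drives the call; the median
difference is stored alongside for display. The q-value (not the raw p)
is thresholded. The fold-change filter is applied jointly with FDR
control; workflows that apply the two sequentially can report different
hit counts on the same data.

## Diagnostic classifier (`sigclassifier`)

All steps operate on the column-wise concatenation of the species and KO
CLR matrices.

1. **Variance filter.** Features with variance strictly below the 25th
   percentile (linear-interpolation percentile, sample variance) of all
   per-feature variances are removed. Default scope is `global` (a
   single pre-pass before cross-validation); this is a mild form of
   leakage into LOOCV, so `per_fold` is available as a documented
   trade-off.
2. **LOOCV with per-fold stability selection.** For each held-out
   sample, the training set is resampled B times with replacement
   (default 1000), **stratified by class** so each draw contains both
   classes, which unstratified draws cannot guarantee at these sample
   sizes. An L2-penalised logistic model (inverse regularisation
   `l2_strength`, default C = 1, intercept unpenalised, no feature
   standardisation — CLR units are already comparable) is fit to every
   resample, and features whose empirical 2.5–97.5 percentile interval
   of the coefficient excludes zero are selected. B < 20 is rejected as
   a degenerate CI.
3. **Fold model and held-out probability.** A fold's model is fit on its
   selected features; a fold selecting nothing is flagged degenerate and
   predicts the training class frequency (intercept-only model).
4. **Signature and final model.** The signature is the intersection of
   selections across non-degenerate folds; the exported model is one
   more L2 logistic fit on all samples restricted to the signature.
   Prediction is `logistic(intercept + Σ coef·x)`; a sample is called a
   case only when the probability **strictly** exceeds the threshold
   (default 0.5) — ties go to control, the conservative direction for a
   screening positive.

**Batched bootstrap solver.** The B bootstrap fits inside a fold share
one design matrix, so a resample is encoded as multinomial count
weights, and the B independent penalised log-likelihoods are summed into
a single L-BFGS problem (two matrix products per iteration). This is the
identical estimator to scikit-learn's `LogisticRegression` with sample
weights — the tests pin the two against each other at 1e-4 — merely
batched; consecutive folds warm-start from the previous optimum, which
is safe because the objective is strictly convex. Per-fold and final
models use scikit-learn directly.

**Seeds.** Each fold draws its bootstrap resamples from an independent
stream derived from (master seed, fold index), so the whole LOOCV is
bit-for-bit reproducible and folds can be recomputed in isolation.

**Known property: pooled-LOOCV pessimism under the null.** LOOCV
produces one held-out probability per sample from n different models,
and the pooled AUC of those probabilities is pessimistically biased when
there is no signal: each training set under-represents the held-out
sample's class (intercept and fitted noise both lean against it), a
small-sample effect documented for pooled cross-validation AUC
estimates. On label-exchangeable synthetic cohorts the mean pooled
LOOCV AUC sits near 0.42–0.45 rather than 0.50 (the same holds for
plain Gaussian noise features, so it is not a property of the cohort
generator). The bias vanishes in the strong-signal regime the
classifier is designed for; per-seed null AUCs still scatter inside
roughly [0.35, 0.65].

**Known property: intersection false discoveries.** The per-fold CI rule
keeps ≈5% of truly uninformative features (verified on independent
Gaussian noise). Because consecutive LOOCV folds share all but two
samples, the *same* chance-associated features tend to be selected in
every fold, so the intersection prunes fold-to-fold instability but is
not a multiplicity control: on planted synthetic cohorts the signature
recovers the planted features essentially completely while also
retaining chance-associated features — largely rare features whose
presence happens to be imbalanced between classes and whose
imputed-versus-present CLR gap is large. Interpret signature membership
as "stably selected on this dataset", not as an FDR-controlled
discovery list.

## Evaluation (`evalreport`)

ROC via the standard threshold sweep; AUC equals the normalised
Mann–Whitney statistic with midrank ties (asserted as an identity test
against pair enumeration). Sensitivity and specificity carry exact
Clopper–Pearson intervals from Beta quantiles (lower bound exactly 0 at
k = 0, upper exactly 1 at k = n). Per-stage detection tallies cases by
lesion stage (OPMD, S1–S4) at the decision threshold, with an explicit
"unstaged" bucket rather than forcing stage totals to match the case
count. PCA ("top features") takes the k largest |coefficient| columns of
the final model — the ranking criterion is this package's choice.
Interference robustness is the per-subject |Δprobability| between a
baseline sample and each perturbed sample. Percentages in reports are
printed to one decimal.

## Synthetic cohorts (`synthdata`)

The generator emulates the statistical shape of a two-class salivary
metatranscriptome study so every stage is testable without any download:

* latent feature log-abundances `μ_f ~ N(0, 1.5²)` (heavy-tailed,
  log-normal across features) with per-sample noise
  `ε ~ N(0, overdispersion²)`, default overdispersion 0.7;
* planted class effects added in log-abundance space
  (`β_f = ±effect_size` for discriminative features), so the CLR-space
  mean shift equals `effect_size` by construction up to an O(k/D)
  closure term — verified within 10% by a calibration test;
* structural zeros from a core/rare prevalence model: a `core_fraction`
  (default 0.2) of features is present in every sample, the rest get a
  zero-skewed Beta prevalence whose mean matches the target presence
  `1 − zero_fraction`, scaled per sample by a Gamma coverage factor
  (mean 1, sd 0.25) shared between the species and KO tables;
* counts are Multinomial(depth) over the masked abundances, default
  depth 1e5 per sample.

Defaults emulate the discovery-cohort shape: 58 cases / 59 controls,
1587 species and 4932 KOs, with `zero_fraction` 0.715 (species) and 0.50
(KO) calibrated so simulated per-sample richness lands near the
reference cohort's means (~438 species, ~2270 KOs) after multinomial
sampling zeros.

Planted features are core members (structurally present in both
classes). This is deliberate: discriminative activity shifts ride on
common organisms, presence carries no label information, and a feature
masked in ~70% of samples could not carry a calibrated CLR shift — nor
would it survive the variance filter the way real discriminative
features do.

What the generator does **not** emulate: between-feature correlation
beyond compositional closure (no ecological interaction structure),
batch or extraction effects, label-correlated covariates by default
(sex/age/smoking are independent of the label), and the full
between-sample richness dispersion (simulated species richness SD ≈ 32
versus ~81 in the reference cohort). Passing tests therefore establish
that the
pipeline is correct and calibrated under exchangeability and recovers
additive CLR-space effects — not that real-data performance figures
transfer.

EM fixtures (`generate_compatibility`) draw read classes with a home
reference and, with probability `ambiguity`, one extra compatible
reference; counts come from the exact mixture the EM model assumes, so
EM is consistent for the planted activity and recovery error can be
asserted (< 0.01 mean absolute error at depth 1e5, ambiguity 0.5).
Interference pairs share a subject's latent composition, perturb a ~5%
feature subset, and emit relative activities with common random numbers
per subject, so zero perturbation yields bit-identical pairs.

## Problem sizes in tests and the acceptance script

The property-based checks run at reduced scale, chosen to make the
statistical assertions sharp while staying desk-scale: null calibration
averages LOOCV AUC over 20 cohorts of n = 60 with 500 features at
B = 100; signal recovery uses one cohort of n = 100 with 10
discriminative of 500 features at effect `2·ln 2` and B = 200; noise
selection calibration uses 4 × 50 independent Gaussian features at
n = 100, B = 200; EM recovery uses 10 references, 120 read classes,
depth 1e5. The worked-number reproductions (specificity from 276 TN / 6
FP → 97.9%, stage-1 sensitivity 12/13 → 92.3%, twofold CLR threshold →
0.69) are instantaneous.

## Numerical conventions

* Percentiles: NumPy linear interpolation everywhere (variance filter,
  bootstrap CIs).
* Batched bootstrap solver tolerance: L-BFGS relative function tolerance
  1e-7, which resolves coefficients two orders of magnitude below the
  bootstrap Monte-Carlo noise of the percentile CIs; the solver-oracle
  agreement tests run the solver at tighter tolerance.
* Variance-filter boundary: features exactly at the cutoff are kept, so
  an all-equal-variance table keeps everything.
* All-zero rows cannot be closed to a composition and are rejected, as
  are compositions whose zero count times δ reaches total mass 1.
* Probability exactly at the decision threshold classifies as control.
* Master seeds are split into named CRC32-keyed substreams (abundance,
  mask, coverage, sampling, covariates; per-fold bootstrap streams), so
  partial regeneration is stable across processes.
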