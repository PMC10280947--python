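# Methods

## The problem setting

Cancer-pain services increasingly deliver follow-up by synchronous
tele-consultation. Whether a given patient will need one remote visit or
several determines scheduling, staffing and how a hybrid in-person/remote
pathway should be calibrated. The analysis this package implements has four
stages: (1) obtain a patient-level cohort; (2) train a conditional GAN to
produce a synthetic twin of it and verify statistical fidelity; (3) benchmark
classifiers that predict "more than one tele-visit" from baseline features;
(4) interrogate the best classifier with Monte-Carlo patient profiles to
express clinical contrasts as simulated odds ratios (sOR).

Because the underlying patient records are not publicly available, stage (1)
is a parametric generator calibrated to the published cohort summaries. Every
downstream stage is therefore testable against a known data-generating
process — which is precisely what makes parameter-recovery tests possible.

## Synthetic cohort generator

One patient record carries: age (integer years, 18–95), gender, tumour site
(12 categories), metastatic status, bone metastases, breakthrough cancer pain
(BTcP), neuropathic pain, ECOG performance status (0–4), morphine-equivalent
dose class (>60 mg/day or not), the tele-visit count (≥1) and its
dichotomization `one`/`more`.

Structure is causal: covariates → outcome → visit count.

- **Age** ~ Gaussian(64, 12) truncated to [18, 95], rounded to integers. The
  per-outcome age difference (≈66 vs ≈62 years) is *not* imposed; it emerges
  from the outcome model, keeping age a cause and the outcome an effect.
- **Gender** ~ Bernoulli(114/218 female). **Site | gender** uses per-gender
  tables built from the pooled site counts with a female-share per site:
  gynecological 1.0, prostate 0.0, breast 0.97, and a common share (~0.46)
  for the remaining sites solved so the female margin is exact. Mixing the two
  tables by the gender split reproduces the pooled site margin exactly, and
  the gender-consistency contract (prostate ⇒ male, gynecological ⇒ female,
  breast ⇒ female with probability ≥0.95) holds by construction.
- **Metastatic** ~ Bernoulli(0.906); **bone metastases** only within the
  metastatic subgroup at rate 0.454/0.906, preserving the 45.4% margin and
  the bone ⇒ metastatic implication. **BTcP** (0.372), **neuropathic pain**
  (0.408), **MED>60** (0.610) are independent Bernoullis at the published
  margins. **ECOG** is categorical (0.05, 0.15, 0.35, 0.30, 0.15) on 0–4,
  giving mean ≈2.35 and median 2; the exact distribution is not published,
  only these summaries.
- **Outcome**: logistic with per-year log-odds ln 0.97, BTcP ln 1.5,
  neuropathic 0, gender ln 1.74, MED ln 1.07, bone ln 0.93 (the three
  non-null auxiliary effects are Table-derived cross-tabulation odds ratios;
  BTcP is set to the risk-analysis point estimate; neuropathic to the null
  the risk analysis reported). The intercept is solved by root finding so
  that the *expected* outcome split is exactly 108/110 — the expectation is
  computable in closed form because the binary covariates are independent
  (32 combinations × the integer-age pmf).
- **Visit count**: 1 if outcome is `one`; otherwise 2 + (Geometric(p=0.45)−1)
  truncated at 8 total visits. This gives overall mean ≈2.07, SD ≈1.45 and
  median 2 against the published mean 2.1, SD 1.6, median 2. (A geometric
  parameter of 0.55 was considered and rejected: it implies mean 1.90.)

What the generator deliberately does *not* emulate: covariate correlations
beyond site–gender and bone–metastasis (the published summaries are
univariate), any nonlinearity in the age effect (the real cohort's risk
reportedly collapses after age 75; a single log-odds slope cannot produce
that cliff), missing data, or visit-level longitudinal structure. Tests that
pass on this generator therefore validate the *machinery* — calibration,
recovery, intervals — not the clinical claims themselves.

## Preprocessing

One encoding dialect serves both consumers. Numerics (age, ECOG, visit
count) are z-standardized with population SD (a zero-variance column falls
back to SD 1 with a logged warning); categoricals become 0/1 indicator
blocks — the full indicator set for the GAN (decoding is per-block arg-max)
and drop-first for regression designs (identifiability). Decoding inverts the
z-score, rounds integer variables into their clinical ranges, and arg-maxes
categorical blocks; `decode(encode(x)) = x` on the record domain. Splits use
a seeded uniform permutation with |train| = floor(ratio·n), remainder to
test (218 → 152/66 at 70/30; 436 → 348/88 at 80/20). In the classifier
bench, encoding parameters are estimated from training rows only.

## Conditional GAN

Both networks are 2-hidden-layer perceptrons (128, 64 units, leaky-ReLU 0.2)
written directly on numpy with Adam (lr 2·10⁻⁴, β₁ = 0.5), batch 32, 300
epochs, one D step then one G step per batch, noise dimension 32, both nets
conditioned on the one-hot `one`/`more` label. D minimizes the binary
cross-entropy −[mean log D(x) + mean log(1−D(G(z)))] (the negated empirical
value function, equilibrium value ln 4); G uses the non-saturating form
−mean log D(G(z)), which shares the fixed point. ECOG is included in the
generated table — the generated-data summaries report it — and the visit
count is generated as an ordinary column while the dichotomized label is the
conditioning variable.

Three stabilizers matter at this table size (152 training rows, width 27),
all adopted after the plain objective failed the fidelity check on the
12-level site variable:

1. **Class-conditional moment matching.** The generator loss adds
   w·‖mean(G batch) − E[x | batch labels]‖² with w = 5, the targets being
   the per-class training means. This anchors the marginals without changing
   the adversarial fixed point (at p_g = p_data the term is zero in
   expectation).
2. **Polyak averaging.** Generator weights are averaged over the final half
   of training, damping the minimax oscillation of the endpoint.
3. **Sampled categorical realization.** At generation time each categorical
   block is drawn from its softmax probabilities rather than arg-maxed; the
   generated level frequencies then equal the softmax means that training
   matched, where arg-max would concentrate on modes (the classic
   mode-collapse signature — a per-epoch monitor warns when fewer than 6
   distinct sites are being produced).

Decoded samples get their record invariants enforced (site-implied gender,
bone ⇒ metastatic, visit count consistent with the conditioning label).
Training diverging to non-finite losses raises with the epoch number;
training on a single class is rejected. The per-epoch log records both
losses and the discriminator's held-out real-vs-fake accuracy.

## Fidelity report

One row per variable: Pearson chi-squared without continuity correction for
categoricals (the correction is omitted deliberately — it is what reproduces
the published gender-table p-values 0.043/0.058), Wilcoxon rank-sum for
numerics (exact tie-aware permutation distribution when the pooled sample
is ≤16, tie-corrected normal approximation otherwise), with a Welch t-test
p reported alongside. Site levels empty in either cohort are dropped from
the site test (sparse categories such as kidney and melanoma/skin may not be
replicated at all). The pooled age-effect check fits
logit P(more) = β₀ + β₁·age + β₂·source + β₃·age·source and reports
exp(β₁) with its Wald interval and the interaction p-value: a large β₃ p
means the age effect does not differ between real and generated data.

## Classifier bench

Features: age, gender, site, bone metastases, BTcP, neuropathic pain,
MED class, ECOG. Metastatic status is excluded (≈91% prevalence carries no
signal) and the raw visit count obviously never enters. Hyperparameters ship
at the published values — GBM {100 trees, depth 5, shrinkage 0.1, min leaf
15}, elastic {α = 0, λ = 0.25}, RF {13 variables per split}, ANN {10 hidden
units, decay 0.035}. α = 0 is pure ridge although the source labels the
model "LASSO"; the label is kept in outputs, the printed α/λ are what run.
The glmnet-style λ maps to scikit-learn's C = 1/(n·λ). Tuning is repeated
stratified K-fold CV (5 folds × 3 repeats by default; K is not published) on
mean accuracy, grids ordered simplest-first and ties kept by the earlier
entry; encoding maps are re-fit inside every fold. Metrics: AUC in the
tie-corrected Mann–Whitney form (reported both on the full dataset, the ROC
figure's convention, and on the test set — the published table does not say
which its AUC column is), exact Clopper–Pearson 95% accuracy intervals,
one-sided exact binomial p against the no-information rate, sensitivity and
specificity with `more` positive, and F1 = 2PR/(P+R) with F1 ≡ 0 at
P = R = 0. No attempt is made to reproduce the published accuracy/AUC values
themselves — they depend on the unavailable real data; ordering and ranges
are property-tested instead.

## Simulated odds ratios

A profile fixes the condition features — age may be fixed *as a
distribution* (Gaussian mean/SD, truncated to 18–95) — and draws free
features from the cohort spec's margins, site conditional on gender; a
uniform-over-levels mode exists because the study describes both samplings
in different places. Each simulated patient is classified by a Bernoulli
draw from the model's predicted probability. This stochastic-classification
reading is forced by the engine's own contracts: a featureless model with
P(more) = 0.7 must yield risk ≈ 0.7 (thresholding would give 1.0), and a
forest trained on a cohort with encoded BTcP odds effect ω must recover sOR
within [0.75ω, 1.25ω] (thresholding inflates such contrasts severalfold,
measured). Risk = classified fraction of S = 200 patients; per replicate
sOR_r = odds(risk_t)/odds(risk_r) with a Haldane-style ε = 0.5/S correction
at risks of exactly 0 or 1; R = 300 replicates give the mean (point
estimate; the median is also reported) and the 2.5/97.5-percentile 95%
credibility interval. (The study's methods text says ~500 × 150; its results
were produced at 200 × 300, which is the default here — both configurable.)
Classification is batched over all S·R profiles per arm, equivalent to
per-replicate simulation and much faster for forests.

The presets: `age` = older (75 ± 5) vs younger (45 ± 5) — ordered so the
reported value (≈0.3, "older patients have −70% risk") is
odds(older)/odds(younger); `btcp` and `neuropathic` = condition present vs
absent; `btcp_neuro` = both vs neither. `risk_by_age` traces the risk over
an age grid with everything else free.

**Calibration caveat.** Under the default generator the population contrast
for the age preset is 0.97³⁰ ≈ 0.40 — there is no age cliff — and a forest's
vote-fraction probabilities attenuate effects toward 1 on a 436-row cohort
(measured calibration slope ≈0.7). Point estimates for this preset therefore
scatter roughly between 0.25 and 0.8 across cohort draws; the BTcP and
neuropathic presets, whose targets sit mid-interval, are much more stable.
This is a property of the study conditions, not of the estimator.

## Pipeline and reproducibility

`telepain run` executes synth → GAN → fidelity → bench → sOR from one YAML
config carrying per-stage seeds; every artifact is a CSV/JSON file hashed
into a manifest, and a rerun with the same config reproduces identical
hashes. All stochastic components take explicit integer seeds; GAN training,
cohort sampling and the sOR engine are bit-reproducible per seed.

Problem sizes used by the shipped tests and the acceptance script — 218/436
patients, 300 GAN epochs, S = 200, R = 300, forest of 500 trees — are the
analysis's own defaults and run in minutes on one CPU.

## Known limitations

- The generator is univariate-calibrated; joint structure beyond
  site–gender and bone–metastasis is independence by construction.
- The GAN is evaluated by univariate fidelity only (as in the source
  analysis); no propensity-score or correlation-distance metrics.
- sOR is a classifier-relative measure; nothing here identifies causal
  effects.
- The elastic model implements only the α = 0 (ridge) limit actually used.
- Forest probabilities are uncalibrated vote fractions; see the calibration
  caveat above.
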