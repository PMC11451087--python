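# Methods

This note documents the statistical model behind each pipeline stage, the
design of the synthetic cohort generator, the numerical choices, and the
known limitations. It describes what the code computes; every number quoted
here is produced by the test suite or `scripts/acceptance.py` at run time.

## Hypothesis tests

Four tests are implemented self-contained (scipy supplies only distribution
functions — normal, t and χ² CDFs and the hypergeometric pmf):

* **Paired Wilcoxon signed-rank.** Zero differences are dropped before
  ranking (the classic convention; an all-zero vector returns p = 1), |d|
  is midranked, and W⁺ is the positive-rank sum. For tie-free inputs with
  n ≤ 20 the two-sided p is exact — the null distribution of W⁺ is built by
  the subset-sum recursion over ranks 1..n, equivalent to enumerating all
  2ⁿ sign assignments — with p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).
  Otherwise a normal approximation with the tie-corrected variance
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 and a 0.5 continuity correction is used.
  The cutoff of 20 guarantees the stability filter's 14-pair case is exact;
  this matters because the p > 0.8 retention rule sits in a region where
  the attainable exact p-values are sparse. `method="approx"` forces the
  approximation so both conventions are available.
* **Mann–Whitney U** (U reported for the first group): exact by enumerating
  all C(n, n_a) rank labelings for tie-free pooled samples with n ≤ 12,
  else the tie-corrected normal approximation with continuity correction.
* **Fisher's exact test** on a 2×2 table: the two-sided p sums the
  hypergeometric probabilities of all tables with the observed margins
  whose probability is ≤ that of the observed table (relative tolerance
  1e-7 on the comparison). This convention reproduces the published
  cohort-table values (0.030, 0.137, 0.476, 1.000) to three decimals.
* **Welch's t** with Satterthwaite degrees of freedom; two constant groups
  compare by mean (p = 1 when equal).

No multiple-testing correction is applied anywhere — faithful to the
analysis design being reproduced. For ~40k probe-level tests this is a
methodological caveat, not an oversight: the stability rule is a heuristic
screen, and its retained count should be read as such.

## Temporal-stability filtering

Stage 1 keeps probes with a nonempty gene annotation, then tests each over
exactly the patients present in both t0 and tr (14 under the default
design; a paired test cannot use the other 20). A probe is retained iff
p > threshold, strictly; the default threshold is 0.8. Because exact
small-n p-values are discrete, the retained count is sensitive to both the
strictness of the inequality and the exact/approximate branch choice —
both are surfaced (`p_threshold`, `--wilcoxon exact|approx`) rather than
hidden. Raising the threshold can only shrink the retained set (tested
property). Probes with any missing beta are dropped (with a logged count)
before filtering.

## LASSO feature selection

The selection objective is

  J(β₀, β) = (2n)⁻¹ Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + α‖β‖₁,

a squared-error (not logistic) LASSO on the 0/1 outcome (non-survivor = 1),
consistent with an MSE-based alpha-tuning diagnostic. It is minimized by
cyclic coordinate descent with soft-thresholding: an active set is swept to
convergence (max coefficient change < 1e-7), then a vectorized KKT pass
over all coordinates admits violators; the loop ends when no coordinate
violates |∇ⱼ| ≤ α (+1e-7). The intercept is unpenalized (optimal value
mean(y) after centering). Solutions satisfy the KKT conditions to 1e-6 and
match scikit-learn's `Lasso` to ~1e-6 on random problems (tested); a numba
JIT of the inner kernel is used when available, with an identical pure-numpy
fallback.

**Standardization.** Predictors are z-scored by default. With raw beta
values in [0,1] and a 0/1 response, the null-solution KKT bound caps the
largest useful penalty at max |cov(xⱼ, y)| = p(1−p)·Δβ ≤ 0.23·Δβ, so the
upper end of the conventional grid (α = 0.2, 0.25) could never select
anything on the raw scale; on the standardized scale the bound is
corr·sd(y) ≈ 0.45 and the whole grid is active. Reported coefficients are
on the fitting scale. `standardize=False` restores raw-scale fitting for
comparison.

**Grid conventions.** α = 0 is "no selection" — all stable probes are
marked retained and no n ≪ p unpenalized fit is attempted. The near-zero
α = 10⁻⁵ selects order-n features at loose effective convergence (the
penalty is below the achievable gradient resolution of an interpolating
fit); it is reported in the path summary but excluded, along with α = 0,
from the default selected-feature table, which lists the selective alphas
only. The optional per-alpha `cv_mse` (5-fold, seeded) is the alpha-tuning
diagnostic; it is off by default in repeated synthetic runs and exercised
by a dedicated test.

## Random-forest classification

scikit-learn's `RandomForestClassifier` with 500 trees, Gini criterion,
√p features per split, bootstrap resampling, `min_samples_leaf=1`, fixed
seed. The positive class is non-survivor; predicted probability is the
ensemble vote fraction; the decision threshold is 0.5.

LOOCV reports *per-fold binary indicators*: each fold holds one patient,
so fold accuracy is 1 iff correct, and precision/recall/F1 use the
undefined-as-zero convention (a held-out true negative contributes 0 to
all three even when predicted correctly). Summaries are mean ± population
SD, and for 0/1 indicators SD = √(m(1−m)) identically — this is the
structure behind "k/n ± √(p̂(1−p̂))"-style LOOCV tables, and it implies a
perfect classifier shows accuracy 1 ± 0 while its LOOCV precision/recall
equal the positive-class fraction. Transfer metrics are pooled
confusion-matrix quantities on the t2 predictions, with t2 features taken
as-is (no recalibration between timepoints — the transfer is the point).
EpiSAVE appends the SAVE score min-max scaled to [0,1] (constant scores
map to 0.5, an uninformative column).

## Survival evaluation

AUC is computed through the rank-sum identity U/(n₊n₋) with midrank ties;
its significance (AUC ≠ 0.5) uses the Mann–Whitney normal approximation
with tie correction rather than DeLong — a simpler convention that is
exact about its null. Clinical scores carry a direction flag (+1 for the
ICU severity scores, −1 for SAVE, whose higher values predict survival);
the output records the direction used. Kaplan–Meier estimation uses
lifelines' product-limit fitter (subjects censored at an event time count
as at risk for that event). The log-rank test is the Mantel–Haenszel
statistic with hypergeometric variance per event time, implemented
directly so per-group observed/expected counts are reported; it matches
lifelines and a naive per-time-table oracle to relative 1e-9 (tested).
Survival time origin is ECMO initiation; in-hospital death is the event;
survivors are censored at discharge.

Cohort comparisons ("Table-1 style") test binary covariates by Fisher's
exact test and continuous ones by Welch's t (summarized as median (IQR));
multi-level categoricals are reported descriptively without a p-value
unless explicitly collapsed to 2×2, and constant covariates are flagged
non-testable.

## Synthetic cohort generator

The generator emulates the study design: `n_patients=34` sampled at t0 and
t2, `n_tr=14` concluding ECMO (sampled with survivor bias 4:1 — patients
who conclude ECMO successfully are likelier to survive), 12 survivors vs
22 in-hospital deaths, 5000 probes by default (a `PAPER_SCALE` config
exists but is not used in CI).

* **Baselines.** Per-probe means follow the 450K bimodal mixture: logit-
  normal components at β ≈ 0.1 and 0.9 (45% each, sd 0.5) plus a 10%
  intermediate component. Per-sample values are Beta-distributed around
  the probe mean with concentration `beta_precision=50`, so support and
  heteroskedasticity of beta values are respected.
* **Probe roles.** `n_prognostic=10` probes shift by `prognostic_effect=1.3`
  logits in non-survivors at *all* timepoints; the shift points toward the
  logit midpoint (hypermethylated sites demethylate, hypomethylated sites
  gain), the typical differential pattern — and the one under which a
  logit-scale effect survives translation to the beta scale instead of
  saturating against the [0,1] boundary. `n_responsive=200` probes shift by
  `responsive_effect=1.5` logits at tr (half at t2) in every patient,
  modelling ECMO-driven drift. Effect sizes are calibrated for
  detectability at n = 34, not to mimic any measured cohort; with the
  defaults the LASSO recovers ≥ 8 of the 10 planted prognostic probes per
  seed.
* **Within-patient stability.** A patient's t0 and tr values of a stable
  probe share one intrinsic draw — within-patient change is exactly zero.
  This idealization is deliberate: a rank test's p-value is scale-
  invariant, so under *any* independent continuous within-pair noise the
  null p is uniform and a p > 0.8 rule would retain only ~20% of truly
  stable probes. The generator therefore models the stable epigenome as
  exactly reproducible; real arrays add technical noise, under which the
  p > 0.8 rule is a lossy screen rather than a clean separator. This is
  the main respect in which passing filter tests say less about real data
  than about the method's logic. `tr_noise_sd` re-enables within-pair
  noise for studying exactly that question.
* **The t2 snapshot** is drawn fresh around the same probe-level means
  (prognostic shift persisting, half the responsive drift) plus a patient-
  level logit offset (`patient_effect_sd=0.3`) shared across probes. The
  patient-level-only coupling is deliberate: if t2 instead reused the
  patient×probe draws, every *spurious* probe–outcome correlation at t0
  would be patient-intrinsic and would transfer to t2, and a no-signal
  cohort would yield transfer AUC far above chance. With per-probe
  redrawing, a no-signal cohort transfers at AUC ≈ 0.5 and planted
  prognostic signal transfers at AUC ≈ 1 (both measured by the acceptance
  script).
* **Survival and scores.** Non-survivor event times are
  Weibull(shape 1.2) with scale 12/HR^(1/1.2) days (`hazard_ratio=3` ⇒
  scale ≈ 4.8 d, so ~79% of deaths occur within 7 days, reproducing a
  ~17/17 early success/failure split); survivors are censored at discharge
  ~ U(30, 60) days. The five clinical scores load on one latent risk
  r = score_signal·1[non-survivor] + N(0,1) with per-score noise and
  realistic integer ranges; SAVE loads negatively (higher = better).
  Comorbidity covariates (diabetes, dialysis, hypertension, smoking,
  gender, age) have mild outcome associations for Table-1-style testing.
* Planted prognostic/responsive probes are always annotated
  (`frac_annotated` applies to the null probes), so the annotation filter
  cannot silently discard the structure under study. Everything is drawn
  from one `numpy` Generator seeded by `seed`; identical configs are
  bitwise-reproducible.

Not modelled: array chemistry (type I/II probe design, detection
p-values), batch and chip effects, cell-composition shifts, and any
genomic organization of probes — probes are exchangeable identifiers.

## Pipeline and reproducibility

Stage order: simulate/load → filter → select → classify → evaluate. Each
stage's seed derives deterministically from the global seed
(seed·1000003 + 7919·stage mod 2³¹); the manifest records version,
parameters, seeds, input hashes and the probe-count ledger
(total → complete → annotated → stable → selected per alpha), which is
monotone non-increasing. Result tables use fixed float formatting
("%.10g"; matrices "%.17g" for lossless round trips) and contain no
timestamps, so reruns are byte-identical. Default problem sizes (5000
probes, 34 patients, 5 replicate seeds in tests / acceptance) are chosen
as the smallest scale at which the planted-structure properties are
measurable with stable averages.

## Known limitations

* Testing on the same patients' t2 samples measures temporal persistence,
  not out-of-sample generalization; the design is reproduced faithfully
  and its optimism is inherited.
* The p > 0.8 retention rule has no false-discovery control and its
  retained count depends on the exact-vs-asymptotic branch at n = 14.
* Linear-LASSO selection on a binary outcome is a screening device, not a
  probability model; logistic LASSO and elastic-net variants are out of
  scope.
* The log-rank p-value relies on the χ²(1) asymptotic, which is coarse at
  n = 34 (it tracks a permutation p within ~0.03 in tests).
* LOOCV per-fold indicator summaries are one convention among several; it
  is implemented because it reproduces the k/n ± √(p̂(1−p̂)) structure of
  the reference results exactly.
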