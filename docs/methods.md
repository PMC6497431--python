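# Methods notes

## The measurement and the score

Q-MSP on bisulfite-converted DNA reports, per gene and specimen, an
amplification quantity for the methylated promoter sequence and one for the
β-actin reference. The methylation value is

    TaqMeth V = 100 · Q(target) / Q(β-actin),

replicates (typically triplicate) aggregated by the arithmetic mean of
quantities *before* the ratio. Two conventions matter downstream and are
enforced in the data model:

* a reference failure (`Q(β-actin) ≤ 0`) invalidates the specimen — mapping
  it to 0 would masquerade as "undetected methylation" and bias every
  cut-off downward;
* a gene never measured on a specimen is *missing*, distinct from a
  measured 0.0. Scores over incomplete panels are flagged and excluded
  from distributions rather than zero-filled.

Each gene contributes `1{TaqMeth V ≥ θ_gene}` to the 0–4 risk score. The
`≥` convention follows the scoring rule (a value equal to the cut-off earns
the point) and is used consistently in every scan and in sensitivity/
specificity bookkeeping. E-cadherin's assay has intrinsically lower PCR
affinity, so values are never rescaled across genes; all thresholds are
per-gene.

## Cut-off discovery

Candidate thresholds are the unique observed values, not midpoints — the
published thresholds look like observed measurements, and observed-value
candidates make scans invariant under strictly increasing transforms.
Objective ties break toward the larger threshold (higher specificity).

* **Diagnostic (tumor vs mucosa):** Youden's J over the candidate set; the
  reported AUC is the all-pairs concordance probability with ties ½.
* **Survival:** for each candidate leaving both groups with at least
  `ceil(min_group_frac · n)` members (default fraction 0.1), a two-group
  log-rank test; the minimum-p threshold is reported only when its p falls
  below α = 0.05, otherwise "no optimal cut-off" (`found = False`). The
  relative risk attached to a found cut-off is the univariate Cox hazard
  ratio of the `≥ θ` indicator.
* **Time to onset:** the same scan with a two-sided pooled-variance t-test
  on the biopsy lead times ("time to development" is the months from the
  biopsy to cancer onset). Group means/SDs/sizes are reported;
  sensitivity/specificity are descriptive, against the label "lead time ≤
  cohort median".

Minimum-p selection is anti-conservative (the selected p is the minimum of
many correlated tests); the scans log a warning once per call and default
to the uncorrected p for fidelity to common practice, with an optional
permutation-adjusted p (`n_permutations`).

## Statistical conventions

Pooled-variance Student t throughout, not Welch: on the published group
summaries (e.g. short/long-term splits (33, 62, 51) vs (10, 152, 113)) the
pooled form reproduces the printed p-values (0.0009, 0.02, 0.07) and Welch
does not. χ² is Pearson without continuity correction, df = 1. Gene–gene
association uses Spearman rank correlation because TaqMeth V margins are
zero-inflated and right-skewed. Survival: Kaplan–Meier with 5-year
administrative framing, log-rank via the standard pooled risk-table
statistic (implemented in-package, vectorized, because the cut-point scan
evaluates it at every candidate; it is cross-checked against lifelines),
Cox PH with Efron ties via lifelines. The univariate screen (p < 0.05,
log-rank for binary factors, univariate Cox for continuous) feeds a
multivariate Cox in which composite stage displaces the individual T/N/M
component factors. The propensity AUC is apparent (in-sample) by design —
the original analysis had no validation split — and a stratified 5-fold
cross-validated AUC is emitted alongside as an honesty output.

## The synthetic cohort

The generator's defaults are the study conditions; every number is tied to
a published summary.

* **Groups and terms.** 35 malignant-initial / 23 benign-initial patients.
  Terms from initial surgery to onset: normal(191.5, 127.5²) and
  normal(485.7, 86.7²) months, truncated at > 1 month. The printed values
  parameterise the *pre-truncation* normal; truncation lifts the realised
  malignant mean to ≈ 209.5 months (closed form: μ + σ·φ(a)/(1−Φ(a))), and
  sampling tests assert against that truncated-moment oracle.
* **TaqMeth margins.** Zero-inflated log-normals. Given a target overall
  mean m, SD s and zero mass π₀, the log-normal component solves
  m₁ = m/(1−π₀), m₂ = (m²+s²)/(1−π₀), σ² = ln(m₂/m₁²), μ = ln m₁ − σ²/2 —
  so the configured margin has the printed moments *exactly*, for any
  admissible π₀ < s²/(m²+s²). For tumor (RT) and remnant-mucosa (RN)
  margins, π₀ is calibrated by bounded scalar search so that
  P(V ≥ θ_diagnostic) matches the published above-cut-off proportions
  (e.g. RT-CDO1 π₀ ≈ 0.15 → 82.8% above 6.49; RT-ECAD π₀ ≈ 0.90 → 10.3%
  above 1.09, consistent with that assay's rarely-methylated behaviour).
  Margins without a published proportion (initial-surgery mucosa, biopsy)
  use π₀ = 0; biopsy margins default to the pooled RN parameters, and RN is
  pooled across diagnosis groups (no per-group RN summaries are published;
  a log-scale group-shift knob exists for sensitivity analysis — which also
  means the methylation-only propensity discrimination is near chance in
  simulation by construction).
* **Dependence.** A Gaussian copula with pairwise latent ρ = 0.6 among
  CDO1/HOPX/Reprimo and zero to E-cadherin. The trio is reported as
  mutually correlated but no coefficients are given; ρ is a knob, not a
  claim. After the
  zero-inflated transform the realised Spearman of the trio falls in
  ≈ 0.45–0.6.
* **Biopsies.** 43 specimens over 12 malignant-initial patients; lead
  times truncated-normal(83.6, 78.5²) months, capped below each patient's
  own term (collisions within a patient are redrawn — endoscopies are
  distinct visits). Methylation couples to lead time on the latent scale,
  `z' = √(1−λ²)·z − λ·w`, with per-gene λ (0.41/0.51/0.70/0.25) calibrated
  once by large-n simulation so the fitted r² of value on lead time lands
  at the published weak values (0.06/0.11/0.14/0.015), slopes negative.
* **Survival.** Exponential event times; stage ≥ III carries a hazard
  ratio of 3 (configurable) over baseline 0.010/month (OS) and an added
  relapse hazard 0.008/month; administrative censoring at 60 months.
  RFS = min(relapse, death) so RFS ≤ OS holds by construction.
* **Clinical margins.** Sex 51:7, age split 29:29 at 70 years, stage
  ≤ II : ≥ III = 46:12, and the remaining categoricals at their published
  marginal counts, scaled proportionally for other cohort sizes and
  shuffled by the seeded generator. All randomness flows from one
  `numpy` Generator per seed: identical seeds give byte-identical output
  tables.

**What the generator does not emulate:** within-patient correlation of
methylation across compartments, longitudinal drift along one patient's
biopsy series, assay batch effects, or any real per-group difference in RN
methylation. Passing tests therefore demonstrate that the *procedures* are
correct and that cohort-level summaries are reproduced under the published
marginal structure — not that the panel's clinical effect sizes would
replicate in new patients.

## Numerical and testing choices

* Copula uniforms are clipped to [1e-12, 1−1e-12] before the quantile
  transform; TSVs are written with shortest round-trip float repr, so
  write→read is exact and runs are byte-reproducible (SHA-256 digests in
  the manifest).
* Logistic fits are unregularized ML; complete separation is detected
  (exception or |standardized coef| > 30) and flagged, with scores taken
  from the iteration-capped fit rather than silently penalized.
* Heavy-tailed margins (component σ ≳ 0.8, all Reprimo margins in
  particular) make the *sample SD* at n = 10⁵ an estimator with 2–12%
  analytic sampling error — no correct implementation can pin it to 2%
  there. The moment tests therefore assert the sampled mean (2%) for every
  margin, the sampled SD (2%) only where the estimator's closed-form
  standard error resolves that tolerance (decided from the margin's exact
  fourth moment before any sampling), and the exact mixture-moment identity
  for all margins.
* Simulation-based test sizes are chosen to keep the default suite around
  half a minute: e.g. 40 replicates at n = 120 for the hazard-switch
  recovery of the log-rank scan, 300 null cohorts for the minimum-p
  inflation property, 120 replicates for Cox CI coverage, 200 cohorts for
  the replicated propensity AUC. The acceptance script's only stochastic
  quantity (the median replicated AUC) uses 200 cohorts seeded from
  `--seed`.

## Known limitations

* The minimum-p cut-points and the apparent AUC are reported uncorrected by
  default because that is the procedure being modelled; both are flagged in
  logs and manifest warnings, and corrected companions (permutation p,
  CV AUC) are available.
* `relative_risk` is defined as the univariate Cox HR of the dichotomy —
  the original report does not define its "relative risk".
* Score distributions silently reflect only complete four-gene panels;
  cohorts with substantial missingness will show a logged exclusion count
  that should be reported alongside the percentages.
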