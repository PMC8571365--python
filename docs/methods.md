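# Methods

## Scope and data model

The package operates on patient-level trauma-registry tables: one row per
admission (demographics, external-cause E-code or precoded mechanism,
Glasgow Coma Scale, systolic blood pressure, pulse, respiratory rate, ICU and
ventilator days, length of stay, comorbidity codes or a precomputed Charlson
index, outcome, hospital id, administrative flags) and one row per injury
(AIS 2005 six-digit predot code plus severity digit 1–6 or 9 = unknown).
Cohort preparation validates every row, applies a fixed exclusion cascade,
and splits patients 66.6 / 16.7 / 16.7 % into derivation (WMDP estimation),
fitting (coefficient refit) and validation partitions by seeded simple random
assignment at the patient level. Exclusions run in a fixed order —
nontraumatic/overexertion/burn mechanism, missing cause of injury,
missing/invalid core fields, age > 89, age < 1, emergency-department-only,
dead on arrival, transferred, all-injuries-severity-9, hospital below 500
trauma patients per year — and each patient is charged to the first rule it
trips, so per-rule counts are order-dependent while the ledger identity
`n_in = n_out + Σ excluded` always holds. Whether the disposition flags
(ED-only, transfer) should precede or follow the missing-data rule is not
determinable from the method description; the listing order above is used.

## WMDP: per-code weighted median death probability

For each predot code the derivation partition yields counts D₁/T₁ (deaths /
bearers among single-injury patients) and D₂/T₂ (among multiple-injury
patients), with duplicate identical codes within one patient counted once.

* **SMR** = D₁/T₁ where T₁ > 0 — the code's own observed lethality.
* **TDP**: each multiple-injury bearer contributes `1{died} / K`. The
  attribution constant K defaults to 4.404 × 0.618 = 2.721672 (mean injuries
  per patient scaled by 0.618); `WMDPConfig.from_cohort` recomputes the mean
  from data. The three largest TDP values are retained (count N_u ≤ 3).
* **WMDP** = weighted median of {SMR} ∪ {top TDP values}, SMR weighted 0.618
  and each TDP candidate (1 − 0.618)/N_u; for codes never seen as an isolated
  injury the TDP candidates carry equal renormalized weight. The weighted
  median is the smallest candidate at which the normalized cumulative weight
  reaches ½; when it hits ½ exactly, the lower of the two middle candidates is
  taken. Because the SMR weight exceeds ½, the weighted median equals the SMR
  whenever a code has single-injury bearers — the TDP candidates decide only
  codes observed exclusively in multi-injury patients. All three ingredients
  (attribution constant, SMR weight, candidate rule) are config-exposed so
  alternative readings of the combination rule can be tested.
* **PMR fallback**: a code with no observed deaths among any bearer receives
  the median possible mortality rate of its bearers,
  `PMR(age) = 0.01202 · exp(0.0719 · age)` — an exponential age trend standing
  in for the unobservable crude death rate. The formula exceeds 1 beyond age
  ≈ 61, so fallback scores are death propensities, not probabilities; a
  monotone `output_transform` hook (identity by default) is provided for
  users who want a different final scale rather than guessing one.

Derivation is deterministic: any row ordering of the same cohort produces the
same table, sorted by predot. The table round-trips through a TSV with
columns `predot, D1, T1, D2, T2, smr, mmr, n_u, pmr_m, wmdp`; this file is
the contract between derivation and scoring.

## The TRIMP probit model

Nineteen predictors: the five highest WMDP values of the patient's injuries
(descending, zero-padded below five — the convention of anatomy-profile
models; injuries tie-broken by higher severity digit, then predot, so the
same-region flag is deterministic), their top-two product, a same-body-region
indicator for the two worst injuries, the number of injured ISS body regions
NBR and its fractional-polynomial companion NBR^0.382 (exponent fixed, not
re-estimated), age and GCS untransformed, male indicator, Charlson index
(Deyo ICD-9 mapping, each condition once, standard severity hierarchies),
mechanism as a single ordinal covariate 1–6, ICU and ventilator indicators
(`days > 0`), and ordinal derangement codes for SBP, pulse and respiratory
rate. The death probability is Φ(linear predictor).

Vital-sign coding is a declared convention, not part of the published method
(its appendix is unavailable): the packaged default reverses the classic
Revised-Trauma-Score bins so that 0 = normal and larger = worse (SBP ≥ 90 →
0, 76–89 → 1, 50–75 → 2, 1–49 → 3, 0 → 4; analogous two-sided tables for
pulse and respiratory rate), which makes the positive published coefficients
point in the right direction. Tables are fully configurable; validation
rejects overlapping intervals and code sequences that are not
monotone-to-normal ("valley" shaped).

The published coefficient table ships in JSON and is returned bit-exactly by
`published_coefficients()`. `fit_trimp` refits by maximum-likelihood probit
(statsmodels) with HC1 sandwich standard errors, requires ≥ 50 events and
≥ 50 non-events, and reports rank-deficient designs by naming the dependent
columns. Patients whose code is missing from the WMDP table raise an error by
default; `on_missing="pmr"` substitutes the patient's age-based PMR.

## TRISS comparator

ISS ignores severity-9 injuries (all-9 patients are an error upstream, an
exclusion in the cascade), takes per-region maxima, sums the three largest
squares, and returns 75 on any severity-6 injury. RTS uses the standard 0–4
coded GCS/SBP/RR intervals and weights (0.9368, 0.7326, 0.2908). Survival is
logistic in RTS, ISS and an age index with mechanism-specific coefficient
sets; stab and firearm wounds count as penetrating, all other mechanisms as
blunt. The packaged set is the 1987 Major Trauma Outcome Study calibration
with the binary age index (≤ 54 → 0). Revised coefficient vintages are not
packaged — their values could not be verified against a primary source at
build time — but the loader accepts user JSON with either the binary
threshold or five-band age coding, so any revision drops in without code
changes.

## Evaluation harness

* **AUC**: Mann–Whitney concordance (scikit-learn's rank-based
  implementation); single-class strata report no AUC.
* **Hosmer–Lemeshow**: g = 10 equal-count risk groups by predicted death
  probability (the conventional deciles; the group count is not specified by
  the method), statistic Σ (O−E)²/(E(1−E/n_g)). Zero-variance groups are
  merged into a neighbor with a log note.
* **AIC** = 2k − 2 lnL with lnL the Bernoulli log-likelihood on the
  evaluation cohort. For models applied with fixed published coefficients, k
  counts the published coefficients (20 for TRIMP, 8 for the two TRISS
  logistic sets by default, overridable) — a documented convention, since
  information criteria for non-refit models are not otherwise defined.
* **Bootstrap**: bias-corrected (BC, not BCa) percentile intervals from B
  patient-level resamples (1000 by default), z₀ estimated from the proportion
  of resample statistics below the point estimate, degenerate data returning
  a degenerate interval. Within model comparison the resample streams are
  derived per stratum and shared across models (paired resamples), so
  identical predictions give identical report rows; strata too small for a
  stable resample statistic report the point estimate without an interval.
* **Calibration**: 10 equal-count bins of predicted survival (equal-width
  optional) with exact Clopper–Pearson 95% intervals on observed survival.
* **Stratification**: overall plus the six ISS body regions of the worst
  injury, ranked by severity digit with the same tie-break as feature
  construction, so strata align across models being compared.

## Synthetic registry generator

The generator exists so every stage has known ground truth. Each synthetic
predot code carries a latent lethality in [0, 1] that plays the role of its
true WMDP; patient outcomes are Bernoulli draws from Φ(true linear predictor)
computed on the true feature vector, so score derivation and coefficient
fitting are both recovery problems with a right answer.

Structural conditions emulated (generator defaults): mean 3.47 injuries per
patient with 28% single-injury admissions (single w.p. 0.28, else
2 + Poisson, matching the mean); power-law code frequencies (`rank^-1.2`);
mechanism mix dominated by falls (44.6%) and motor-vehicle crashes (32.6%);
62.1% male; bimodal age mixture (young-adult and elderly peaks, medians near
the high-40s); ~12% ventilated and ~25% ICU admissions; ~3.03% overall
mortality. Physiology (GCS, SBP, pulse, RR) worsens with a patient's
anatomical load through a deliberately mild sigmoid coupling plus noise.

Two generator choices are driven by estimability rather than realism, and
matter for interpreting recovery results. First, the default catalog is small
(24 codes spanning all nine AIS chapters and hence all six body regions) with
distinct, evenly spaced lethalities ordered by severity: because the weighted
median collapses to the SMR, recovering a code's lethality rank requires
enough single-injury bearers that its observed death rate is informative
(E[deaths per code] well above 1 at the cohort sizes used); a realistic
1,980-code catalog at desk scale would leave most codes with uninformative
zero counts. Second, the physiology–anatomy coupling is kept weak so the
anatomy coefficients, not physiology tails, carry the mortality gradient
across codes. Passing recovery tests therefore shows the estimators work
where the signal is statistically recoverable; they do not show that a
200,000-patient registry could rank two thousand real codes.

The intercept of the true coefficient table is re-solved (Brent's method) so
that expected mortality over the generator's feature distribution equals the
configured target (3.03% by default), using a fixed-size internal feature
sample (30,000) whose seed derives from the config seed — the truth is
therefore independent of `n_patients`, and `known_truth` returns exactly the
quantities used to draw outcomes. Cohorts are fully reproducible from the
catalog and config seeds.

Not emulated: real marginal distributions of any registry beyond the summary
conditions above, hospital-level clustering, code-specific physiology
signatures, correlated comorbidity structure, and ICD-10 coding.

## Numerical conventions and problem sizes

Weighted-median ties take the lower candidate; probabilities are clipped at
1e-12 for log-likelihoods; probit fits run to 200 iterations with
convergence checked; bootstrap z₀ proportions are clipped away from 0 and 1
at 1/(B+1). Recovery checks in the test suite use 50,000 patients for
coefficient refitting (all 20 coefficients within three robust standard
errors of truth on the reference seeds, with 18/20 the asserted floor),
200,000 patients for WMDP rank recovery (Spearman 0.96 on the reference
seeds against the > 0.9 floor, over codes with ≥ 50 bearers), 500 × B = 500
repetitions for bootstrap coverage of a mean at n = 200 (93–97% band), and
30,000 patients for the TRIMP-vs-TRISS comparison. These sizes were chosen
so each check is decisively powered at desk scale.

## Known limitations

The exact published combination rule behind the WMDP (and the scale on which
published extreme values like 2.7469 live) is not fully specified in the
method description; the canonical interpretation implemented here keeps
scores on the probability scale whenever deaths are observed, and the PMR
fallback reproduces values above 1 only through the age exponential. The
E-code → mechanism ranges and the vital-sign bins are editable packaged
conventions. ISS body regions for spine injuries are assigned from the
vertebral-level digit with cervical as the default for unrecognized level
digits. The hospital-volume exclusion assumes the file covers whole calendar
years (`n_years` configurable). Mechanism enters the probit model as ordinal
1–6; whether the published model dummy-coded it cannot be determined from a
single printed coefficient.
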