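# Methods

This note documents the models, conventions and design choices behind
`ihtminer`. The package mirrors a published exploratory analysis of
in-hospital mortality after interhospital transfer; the protected EHR
cohort behind that analysis is replaced here by a calibrated synthetic
generator, so every statement below about empirical behaviour refers to
quantities the test suite or `scripts/acceptance.py` actually computes.

## Rule mining

Rules take the form X ⇒ death, where X is a set of 1–4 prefix-named
diagnosis indicators and the consequent is fixed: in-hospital death.
The search is classical Apriori — levelwise candidate generation with
subset pruning, justified by the anti-monotonicity of support — with
counting done on packed per-item patient bitsets (one `np.packbits`
vector per item; a candidate's count is the popcount of its parents'
intersection). An exhaustive enumerator (`brute_force_mine`, guarded to
≤ 16 items) provides the reference semantics the miner is tested
against on random matrices; it deliberately shares none of the
levelwise machinery.

Conventions, fixed after genuinely open readings of the source method:

* **Support floor.** "Minimum left-hand support of 25 subjects" is an
  absolute carrier count on the antecedent alone, outcome-agnostic.
  Default `min_antecedent_count=25`, `max_order=4`.
* **Two lifts.** The textbook definition of lift for an itemset
  (observed co-occurrence over the independence expectation) conflicts
  with how mortality-rule tables in this domain are actually printed,
  where the "lift" column equals confidence ÷ baseline mortality. Both
  are computed on every rule — `lift_outcome` (the printed convention)
  and `lift_cooccurrence` — and reports label them explicitly rather
  than guessing. The identity `lift_outcome × (D/N) = confidence` holds
  to float precision by construction and is asserted in tests.
* **No confidence threshold.** Rules are ranked, never thresholded on
  confidence.
* **Determinism.** Output order is (order, lexicographic antecedent);
  ties in ranked reports break lexicographically.

## Minimum-improvement filtering

A rule's improvement is `100 × (confidence − best)`, where `best` is
the maximum confidence over *all* proper non-empty sub-antecedents that
met the support floor, plus the cohort baseline (so single-item rules
are filterable against baseline). Rules below 10 percentage points are
dropped.

* "10% higher" is read as an **absolute margin of 10 percentage
  points**. The worked clinical example (72.6% for the two-way rule
  against singletons at 59.3% and 25.0%, margin 13.3 pp) passes under
  either the absolute or the relative reading; the absolute reading
  matches the confidence-minus-confidence arithmetic of the source
  description. A relative mode exists behind `relative=True`.
* The comparison spans all proper subsets, not only the immediate
  (k−1)-subsets — the stricter, literal reading of "any of the
  subcombinations". The two coincide whenever confidence is monotone
  along the lattice.
* Sub-antecedents below the support floor have unknown confidence under
  the search constraints; they are skipped with a log note, never
  imputed.

## Odds ratios

Unadjusted: OR = ad/bc from the exact 2×2 carrier-by-death table, CI =
exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)). Tables with a zero cell get the
Haldane–Anscombe +0.5 added to every cell and the estimate is flagged;
a fully empty row or column is an error. Wald intervals are used
throughout because the source analysis's CI method is unstated and its
printed intervals show Wald-style asymmetry on the log scale.

Adjusted: one logistic regression **per rule** — death on the carrier
indicator plus age (years, continuous, entered linearly), sex
(reference Male) and race (reference White; dummies for Black, Other).
Covariate coding is a convention fixed here and recorded in every
report; the source analysis does not state it. No multiple-testing
adjustment is applied, matching the exploratory framing of the method.

The fit is maximum likelihood by iteratively reweighted least squares,
implemented in the package (the fit is part of the contribution, and
statsmodels serves as an independent cross-check in the tests, agreeing
to 1e-6 in coefficients and standard errors). Numerical details:
intercept initialized at the empirical logit; convergence when the
deviance changes < 1e-8, cap 50 iterations; Newton steps are halved
(≤ 30 times) whenever they would increase the deviance, which is what
rare, nearly separated carrier indicators otherwise provoke; standard
errors from the inverse observed information; |coefficient| > 15 flags
probable separation; rank-deficient designs raise an error naming the
collinear columns (pivoted QR).

### Reconstruction oracle

`reconstruct_table(N, D, coverage %, confidence %)` inverts printed
one-decimal summaries into an integer table: n₁ = round(coverage·N/100)
carriers, a = round(confidence·n₁/100) carrier deaths, the rest from
the margins. Applied to the published high-impact rows with coverage
≥ 0.5% it reproduces the printed unadjusted ORs within 5% (one
three-way row lands exactly on that boundary at 5.004%; the printed
one-decimal rounding of coverage and confidence is precisely what
bounds the achievable agreement, and rows below 0.5% coverage are too
small for the inversion to be meaningful).

## Synthetic cohorts

Per patient: age ~ TruncNormal(63.5, 14.3) on [21, 90], integer-rounded
and top-coded at 90 (mirroring the deidentification convention of the
source cohort); sex and race categorical at the published mix; a single
latent burden factor Z ~ N(0,1); item presence Bernoulli with log-odds
`b_j + λ_j Z + α_j·(age−63.5)/10`. The shared loading λ_j induces the
positive co-occurrence heavy multimorbidity shows without asserting an
unreported correlation structure — one factor is the simplest mechanism
that does it. The per-item age loading α_j (small and positive for
chronic comorbidities) couples item prevalence to age, which is what
makes age a genuine confounder for age-loaded antecedents and gives the
adjusted-vs-unadjusted contrast something real to test against.

Death is Bernoulli with log-odds `β₀ + Σ β_j x_j + Σ_S γ_S ∏_{j∈S} x_j
+ covariate terms` (0.5 per decade of age, +0.15 for Female, 0 by race,
consistent with the published stratified rates). The intercept β₀ is
calibrated by bisection on a fixed probe sample from a dedicated seed
stream, deterministic given the config seed, to hit the 11.7% mortality
target within 0.002; `solve_interaction_gamma` does the analogous
bisection for a planted interaction's carrier mortality, re-calibrating
β₀ at every step.

The default catalog (`data/default_cohort.yaml`, versioned; loaded by
`default_config()`) has **71 items**: per-subcategory prevalence sums
match the published mean diagnosis counts (≈ 2.9 pdx, 5.1 pl, 8.1 dx,
6.2 cm, 2.1 hx, 1.1 ddx per patient), which cannot be reached with
fewer items while keeping every per-item prevalence ≤ 0.75. Items
named in the published combination tables carry their published
coverages (acidosis 12.6%, cardiac arrest 1.6%, acute respiratory
failure ≈ 9.6%, …); all other per-item prevalences are **plausible
inventions** — the source never reported them — and are labeled as such
in the YAML. The YAML stores prevalences; base log-odds are recovered
at load time by Gauss–Hermite inversion of the marginal
`E[σ(b + s·Z)]`, folding the burden and age loadings into one effective
latent sd (the age truncation makes this approximate, to a few tenths
of a percent).

Three interactions are planted, with γ frozen from the bisection
solver: acidosis + cardiac arrest at ≈ 0.72 model-implied carrier
mortality (the recovery target used in acceptance checks; ≈ 140
carriers per 50,000 patients), counseling + atelectasis at ≈ 0.77, and
a dyspnea/hypotension/respiratory-failure triple at γ = 0.8.
Survivor discharge dispositions are sampled from the published
proportions renormalized over the non-death categories — disposition is
descriptive only.

What the generator does **not** emulate: real ICD code semantics (the
default mapping uses synthetic `SYnn.n` codes, one per item,
bijectively — which is also what makes the records → indicators round
trip exact), transfer logistics, lengths of stay, clinical/
administrative source disagreement, per-item prevalence tails, or any
dependence structure beyond one latent factor. Passing tests therefore
demonstrate that the pipeline recovers signals of the planted form at
the study's scale and noise level, not that it would rank real clinical
combinations identically.

## Problem sizes in the checks

Monte-Carlo checks run at n = 50,000 (calibration within 0.01 of
target, planted-pair recovery, zero-confounding aOR/OR agreement within
5%), parameter recovery at 100 replicates of n = 5,000 (each
coefficient within 2 SE of truth in ≥ 93 replicates — the nominal rate
is 95.45%, so this condition carries an inherent few-percent
false-alarm risk per coefficient), miner/oracle equivalence on 50
random 200×12 matrices, and the pipeline demo at the cohort's own
n = 8,893 with antecedent order ≤ 3.

## Known limitations

* The improvement filter compares against sub-rules' point confidences;
  no statistical uncertainty on the margin is propagated (the source
  method defines none).
* Wald CIs misbehave for very sparse tables even after the +0.5
  correction; estimates from corrected tables are flagged, not
  suppressed.
* One adjusted model per rule means overlapping rules are not mutually
  adjusted; this mirrors the source design.
* The co-occurrence lift uses the independence expectation from
  marginal prevalences only.
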