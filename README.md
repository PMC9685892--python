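# ihtminer

Association-rule mining of high-mortality diagnosis combinations in
interhospital-transfer (IHT) cohorts.

Patients transferred between hospitals die in hospital far more often than
non-transferred patients, and single-diagnosis risk models miss the
combinations of conditions that drive the worst outcomes. `ihtminer`
implements, as a reusable and tested pipeline, the analysis used to find
those combinations in a cohort of 8,893 adult critical-care transfers
(11.7% in-hospital mortality):

1. **Subcategorized indicators** (`code_mapping`) — each ICD-9/10-style
   diagnosis code is mapped through a user-supplied table to a clinical
   concept in one of six subcategories (primary/admitting `pdx`, problem
   list `pl`, unassigned `dx`, comorbidity `cm`, history `hx`, discharge
   `ddx`) and flagged as a 0/1 indicator named `<prefix>_<Concept>`.
2. **Apriori rule mining** (`rule_mining`) — levelwise search over 1–4-item
   antecedents X for rules X ⇒ death, with a minimum left-hand support of
   25 subjects. For antecedent carried by n_x patients of whom n_xy died:

       coverage   = n_x / N
       confidence = n_xy / n_x                (carrier mortality)
       lift       = confidence / (D / N)     (outcome form)

   plus the classical co-occurrence lift n_x / (N·∏ prevalenceⱼ), reported
   separately.
3. **Minimum-improvement filtering** (`redundancy_filter`) — a rule is kept
   only if its confidence exceeds the best confidence among all of its
   proper sub-combinations (and the cohort baseline) by ≥ 10 percentage
   points.
4. **Effect estimation** (`effect_estimation`) — unadjusted odds ratios
   from exact 2×2 tables (Wald CIs, Haldane–Anscombe correction for zero
   cells) and adjusted odds ratios from a self-implemented IRLS logistic
   regression of death on the carrier indicator controlling for age, sex
   and race; also a reconstruction oracle that inverts printed
   (coverage %, confidence %) summaries back into integer 2×2 tables.
5. **Reports and CLI** (`reporting`, `cli`) — prevalence-ranked and
   impact-ranked rule tables as CSV/markdown/JSON, with full-precision
   companions, and `ihtminer` subcommands for every stage.

Because the underlying EHR data are not shareable, `synthetic_cohort`
generates seeded cohorts with the published marginal structure (age
truncated-normal and top-coded at 90, published sex/race mix, six
subcategories with published mean diagnosis counts, calibrated 11.7%
mortality) and *planted* high-risk interactions — e.g. comorbid acidosis
with an admitting diagnosis of cardiac arrest at ≈ 72% carrier mortality —
that the downstream pipeline provably recovers.

## Worked example

Run the whole pipeline on a synthetic cohort at the study scale:

```python
from ihtminer import run_pipeline

result = run_pipeline({
    "seed": 1,
    "output_dir": "out",
    "simulate": {"n_patients": 8893},
    "mine": {"min_count": 25, "max_order": 3},
    "filter": {"min_improvement": 10.0},
    "estimate": {"top_k_per_order": 5},
    "report": {"formats": ["csv", "markdown"], "top_k": 5},
})
print(len(result.rules), len(result.retained), len(result.estimates))
```

This mines 45,092 rules, retains 361 after improvement filtering, fits
adjusted models for the top 15, and writes `out/report_impact.md`
containing (abridged):

| antecedent                          | coverage_pct | confidence_pct | lift_outcome | improvement_pp | odds_ratio | adjusted_or |
|-------------------------------------|-------------:|---------------:|-------------:|---------------:|-----------:|------------:|
| ddx_DNR                             | 0.3          | 71.0           | 5.94         | 59.0           | 18.39      | 17.00       |
| dx_Encounter.for.counseling         | 0.6          | 63.2           | 5.29         | 51.2           | 13.05      | 13.48       |
| pdx_Cardiac.Arrest                  | 1.5          | 54.9           | 4.60         | 42.9           | 9.56       | 10.58       |
| cm_Acidosis & pdx_Cardiac.Arrest    | 0.4          | 68.8           | 5.76         | 13.9           | 16.54      | 18.26       |

Reading the acidosis & cardiac-arrest row: 0.4% of the cohort carries both
diagnoses, 68.8% of those carriers die in hospital (5.76× the cohort
baseline), that mortality is 13.9 percentage points above the deadlier of
the two singleton rules (so the combination adds information), and the
covariate-adjusted odds ratio of death for carriers is 18.3. The planted
end-of-life and cardiac-arrest signals dominate the ranking, exactly as
the corresponding combinations do in the real cohort.

The same pipeline is scriptable from the shell:

```bash
ihtminer simulate --n 8893 --seed 1 --out-dir cohort
ihtminer map --records cohort/records.csv --mapping cohort/mapping.csv \
             --demographics cohort/demographics.csv --out indicators.csv
ihtminer mine --indicators indicators.csv --min-count 25 --max-order 4 --out rules.jsonl
ihtminer filter --rules rules.jsonl --min-improvement 10 --out retained.jsonl
ihtminer report --rules retained.jsonl --rank-by confidence --out report.csv
```

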