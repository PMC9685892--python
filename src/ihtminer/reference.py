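"""Published summary statistics of the motivating transfer cohort.

The EHR cohort behind this package (8,893 adult critical-care transfer
episodes, 1,041 in-hospital deaths) is not publicly available; what is
available are its published summary tables. Those printed summaries are
themselves inputs to the consistency checks here: the outcome-form lift
identity (lift = confidence / baseline mortality) and the 2x2-table
reconstruction oracle in :mod:`ihtminer.effect_estimation` both operate
on these numbers, not on patient data.

Concept names are normalized from the printed tables (obvious
typographical slips such as doubled dots are cleaned); values are
carried exactly as printed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Cohort totals: transfer episodes and in-hospital deaths.
REFERENCE_N = 8893
REFERENCE_DEATHS = 1041


@dataclass(frozen=True)
class ImpactRow:
    """One published high-mortality combination with its printed summaries.

    ``coverage_pct`` and ``confidence_pct`` are the printed one-decimal
    percentages; ``odds_ratio`` / ``adjusted_or`` and the aOR CI are the
    printed two-decimal values.
    """

    antecedent: tuple[str, ...]
    coverage_pct: float
    confidence_pct: float
    odds_ratio: float
    adjusted_or: float
    aor_ci: tuple[float, float]


#: Highest-impact combinations, ranked as published (by aOR within order).
IMPACT_ROWS: tuple[ImpactRow, ...] = (
    # individual diagnoses
    ImpactRow(("pdx_Cardiac.Arrest",), 1.6, 59.3, 11.89, 13.09, (9.21, 18.57)),
    ImpactRow(("dx_Encounter.for.counseling",), 0.7, 64.7, 14.39, 13.01, (7.75, 21.83)),
    ImpactRow(("ddx_DNR",), 0.4, 65.9, 14.97, 12.12, (6.35, 23.14)),
    ImpactRow(("pl_Acute.respiratory.failure",), 9.6, 29.4, 3.83, 4.00, (3.37, 4.73)),
    ImpactRow(("dx_Other.ascites",), 1.1, 28.0, 2.98, 3.56, (2.26, 5.60)),
    ImpactRow(("ddx_Acute.respiratory.failure",), 1.2, 33.3, 3.87, 3.39, (2.23, 5.14)),
    ImpactRow(("cm_Acidosis",), 12.6, 25.0, 3.07, 3.37, (2.87, 3.95)),
    ImpactRow(("dx_Hypothermia.due.to.exposure",), 0.5, 30.4, 3.33, 3.26, (1.69, 6.26)),
    ImpactRow(("hx_ARF.with.tubular.necrosis",), 0.9, 24.4, 2.46, 2.65, (1.57, 4.45)),
    ImpactRow(("hx_Coagulopathy",), 1.3, 29.1, 3.16, 2.54, (1.68, 3.84)),
    # two-way combinations
    ImpactRow(("pl_Atelectasis", "dx_Encounter.for.counseling"), 0.3, 76.7, 25.32, 24.75, (10.29, 59.50)),
    ImpactRow(("cm_Acidosis", "pdx_Cardiac.Arrest"), 0.5, 72.6, 20.63, 21.97, (11.62, 41.52)),
    ImpactRow(("pl_Hypotension", "pdx_Cardiac.Arrest"), 0.2, 68.0, 16.27, 20.12, (8.53, 47.47)),
    ImpactRow(("cm_Essential.Hypertension", "ddx_DNR"), 0.3, 74.2, 22.15, 18.22, (7.95, 41.72)),
    ImpactRow(("cm_Essential.Hypertension", "dx_Encounter.for.counseling"), 0.4, 72.5, 20.42, 16.37, (8.02, 33.36)),
    ImpactRow(("pl_Acute.respiratory.failure", "pdx_Cerebral.Hemorrhage"), 0.5, 55.1, 9.47, 8.37, (4.68, 14.96)),
    ImpactRow(("cm_Congestive.heart.failure", "hx_ARF.with.tubular.necrosis"), 0.3, 50.0, 7.63, 6.72, (3.14, 14.35)),
    ImpactRow(("pl_Atelectasis", "ddx_Acute.respiratory.failure"), 0.3, 42.3, 5.57, 5.71, (2.54, 12.79)),
    ImpactRow(("pl_Acute.respiratory.failure", "dx_Encounter.due.to.CABG"), 0.4, 44.4, 6.11, 5.55, (2.82, 10.91)),
    ImpactRow(("ddx_Kidney.Failure.Acute", "ddx_Atrial.Fibrillation"), 0.2, 48.0, 7.03, 5.55, (2.47, 12.43)),
    # three-way combinations
    ImpactRow(("pl_Dyspnea", "pl_Hypotension", "pl_Acute.respiratory.failure"), 0.3, 48.0, 7.03, 7.90, (3.49, 17.88)),
    ImpactRow(("cm_Acidosis", "pl_Atrial.Fibrillation", "pl_Hypotension"), 0.4, 50.0, 7.65, 6.91, (3.46, 13.76)),
    ImpactRow(("cm_Essential.Hypertension", "pl_Hypotension", "dx_ECG.abnormalities.non.specific"), 0.3, 42.9, 5.71, 6.32, (2.93, 13.60)),
    ImpactRow(("cm_Anemia", "cm_Acidosis", "dx_Long.term.use.of.medications"), 0.4, 46.0, 6.50, 6.00, (3.07, 11.70)),
    ImpactRow(("pl_Kidney.Failure.Acute", "cm_Acidosis", "cm_Chronic.atrial.fibrillation"), 0.6, 48.2, 7.07, 5.94, (2.72, 12.95)),
    ImpactRow(("cm_Congestive.heart.failure", "cm_Acidosis", "dx_Long.term.use.of.medications"), 0.6, 43.2, 5.82, 5.92, (2.98, 11.73)),
    ImpactRow(("cm_Congestive.heart.failure", "pl_Acute.respiratory.failure", "dx_Abnormal.blood.chemistry"), 0.3, 46.4, 6.60, 5.58, (2.57, 12.10)),
    ImpactRow(("cm_Essential.Hypertension", "pl_Acute.respiratory.failure", "cm_Chronic.Kidney.Diseases"), 0.4, 45.7, 6.43, 5.57, (2.81, 11.00)),
    ImpactRow(("cm_Anemia", "cm_Acidosis", "pl_Acute.respiratory.failure"), 0.7, 40.0, 5.13, 5.32, (3.19, 8.87)),
    ImpactRow(("cm_Essential.Hypertension", "pl_Hypotension", "pl_Acute.respiratory.failure"), 0.6, 41.1, 5.35, 5.26, (3.03, 9.13)),
    # four-way combinations
    ImpactRow(("cm_Essential.Hypertension", "cm_Anemia", "cm_Acidosis", "pl_Acute.respiratory.failure"), 0.2, 52.0, 8.26, 8.76, (3.96, 19.40)),
    ImpactRow(("pl_Kidney.Failure.Acute", "cm_Anemia", "cm_Acidosis", "pl_Acute.respiratory.failure"), 0.3, 50.0, 7.63, 7.75, (3.65, 16.47)),
    ImpactRow(("pl_Kidney.Failure.Acute", "cm_Acidosis", "pl_Acute.respiratory.failure", "cm_Chronic.Kidney.Diseases"), 0.3, 48.3, 7.12, 7.53, (3.56, 15.91)),
    ImpactRow(("cm_Essential.Hypertension", "dx_Abnormal.EKG", "pl_Hypotension", "dx_ECG.abnormalities.non.specific"), 0.2, 46.2, 6.53, 7.02, (3.19, 15.48)),
    ImpactRow(("pl_Kidney.Failure.Acute", "cm_Congestive.heart.failure", "cm_Acidosis", "cm_Chronic.Kidney.Diseases"), 0.3, 46.4, 6.61, 6.49, (3.02, 13.95)),
    ImpactRow(("pl_Dyspnea", "pl_Kidney.Failure.Acute", "cm_Acidosis", "cm_Chronic.kidney.disease.stage.3.moderate"), 0.3, 46.4, 6.61, 5.43, (2.54, 11.61)),
    ImpactRow(("pl_Dyspnea", "pl_Kidney.Failure.Acute", "cm_Acidosis", "cm_Chronic.Kidney.Diseases"), 0.3, 39.3, 4.92, 5.28, (2.40, 11.61)),
    ImpactRow(("pl_Kidney.Failure.Acute", "cm_Acidosis", "pl_Atrial.Fibrillation", "pl_Acute.respiratory.failure"), 0.2, 40.0, 5.07, 5.20, (2.29, 11.80)),
    ImpactRow(("cm_Essential.Hypertension", "dx_Abnormal.EKG", "cm_Acidosis", "pl_Hypotension"), 0.3, 35.5, 5.21, 5.19, (2.51, 10.74)),
    ImpactRow(("cm_Essential.Hypertension", "dx_Encounter.due.to.tobacco", "pl_Atrial.Fibrillation", "pl_Acute.respiratory.failure"), 0.4, 39.3, 6.56, 4.92, (2.59, 9.38)),
)


@dataclass(frozen=True)
class PrevalenceRow:
    """One published high-prevalence combination: printed lift and confidence.

    ``identity_2dp`` marks whether the printed lift equals
    confidence / baseline mortality at two decimals; rows where the
    printed value sits on (or beyond) a rounding boundary of that
    identity are flagged False and excluded from identity checks.
    """

    antecedent: tuple[str, ...]
    printed_lift: float
    confidence_pct: float
    identity_2dp: bool


PREVALENCE_ROWS: tuple[PrevalenceRow, ...] = (
    PrevalenceRow(("pl_Atelectasis", "dx_Encounter.for.counseling"), 6.54, 76.7, False),
    PrevalenceRow(("cm_Essential.Hypertension", "ddx_DNR"), 6.33, 74.2, False),
    PrevalenceRow(("cm_Acidosis", "pdx_Cardiac.Arrest"), 6.20, 72.6, True),
    PrevalenceRow(("cm_Essential.Hypertension", "dx_Encounter.for.counseling"), 6.19, 68.0, False),
    PrevalenceRow(("pl_Hypotension", "pdx_Cardiac.Arrest"), 5.80, 65.9, False),
    PrevalenceRow(("pl_Acute.respiratory.failure", "pdx_Cerebral.Hemorrhage"), 4.70, 55.1, False),
    PrevalenceRow(("cm_Congestive.heart.failure", "hx_ARF.with.tubular.necrosis"), 4.27, 50.0, True),
    PrevalenceRow(("cm_Altered.mental.status", "hx_Atherosclerosis.without.angina"), 4.10, 48.0, True),
    PrevalenceRow(("ddx_Kidney.Failure.Acute", "ddx_Atrial.Fibrillation"), 4.10, 48.0, True),
    PrevalenceRow(("ddx_Coronary.atherosclerosis.of.native", "ddx_Acute.respiratory.failure"), 4.03, 47.2, True),
    PrevalenceRow(("cm_Essential.Hypertension", "cm_Anemia", "cm_Acidosis", "pl_Acute.respiratory.failure"), 4.44, 52.0, True),
)

#: The worked pruning example: the two-way rule's confidence against its
#: singleton sub-rules (all percentages as printed).
WORKED_EXAMPLE = {
    "rule": ("cm_Acidosis", "pdx_Cardiac.Arrest"),
    "rule_confidence_pct": 72.6,
    "sub_confidences_pct": {
        ("cm_Acidosis",): 25.0,
        ("pdx_Cardiac.Arrest",): 59.3,
    },
}
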