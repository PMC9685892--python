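"""Generator behaviour: calibration, determinism, marginals, round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ihtminer import calibrate_intercept, default_config, generate_cohort
from ihtminer.synthetic_cohort import (
    CatalogItem,
    ConfigurationError,
    SimulationConfig,
    base_logit_for_prevalence,
    build_default_mapping,
    cohort_to_records,
    marginal_prevalence,
    model_implied_carrier_mortality,
    roundtrip_indicators,
)

PLANTED_PAIR = ("cm_Acidosis", "pdx_Cardiac.Arrest")


def flat_config(**overrides) -> SimulationConfig:
    """Minimal config with no effects: death odds are the intercept alone."""
    defaults = dict(
        n_patients=100,
        seed=3,
        item_catalog=(CatalogItem("Essential.Hypertension", "cm", 0.0),),
        sex_probs={"Male": 0.5, "Female": 0.5},
        race_probs={"White": 1.0},
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestCalibration:
    def test_symmetric_target_gives_zero_intercept(self):
        b0 = calibrate_intercept(flat_config(target_mortality=0.5), n_probe=10_000)
        assert b0 == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_logit_with_no_effects(self):
        b0 = calibrate_intercept(flat_config(target_mortality=0.117), n_probe=10_000)
        assert b0 == pytest.approx(np.log(0.117 / 0.883), abs=1e-6)

    def test_default_conditions_hit_target_rate(self, study_scale_cohort):
        assert abs(study_scale_cohort.death_rate - 0.117) < 0.01

    def test_probe_floor_enforced(self):
        with pytest.raises(ConfigurationError):
            calibrate_intercept(flat_config(), n_probe=5_000)


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            flat_config(sex_probs={"Male": 0.6, "Female": 0.6})

    def test_duplicate_item_names_rejected(self):
        items = (
            CatalogItem("Acidosis", "cm", 0.0),
            CatalogItem("Acidosis", "cm", -1.0),
        )
        with pytest.raises(ConfigurationError, match="unique"):
            flat_config(item_catalog=items)

    def test_planted_interaction_size_bounds(self):
        with pytest.raises(ConfigurationError, match="2-4 items"):
            default_config(
                n_patients=10,
                seed=0,
                planted_interactions=[{"items": ["cm_Acidosis"], "gamma": 1.0}],
            )

    def test_interaction_must_reference_catalog(self):
        with pytest.raises(ConfigurationError, match="unknown items"):
            default_config(
                n_patients=10,
                seed=0,
                planted_interactions=[{"items": ["cm_Nope", "pdx_Cardiac.Arrest"], "gamma": 1.0}],
            )

    def test_prevalence_inversion_matches_forward_model(self):
        for p, loading in [(0.05, 0.8), (0.5, 0.3), (0.75, 0.0)]:
            b = base_logit_for_prevalence(p, loading)
            assert marginal_prevalence(b, loading) == pytest.approx(p, abs=1e-9)


class TestGeneration:
    def test_empty_cohort_is_valid(self):
        cohort = generate_cohort(flat_config(n_patients=0))
        assert cohort.n == 0
        assert list(cohort.items.columns) == ["cm_Essential.Hypertension"]

    def test_seed_determinism(self, small_config, small_cohort):
        again = generate_cohort(small_config)
        pd.testing.assert_frame_equal(small_cohort.demographics, again.demographics)
        pd.testing.assert_frame_equal(small_cohort.items, again.items)

    def test_different_seeds_differ(self, small_config, small_cohort):
        other = generate_cohort(default_config(n_patients=2500, seed=8))
        assert not small_cohort.demographics["died"].equals(other.demographics["died"])

    def test_ages_within_topcoded_range(self, small_cohort):
        ages = small_cohort.demographics["age"]
        assert ages.between(21, 90).all()

    def test_death_implies_died_disposition(self, small_cohort):
        demo = small_cohort.demographics
        assert (demo.loc[demo["died"] == 1, "disposition"] == "Died").all()
        assert (demo.loc[demo["died"] == 0, "disposition"] != "Died").all()

    def test_dead_patients_skew_older(self, study_scale_cohort):
        demo = study_scale_cohort.demographics
        mean_dead = demo.loc[demo["died"] == 1, "age"].mean()
        mean_alive = demo.loc[demo["died"] == 0, "age"].mean()
        assert mean_dead > mean_alive + 3  # positive per-decade effect

    def test_subcategory_mean_counts_near_published(self, study_scale_cohort):
        targets = {"pdx": 2.9, "pl": 5.1, "dx": 8.1, "cm": 6.2, "hx": 2.1, "ddx": 1.1}
        items = study_scale_cohort.items
        for sub, target in targets.items():
            cols = [c for c in items.columns if c.startswith(sub + "_")]
            mean_count = items[cols].sum(axis=1).mean()
            assert mean_count == pytest.approx(target, rel=0.25), sub

    def test_shared_burden_induces_cooccurrence(self, study_scale_matrix):
        # Items with positive loadings co-occur above independence.
        m = study_scale_matrix.items
        pairs = [
            ("cm_Acidosis", "pl_Kidney.Failure.Acute"),
            ("cm_Congestive.heart.failure", "pl_Acute.respiratory.failure"),
            ("cm_Chronic.Kidney.Diseases", "pl_Hypotension"),
        ]
        for a, b in pairs:
            pa, pb = m[a].mean(), m[b].mean()
            observed = (m[a] & m[b]).mean()
            assert observed / (pa * pb) > 1.1, (a, b)

    def test_planted_carrier_mortality_matches_model(self, study_scale_config, study_scale_cohort):
        implied, _ = model_implied_carrier_mortality(study_scale_config, PLANTED_PAIR)
        items = study_scale_cohort.items
        carrier = items[PLANTED_PAIR[0]].astype(bool) & items[PLANTED_PAIR[1]].astype(bool)
        n_carriers = int(carrier.sum())
        assert n_carriers >= 100
        observed = study_scale_cohort.demographics.loc[carrier.values, "died"].mean()
        mc_se = np.sqrt(implied * (1 - implied) / n_carriers)
        assert abs(observed - implied) < 3 * mc_se
        assert implied > 0.5  # a genuinely high-risk combination


class TestRoundTrip:
    def test_single_item_single_patient(self):
        cfg = flat_config(n_patients=1, item_catalog=(CatalogItem("Essential.Hypertension", "cm", 10.0),))
        cohort = generate_cohort(cfg)
        mapping = build_default_mapping(cfg.item_catalog)
        records, demo = cohort_to_records(cohort, mapping)
        assert len(records) == 1
        assert records.loc[0, "code_system"] == "icd10"
        matrix = roundtrip_indicators(cohort, mapping)
        assert matrix.items.loc[cohort.items.index[0], "cm_Essential.Hypertension"] == 1

    def test_full_cohort_roundtrip_exact(self, small_config, small_cohort):
        mapping = build_default_mapping(small_config.item_catalog)
        matrix = roundtrip_indicators(small_cohort, mapping)
        original = small_cohort.items.reindex(columns=sorted(small_cohort.items.columns))
        # Items never observed present are absent from the rebuilt matrix.
        present = [c for c in original.columns if original[c].sum() > 0]
        assert list(matrix.items.columns) == present
        np.testing.assert_array_equal(
            matrix.items.loc[original.index, present].to_numpy(),
            original[present].to_numpy(),
        )
        assert matrix.N == small_cohort.n
        assert matrix.D == int(small_cohort.demographics["died"].sum())

    def test_zero_item_patient_kept_in_demographics(self):
        cfg = flat_config(n_patients=50, item_catalog=(CatalogItem("Rare", "hx", -20.0),))
        cohort = generate_cohort(cfg)
        assert cohort.items.to_numpy().sum() == 0
        mapping = build_default_mapping(cfg.item_catalog)
        records, demo = cohort_to_records(cohort, mapping)
        assert len(records) == 0
        assert len(demo) == 50

    def test_unmapped_concept_aborts_with_report(self, small_cohort):
        import ihtminer.synthetic_cohort as sc

        incomplete = build_default_mapping(
            [CatalogItem("Essential.Hypertension", "cm", 0.0)]
        )
        with pytest.raises(sc.UnmappedConceptError) as err:
            cohort_to_records(small_cohort, incomplete)
        assert len(err.value.missing) == small_cohort.items.shape[1] - 1
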