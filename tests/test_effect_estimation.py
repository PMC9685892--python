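"""Odds-ratio estimation: 2x2 identities, IRLS correctness, adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ihtminer import (
    ContingencyTable,
    contingency_from_indicators,
    estimate_adjusted_or,
    estimate_or,
    fit_logistic,
    reconstruct_table,
)
from ihtminer.effect_estimation import EstimationError, adjusted_design

from conftest import random_matrix


class TestContingency:
    def test_balanced_cross_tabulation(self):
        m = random_matrix(4, 1, seed=1)
        m.items.iloc[:, 0] = np.array([1, 1, 0, 0], dtype=np.int8)
        m.died[:] = [1, 0, 1, 0]
        m.__post_init__()  # refresh cached D after direct mutation
        table = contingency_from_indicators(m, m.item_names)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)

    def test_margins_conserved_on_synthetic_matrix(self, small_cohort):
        m = small_cohort.to_indicator_matrix()
        table = contingency_from_indicators(m, ("cm_Acidosis",))
        assert table.N == m.N and table.D == m.D

    def test_universal_carrier_degenerate_margin(self):
        m = random_matrix(10, 1, seed=2)
        m.items.iloc[:, 0] = 1
        table = contingency_from_indicators(m, m.item_names)
        assert table.c == table.d == 0

    def test_unknown_item_raises(self):
        m = random_matrix(10, 2, seed=3)
        with pytest.raises(KeyError):
            contingency_from_indicators(m, ("dx_Missing",))


class TestReconstruction:
    def test_published_cardiac_arrest_row(self):
        t = reconstruct_table(8893, 1041, 1.6, 59.3)
        assert (t.a, t.b, t.c, t.d) == (84, 58, 957, 7794)

    def test_full_coverage_identity(self):
        t = reconstruct_table(100, 10, 100.0, 10.0)
        assert (t.a, t.b, t.c, t.d) == (10, 90, 0, 0)

    def test_published_two_way_row(self):
        t = reconstruct_table(8893, 1041, 0.5, 72.6)
        assert (t.a, t.b, t.c, t.d) == (32, 12, 1009, 7840)

    def test_margins_always_consistent(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            N = int(rng.integers(100, 10_000))
            D = int(rng.integers(1, N // 2))
            cov = float(rng.uniform(0.1, 100))
            conf = float(rng.uniform(0, 100))
            try:
                t = reconstruct_table(N, D, cov, conf)
            except EstimationError:
                continue  # infeasible print combination: correctly refused
            assert t.N == N and t.D == D

    def test_infeasible_cells_named(self):
        with pytest.raises(EstimationError, match="cell c"):
            reconstruct_table(100, 5, 50.0, 90.0)


class TestOddsRatio:
    def test_balanced_table_is_null(self):
        est = estimate_or(ContingencyTable(10, 10, 10, 10))
        assert est.value == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_reconstructed_cardiac_arrest_or(self):
        est = estimate_or(reconstruct_table(8893, 1041, 1.6, 59.3))
        assert est.value == pytest.approx(11.80, abs=0.01)

    def test_zero_cell_takes_haldane_correction(self):
        est = estimate_or(ContingencyTable(5, 0, 10, 100))
        assert est.corrected
        assert np.isfinite(est.value) and est.value > 1

    def test_empty_row_is_undefined(self):
        with pytest.raises(EstimationError, match="undefined"):
            estimate_or(ContingencyTable(0, 0, 10, 100))

    def test_row_swap_gives_reciprocal(self):
        t = ContingencyTable(84, 58, 957, 7794)
        assert estimate_or(t.swapped_rows()).value == pytest.approx(1 / estimate_or(t).value)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 0, 0, 0] * 25)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.params["intercept"] == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_single_binary_covariate_matches_crossproduct_or(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 500)
        y = (rng.random(500) < np.where(x == 1, 0.45, 0.2)).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        assert fit.params["x"] == pytest.approx(np.log((a * d) / (b * c)), abs=1e-6)

    def test_matches_statsmodels_on_mixed_design(self):
        rng = np.random.default_rng(12)
        n = 2000
        X = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.integers(0, 2, n).astype(float),
                "x3": rng.uniform(20, 90, n),
            }
        )
        eta = -1.0 + 0.8 * X["x1"] + 0.5 * X["x2"] + 0.02 * X["x3"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        mine = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(mine.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(mine.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-6)

    def test_parameter_recovery_coverage(self, recovery_simulation):
        for name, count in recovery_simulation.items():
            assert count >= 93, (name, count)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        X = pd.DataFrame({"x": x, "x_twice": 2 * x})
        y = (rng.random(200) < 0.3).astype(int)
        with pytest.raises(EstimationError, match="collinear"):
            fit_logistic(X, y)

    def test_separation_flagged(self):
        x = np.repeat([0.0, 1.0], 50)
        y = np.repeat([0, 1], 50)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation_flag

    def test_more_parameters_than_rows_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(EstimationError, match="observations"):
            fit_logistic(X, np.array([0, 1, 0]))


class TestAdjustedOR:
    def test_no_confounding_limit(self, no_confounding_matrix):
        est = estimate_adjusted_or(no_confounding_matrix, ("cm_Acidosis", "pdx_Cardiac.Arrest"))
        assert est.aor == pytest.approx(est.or_unadjusted.value, rel=0.05)

    def test_age_confounded_antecedent_shrinks_after_adjustment(self):
        # Item prevalence and mortality both rise with age: adjusting for
        # age must pull the combination's odds ratio toward the null.
        from ihtminer.synthetic_cohort import (
            CatalogItem,
            CovariateEffects,
            SimulationConfig,
            generate_cohort,
        )

        cfg = SimulationConfig(
            n_patients=30_000,
            seed=13,
            item_catalog=(
                CatalogItem("Frailty", "cm", -1.0, loading=0.3, age_loading=0.9),
                CatalogItem("Anemia", "cm", -0.5, loading=0.3),
            ),
            sex_probs={"Male": 0.5, "Female": 0.5},
            race_probs={"White": 1.0},
            outcome_main_effects={"cm_Frailty": 0.3},
            covariate_effects=CovariateEffects(age_per_decade=0.9),
        )
        m = generate_cohort(cfg).to_indicator_matrix()
        est = estimate_adjusted_or(m, ("cm_Frailty",))
        assert est.aor < est.or_unadjusted.value

    def test_covariate_design_reference_levels(self, small_cohort):
        m = small_cohort.to_indicator_matrix()
        X = adjusted_design(m, ("cm_Acidosis",))
        assert list(X.columns) == ["carrier", "age", "sex_Female", "race_Black", "race_Other"]

    def test_carrierless_antecedent_infeasible(self):
        m = random_matrix(50, 2, seed=6)
        m.items.iloc[:, 0] = 0
        with pytest.raises(EstimationError, match="no carriers"):
            estimate_adjusted_or(m, (m.item_names[0],))

    def test_matches_statsmodels_adjusted_fit(self, small_cohort):
        m = small_cohort.to_indicator_matrix()
        est = estimate_adjusted_or(m, ("pl_Acute.respiratory.failure",))
        X = sm.add_constant(adjusted_design(m, ("pl_Acute.respiratory.failure",)))
        ref = sm.Logit(np.asarray(m.died, dtype=float), X).fit(disp=0)
        assert est.aor == pytest.approx(float(np.exp(ref.params["carrier"])), rel=1e-6)
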