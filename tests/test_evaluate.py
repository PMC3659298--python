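"""Cross-validation orchestration, R2, bootstrap CIs, age windows."""

import numpy as np
import pandas as pd
import pytest

from lipidprs import (
    CVResult,
    LongCohort,
    PhenotypeTable,
    SimulationConfig,
    ValidationError,
    age_window_analysis,
    bootstrap_ci_r2,
    generate_cohort,
    impute_missing_dosages,
    loso_cv,
    ncbi_score,
    r2,
    score_significance,
    select_window_observations,
)
from lipidprs.evaluate import nongenetic_builder
from lipidprs.scores import cohort_arrays


class TestR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2(y, y) == pytest.approx(1.0)

    def test_affine_invariance(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2(y, 3.0 + 2.0 * y) == pytest.approx(1.0)

    def test_hand_computed_four_point_example(self):
        # r = 2.25 / sqrt(5 * 2.1875) by the textbook formula
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([2.0, 2.5, 4.0, 3.0])
        assert r2(obs, pred) == pytest.approx(0.46285714285714286)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            r2(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            r2(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _fake_result(rng, n_subjects, noise=1.0):
    truth = rng.normal(size=n_subjects)
    recs = []
    for i, t in enumerate(truth):
        for _ in range(3):
            recs.append((f"s{i}", 10.0, t + rng.normal(0, noise), t))
    return CVResult(
        records=pd.DataFrame(
            recs, columns=["subject_id", "age", "observed", "predicted"]
        ),
        model_label="x", r2=0.0, r2_ci=None, delta_r2_vs_baseline=None,
        p_value=None, n_subjects=n_subjects, n_observations=3 * n_subjects,
    )


class TestBootstrapCI:
    def test_perfect_predictions_give_degenerate_interval(self):
        rng = np.random.default_rng(0)
        res = _fake_result(rng, 30, noise=0.0)
        lo, hi = bootstrap_ci_r2(res, n_boot=200, seed=1)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        res = _fake_result(rng, 60)
        point = r2(res.records["observed"], res.records["predicted"])
        lo, hi = bootstrap_ci_r2(res, n_boot=400, seed=2)
        assert lo <= point <= hi

    def test_wider_interval_at_smaller_sample(self):
        rng = np.random.default_rng(2)
        small = bootstrap_ci_r2(_fake_result(rng, 40), n_boot=400, seed=3)
        large = bootstrap_ci_r2(_fake_result(rng, 400), n_boot=400, seed=3)
        assert small[1] - small[0] > large[1] - large[0]

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        res = _fake_result(rng, 40)
        assert bootstrap_ci_r2(res, 300, seed=4) == bootstrap_ci_r2(res, 300, seed=4)

    def test_too_few_resamples_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            bootstrap_ci_r2(_fake_result(rng, 10), n_boot=50, seed=0)


class TestLosoCV:
    def test_oracle_predictor_approaches_theoretical_ceiling(self):
        cfg = SimulationConfig(
            n_subjects=200, n_causal=10, n_null=0, seed=41, missing_rate=0.0
        )
        cohort, truth = generate_cohort(cfg)
        arr = cohort_arrays(cohort, "LDL")

        def oracle_builder(cohort, trait):
            sidx = {s: i for i, s in enumerate(arr.subject_ids)}

            def fold_fn(fold):
                test = fold.test_mask
                rows = fold.arr.subj_of_obs[test]
                return (
                    cfg.mu
                    + cfg.age_effect * np.sin(
                        0.5 * np.pi * (2 * fold.arr.age[test] - 52.0) / 44.0
                    )
                    + cfg.sex_effect * fold.arr.sex[test]
                    + cfg.bmi_effect * fold.arr.bmi[test]
                    + truth.genetic_values[rows]
                )

            return fold_fn

        res = loso_cv(cohort, oracle_builder, "LDL")
        # ceiling: var(predictable signal) / var(total)
        signal = (
            cfg.age_effect * np.sin(0.5 * np.pi * (2 * arr.age - 52.0) / 44.0)
            + cfg.sex_effect * arr.sex
            + cfg.bmi_effect * arr.bmi
            + truth.genetic_values[arr.subj_of_obs]
        )
        ceiling = np.var(signal) / np.var(arr.y)
        # sampling error of a squared correlation with 200 independent
        # subjects is ~0.05; allow two of those
        assert res.r2 == pytest.approx(ceiling, abs=0.1)

    def test_constant_predictor_reported_degenerate(self, small_cohort):
        cohort, _ = small_cohort

        def constant_builder(cohort, trait):
            return lambda fold: np.zeros(int(fold.test_mask.sum()))

        with pytest.raises((RuntimeError, ValidationError)):
            loso_cv(cohort, constant_builder, "LDL")

    def test_heldout_mutation_does_not_change_own_predictions(self, small_cohort):
        cohort, _ = small_cohort
        base = loso_cv(cohort, nongenetic_builder, "LDL")
        sid = base.records["subject_id"].iloc[0]
        df = cohort.phenotypes.df.copy()
        df.loc[df.subject_id == sid, "ldl"] += 300.0
        mutated = LongCohort(
            PhenotypeTable(df), cohort.genotypes, list(cohort.catalog)
        )
        after = loso_cv(mutated, nongenetic_builder, "LDL")
        mask = base.records["subject_id"] == sid
        assert np.array_equal(
            base.records.loc[mask, "predicted"].to_numpy(),
            after.records.loc[mask, "predicted"].to_numpy(),
        )


class TestScoreSignificance:
    def test_true_genetic_scores_strongly_associated(self, clean_cohort):
        cohort, truth = clean_cohort
        sv = ncbi_score(cohort.genotypes, cohort.catalog, "LDL")
        assert score_significance(cohort, sv, "LDL") < 1e-6

    def test_constant_scores_rejected(self, clean_cohort):
        cohort, _ = clean_cohort
        sv = ncbi_score(cohort.genotypes, cohort.catalog, "LDL")
        sv.scores = np.zeros_like(sv.scores)
        with pytest.raises(ValidationError):
            score_significance(cohort, sv, "LDL")


class TestAgeWindow:
    def _toy_cohort(self, ages_by_subject):
        rows = []
        rng = np.random.default_rng(0)
        for i, ages in enumerate(ages_by_subject):
            for a in ages:
                rows.append(
                    (f"s{i}", a, i % 2, 20.0, np.nan, rng.normal(100, 10),
                     np.nan, np.nan)
                )
        pheno = PhenotypeTable(pd.DataFrame(
            rows,
            columns=["subject_id", "age", "sex", "bmi", "hdl", "ldl", "tc", "tg"],
        ))
        from lipidprs import GenotypeMatrix, MarkerCatalogEntry

        n = len(ages_by_subject)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(n)], ["rs0"],
            rng.integers(0, 3, size=(n, 1)).astype(float),
        )
        cat = [MarkerCatalogEntry("rs0", "A", "G", 1.0, "LDL", 10)]
        return LongCohort(pheno, g, cat)

    def test_nearest_observation_within_window_selected(self):
        cohort = self._toy_cohort([[8.1, 9.9, 12.4]] + [[9.0]] * 35)
        sel = select_window_observations(cohort, "LDL", 10.0)
        assert sel.loc[sel.subject_id == "s0", "age"].iloc[0] == 9.9

    def test_subject_with_no_observation_in_window_excluded(self):
        cohort = self._toy_cohort([[5.0, 14.0]] + [[9.0]] * 35)
        sel = select_window_observations(cohort, "LDL", 10.0)
        assert "s0" not in set(sel.subject_id)

    def test_previous_measurement_taken_from_any_earlier_age(self):
        cohort = self._toy_cohort([[4.0, 9.9]] + [[5.0, 9.0]] * 35)
        sel = select_window_observations(cohort, "LDL", 10.0, use_previous=True)
        row = sel[sel.subject_id == "s0"].iloc[0]
        arr = cohort_arrays(cohort, "LDL")
        first = arr.y[(arr.subj_of_obs == 0) & (arr.age == 4.0)][0]
        assert row["previous"] == first

    def test_subject_without_previous_dropped(self):
        cohort = self._toy_cohort([[9.9]] + [[5.0, 9.0]] * 35)
        sel = select_window_observations(cohort, "LDL", 10.0, use_previous=True)
        assert "s0" not in set(sel.subject_id)

    def test_underpowered_window_rejected(self):
        cohort = self._toy_cohort([[9.0, 12.0]] * 20)
        g = impute_missing_dosages(cohort.genotypes, cohort.genotypes.subject_ids)
        sv = ncbi_score(g, cohort.catalog, "LDL")
        with pytest.raises(ValidationError, match="underpowered"):
            age_window_analysis(cohort, sv, 40.0, False, "LDL")
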