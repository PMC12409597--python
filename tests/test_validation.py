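"""Fold construction, nested grid search, and the outer validation loop."""

import numpy as np
import pandas as pd
import pytest

from connpred import (
    HyperGrid,
    SyntheticSpec,
    generate_cohort,
    inner_grid_search,
    make_folds,
    outcome_variant,
    run_validation,
)
from connpred.rcca import Standardizer, fit_rcca, fit_standardize_pca
from connpred.validation import select_best_cell
from sklearn.model_selection import KFold
from tests.conftest import SMALL_SIZES


class TestMakeFolds:
    def test_kfold_partitions_evenly(self, planted_small):
        cohort, _ = planted_small
        sub = cohort.subset_rows(cohort.participant_ids[:20])
        plan = make_folds(sub, "kfold", K=10, seed=0)
        sizes = plan.assignments.value_counts()
        assert len(sizes) == 10 and set(sizes) == {2}
        assert sorted(plan.assignments.index) == sorted(sub.participant_ids)

    def test_group_scheme_folds_are_the_label_partition(self, planted_small):
        cohort, _ = planted_small
        plan = make_folds(cohort, "cross_treatment", seed=0)
        assert set(plan.fold_labels()) == set(cohort.treatment.unique())
        for arm in plan.fold_labels():
            assert set(plan.test_ids(arm)) == set(
                cohort.participant_ids[cohort.treatment == arm]
            )

    def test_seed_determinism(self, planted_small):
        cohort, _ = planted_small
        a = make_folds(cohort, "kfold", K=5, seed=3).assignments
        b = make_folds(cohort, "kfold", K=5, seed=3).assignments
        c = make_folds(cohort, "kfold", K=5, seed=4).assignments
        assert a.equals(b)
        assert not a.equals(c)

    def test_small_group_error_names_the_group(self, planted_small):
        cohort, _ = planted_small
        diag = cohort.diagnosis.copy()
        diag.iloc[:] = "MDD"
        diag.iloc[:2] = "PDD"
        bad = cohort.__class__(**{**cohort.__dict__, "diagnosis": diag})
        with pytest.raises(ValueError, match="PDD"):
            make_folds(bad, "cross_diagnosis")

    @pytest.mark.parametrize("K, match", [(1, "2 <= K"), (200, "2 <= K")])
    def test_kfold_bounds(self, planted_small, K, match):
        cohort, _ = planted_small
        with pytest.raises(ValueError, match=match):
            make_folds(cohort, "kfold", K=K)

    def test_too_many_folds_for_two_member_minimum(self, planted_small):
        cohort, _ = planted_small
        with pytest.raises(ValueError, match=">= 2 members"):
            make_folds(cohort.subset_rows(cohort.participant_ids[:19]), "kfold", K=10)


class TestCellSelection:
    def test_ties_prefer_larger_c_then_smaller_k(self):
        cells = [(0.2, 10), (0.2, 20), (0.8, 10), (0.8, 20)]
        assert select_best_cell(cells, [0.5, 0.5, 0.5, 0.5]) == 2  # larger c wins
        assert select_best_cell(cells, [0.5, 0.5, 0.4, 0.5]) == 3  # then smaller k among c=0.8? no: 0.5 ties -> larger c
        assert select_best_cell([(0.8, 20), (0.8, 10)], [0.5, 0.5]) == 1  # smaller k
        assert select_best_cell(cells, [-np.inf, 0.1, np.nan, 0.3]) == 3

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            select_best_cell([(0.5, 5)], [np.nan])


class TestInnerGridSearch:
    def test_single_cell_grid_short_circuits(self, planted_small):
        cohort, _ = planted_small
        res = inner_grid_search(
            cohort.edge_values(), cohort.metric_values(), HyperGrid.single(0.3, 7), seed=0
        )
        assert (res.c, res.k) == (0.3, 7)

    def test_fast_path_matches_generic_per_cell_fit(self, planted_small):
        """The shared-PCA grid evaluation must agree with naively refitting
        each cell through the public solver, fold by fold."""
        cohort, _ = planted_small
        edges = cohort.edge_values()[:60]
        metrics = cohort.metric_values()[:60]
        grid = HyperGrid(reg_values=(0.2, 0.8), k_values=(4, 9))
        res = inner_grid_search(edges, metrics, grid, seed=5)

        for c, k in [(0.2, 4), (0.8, 9)]:
            pooled_u = np.full(len(edges), np.nan)
            pooled_v = np.full(len(edges), np.nan)
            kf = KFold(5, shuffle=True, random_state=5)
            for tr, te in kf.split(np.arange(len(edges))):
                estd, basis, scores = fit_standardize_pca(edges[tr], k)
                mstd = Standardizer.fit(metrics[tr])
                sol = fit_rcca(scores, mstd.transform(metrics[tr]), c)
                w_x, w_y = sol["w_x"], sol["w_y"]
                v_tr = mstd.transform(metrics[tr]) @ w_y
                anchor = mstd.transform(metrics[tr]).mean(axis=1)
                if np.corrcoef(v_tr, anchor)[0, 1] < 0:
                    w_x, w_y = -w_x, -w_y
                pooled_u[te] = basis.project(estd.transform(edges[te]), k) @ w_x
                pooled_v[te] = mstd.transform(metrics[te]) @ w_y
            expected = np.corrcoef(pooled_u, pooled_v)[0, 1]
            got = res.table.set_index(["c", "k"]).loc[(c, k), "criterion"]
            assert got == pytest.approx(expected, abs=1e-8)

    def test_noise_free_cohort_reaches_near_perfect_criterion(self, noisefree_small):
        cohort, _ = noisefree_small
        grid = HyperGrid(reg_values=(0.1, 0.5, 1.0), k_values=(2, 5))
        res = inner_grid_search(cohort.edge_values(), cohort.metric_values(), grid, seed=1)
        assert res.criterion >= 0.99

    def test_requires_minimum_training_rows(self, planted_small):
        cohort, _ = planted_small
        with pytest.raises(ValueError, match=">= 15"):
            inner_grid_search(
                cohort.edge_values()[:10], cohort.metric_values()[:10],
                HyperGrid.single(0.5, 2), seed=0,
            )


class TestRunValidation:
    def test_noise_free_prediction_is_near_perfect(self, noisefree_small):
        cohort, _ = noisefree_small
        grid = HyperGrid(reg_values=(0.5,), k_values=(2, 5))
        res = run_validation(cohort, "kfold", grid=grid, K=5, seed=2)
        assert res.prediction_r >= 0.99

    def test_pooled_scores_cover_every_participant_once(self, planted_small, reduced_grid):
        cohort, _ = planted_small
        for scheme in ("kfold", "cross_diagnosis", "cross_treatment"):
            res = run_validation(cohort, scheme, grid=reduced_grid, K=5, seed=1)
            assert res.pooled.index.equals(cohort.participant_ids)
            assert res.pooled[["u", "v"]].notna().all().all()

    def test_rerun_is_bit_identical(self, planted_small, reduced_grid):
        cohort, _ = planted_small
        a = run_validation(cohort, "kfold", grid=reduced_grid, K=5, seed=9)
        b = run_validation(cohort, "kfold", grid=reduced_grid, K=5, seed=9)
        assert a.prediction_r == b.prediction_r
        pd.testing.assert_frame_equal(a.pooled, b.pooled)
        assert a.to_json_dict() == b.to_json_dict()

    def test_perturbing_test_rows_never_changes_that_folds_fit(
        self, planted_small, reduced_grid
    ):
        cohort, _ = planted_small
        res = run_validation(cohort, "kfold", grid=reduced_grid, K=5, seed=3)
        fold0 = res.per_fold[0]
        # scramble ONLY fold 0's held-out rows
        rng = np.random.default_rng(0)
        edges = cohort.edges.copy()
        edges.loc[fold0["test_ids"]] = rng.standard_normal(
            (len(fold0["test_ids"]), cohort.n_edges)
        )
        res2 = run_validation(cohort.with_edges(edges), "kfold", grid=reduced_grid, K=5, seed=3)
        fold0b = res2.per_fold[0]
        assert fold0b["train_checksum"] == fold0["train_checksum"]
        assert fold0b["train_r"] == fold0["train_r"]
        assert (fold0b["c"], fold0b["k"]) == (fold0["c"], fold0["k"])

    def test_cross_treatment_reports_per_arm_correlations(self, planted_small, reduced_grid):
        cohort, _ = planted_small
        res = run_validation(cohort, "cross_treatment", grid=reduced_grid, seed=0)
        per_arm = res.per_fold_r()
        assert set(per_arm) == set(cohort.treatment.unique())
        assert all(np.isfinite(r) for r in per_arm.values())

    def test_null_cohort_prediction_centers_on_zero(self, reduced_grid):
        rs = []
        for s in range(50):
            spec = SyntheticSpec.from_target_rho(
                0.0, n_participants=60, network_sizes=SMALL_SIZES, seed=4000 + s
            )
            cohort, _ = generate_cohort(spec)
            rs.append(run_validation(cohort, "kfold", grid=reduced_grid, K=5, seed=s).prediction_r)
        assert abs(np.mean(rs)) < 0.05

    def test_prediction_tracks_planted_correlation(self, reduced_grid):
        from scipy import stats

        pairs = []
        for rho in (0.0, 0.25, 0.5, 0.75):
            for s in range(8):
                spec = SyntheticSpec.from_target_rho(
                    rho, n_participants=120, network_sizes=SMALL_SIZES, seed=3000 + s
                )
                cohort, _ = generate_cohort(spec)
                r = run_validation(cohort, "kfold", grid=reduced_grid, K=10, seed=s).prediction_r
                pairs.append((rho, r))
        arr = np.array(pairs)
        assert stats.spearmanr(arr[:, 0], arr[:, 1]).statistic > 0
        means = [arr[arr[:, 0] == rho, 1].mean() for rho in (0.0, 0.25, 0.5, 0.75)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_missing_metrics_are_refused(self, planted_small, reduced_grid):
        cohort, _ = planted_small
        metrics = cohort.metrics.copy()
        metrics.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="completers"):
            run_validation(cohort.with_metrics(metrics), "kfold", grid=reduced_grid)


class TestOutcomeVariant:
    def test_difference_and_percent_change_arithmetic(self, planted_small):
        cohort, _ = planted_small
        pre = cohort.metrics_pre.copy()
        post = cohort.metrics_post.copy()
        pre.iloc[0, 0], post.iloc[0, 0] = 20.0, 10.0
        mod = cohort.__class__(**{**cohort.__dict__, "metrics_pre": pre, "metrics_post": post})
        diff = outcome_variant(mod, "difference")
        pct = outcome_variant(mod, "percent_change")
        assert diff.metrics.iloc[0, 0] == -10.0
        assert pct.metrics.iloc[0, 0] == -50.0

    def test_no_change_gives_zero_under_both_variants(self, planted_small):
        cohort, _ = planted_small
        same = cohort.__class__(
            **{**cohort.__dict__, "metrics_post": cohort.metrics_pre.copy()}
        )
        assert (outcome_variant(same, "difference").metrics == 0).all().all()
        assert (outcome_variant(same, "percent_change").metrics == 0).all().all()

    def test_zero_pre_score_lists_offending_rows(self, planted_small):
        cohort, _ = planted_small
        pre = cohort.metrics_pre.copy()
        pre.iloc[2, 3] = 0.0
        mod = cohort.__class__(**{**cohort.__dict__, "metrics_pre": pre})
        with pytest.raises(ValueError, match=str(cohort.participant_ids[2])):
            outcome_variant(mod, "percent_change")

    def test_percent_change_matches_difference_when_baselines_constant(
        self, planted_small, reduced_grid
    ):
        cohort, _ = planted_small  # generator default: constant per-metric baselines
        r_diff = run_validation(
            outcome_variant(cohort, "difference"), "kfold", grid=reduced_grid, K=5, seed=1
        ).prediction_r
        r_pct = run_validation(
            outcome_variant(cohort, "percent_change"), "kfold", grid=reduced_grid, K=5, seed=1
        ).prediction_r
        assert abs(r_diff - r_pct) < 0.1
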