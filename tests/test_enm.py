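import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pondscape import (
    GridRaster,
    ModelRun,
    OccurrenceSet,
    auc_roc,
    build_ensemble,
    compute_weights,
    count_model_runs,
    fit_single_model,
    permutation_importance,
    response_curve,
    sample_pseudo_absences,
    select_variables,
    split_train_eval,
    thin_occurrences,
    tss,
)
from pondscape.enm import EmptyEnsembleError, enumerate_run_specs


class TestThinning:
    def test_points_within_radius_collapse(self):
        occ = OccurrenceSet("sp", [[0, 0], [0, 30]])
        assert len(thin_occurrences(occ, 50.0)) == 1

    def test_points_outside_radius_survive(self):
        occ = OccurrenceSet("sp", [[0, 0], [0, 60]])
        assert len(thin_occurrences(occ, 50.0)) == 2

    def test_greedy_pass_on_collinear_points(self):
        # 5 points spaced 40 m: the greedy pass keeps points 1, 3, 5
        occ = OccurrenceSet("sp", [[40 * i, 0] for i in range(5)])
        out = thin_occurrences(occ, 50.0)
        np.testing.assert_array_equal(out.points[:, 0], [0, 80, 160])


class TestPseudoAbsences:
    frame = GridRaster(np.zeros((40, 40)), origin=(0, 2000), cell_size=50.0)

    def test_disk_method_respects_the_exclusion_radius(self):
        occ = OccurrenceSet("sp", [[1000.0, 1000.0], [500.0, 1500.0]])
        (pa,) = sample_pseudo_absences(
            self.frame, occ, 200, method="disk", min_dist=50.0, seed=0
        )
        d = np.min(
            np.hypot(
                pa[:, None, 0] - occ.points[None, :, 0],
                pa[:, None, 1] - occ.points[None, :, 1],
            ),
            axis=1,
        )
        assert d.min() > 50.0

    def test_requested_number_of_sets_and_points(self):
        occ = OccurrenceSet("sp", np.empty((0, 2)))
        sets = sample_pseudo_absences(self.frame, occ, 100, n_sets=10, seed=1)
        assert len(sets) == 10
        assert all(s.shape == (100, 2) for s in sets)
        # independent draws: at least two sets differ
        assert any(not np.array_equal(sets[0], s) for s in sets[1:])

    def test_infeasible_request_rejected(self):
        occ = OccurrenceSet("sp", np.empty((0, 2)))
        with pytest.raises(ValueError):
            sample_pseudo_absences(self.frame, occ, 40 * 40 + 1, seed=0)


class TestWeightsAndSplit:
    def test_equal_class_totals(self):
        assert compute_weights(100, 100) == (1.0, 1.0)
        w_p, w_pa = compute_weights(183, 1000)
        assert w_pa == pytest.approx(0.183)
        assert 183 * w_p == pytest.approx(1000 * w_pa)
        with pytest.raises(ValueError):
            compute_weights(0, 10)

    def test_split_sizes_determinism_and_stratification(self):
        labels = np.r_[np.ones(10), np.zeros(30)]
        tr, ev = split_train_eval(labels, 0.7, seed=5)
        assert labels[tr].sum() == 7 and (labels[tr] == 0).sum() == 21
        tr2, _ = split_train_eval(labels, 0.7, seed=5)
        np.testing.assert_array_equal(tr, tr2)
        # proportions in train within one point of overall
        assert abs(labels[tr].mean() - labels.mean()) * len(tr) <= 1.0
        with pytest.raises(ValueError):
            split_train_eval(np.r_[np.ones(1), np.zeros(5)])


class TestAuc:
    def test_hand_example_and_extremes(self):
        assert auc_roc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)
        assert auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert auc_roc(scores, labels) == pytest.approx(0.5, abs=0.03)
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("n", [10, 25, 50])
    def test_matches_pairwise_concordance_oracle(self, n):
        rng = np.random.default_rng(n)
        scores = rng.integers(0, 8, size=n) / 8.0  # ties on purpose
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auc_roc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))


class TestTss:
    def test_perfect_constant_and_hand_values(self):
        val, _ = tss([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert val == 1.0
        val, _ = tss([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert val == 0.0
        # sensitivity 0.9 and specificity 0.8 at the optimum -> 0.7
        scores = np.r_[np.linspace(0.6, 1.0, 9), [0.1], np.linspace(0.0, 0.4, 8), [0.7, 0.8]]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        val, thr = tss(scores, labels)
        assert val == pytest.approx(0.9 + 0.8 - 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        base, _ = tss(scores, labels)
        trans, _ = tss(np.exp(2.0 * scores) + 1.0, labels)
        assert trans == pytest.approx(base)


class TestLearners:
    def test_tree_ensemble_separates_separable_data(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(3, 0.3, (40, 2)), rng.normal(-3, 0.3, (40, 2))]
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        run = fit_single_model("rf", X, y, np.ones(80), seed=0)
        assert auc_roc(run.predict(X), y) == 1.0

    def test_duplicating_points_equals_doubling_weights_for_logistic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + rng.normal(scale=0.7, size=60) > 0).astype(int)
        w = np.ones(60)
        base = fit_single_model("logistic", X, y, w)
        dup = fit_single_model("logistic", np.vstack([X, X]), np.r_[y, y], np.r_[w, w])
        grid = rng.normal(size=(20, 2))
        np.testing.assert_allclose(base.predict(grid), dup.predict(grid), atol=1e-5)

    def test_constant_covariate_predicts_weighted_prevalence(self):
        X = np.ones((50, 1))
        y = np.r_[np.ones(10), np.zeros(40)].astype(int)
        w = np.r_[np.full(10, 1.0), np.full(40, 0.25)]  # equal class totals
        run = fit_single_model("logistic", X, y, w)
        assert run.predict(X)[0] == pytest.approx(0.5, abs=1e-6)

    def test_unknown_learner_and_degenerate_labels_rejected(self):
        X = np.zeros((4, 1))
        with pytest.raises(KeyError):
            fit_single_model("nope", X, [0, 1, 0, 1], np.ones(4))
        with pytest.raises(ValueError):
            fit_single_model("logistic", X, [1, 1, 1, 1], np.ones(4))


class TestImportanceAndSelection:
    def _fit_on_one_signal(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0).astype(int)
        return fit_single_model("logistic", X, y, np.ones(300)), X

    def test_irrelevant_variable_scores_near_zero(self):
        run, X = self._fit_on_one_signal()
        assert permutation_importance(run, X, 1, n_perm=5, seed=0) < 0.05
        assert permutation_importance(run, X, 0, n_perm=5, seed=0) > 0.5

    def test_importance_unaffected_by_duplicated_unrelated_variables(self):
        run, X = self._fit_on_one_signal()
        base = permutation_importance(run, X, 0, n_perm=5, seed=1)
        X_dup = np.column_stack([X, X[:, 1]])
        run2 = fit_single_model(
            "logistic", X_dup, (X[:, 0] > 0).astype(int), np.ones(300)
        )
        again = permutation_importance(run2, X_dup, 0, n_perm=5, seed=1)
        assert again == pytest.approx(base, abs=0.1)

    def test_select_keeps_uncorrelated_and_drops_duplicates(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=400)
        c = rng.normal(size=400)
        df = pd.DataFrame({"a": a, "b": a + 1e-9 * rng.normal(size=400), "c": c})
        # pairwise |r| < 0.7 -> all retained
        low = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("xyz"))
        assert select_variables(low, {"x": 1, "y": 1, "z": 1}) == ["x", "y", "z"]
        # duplicated variable: the more important copy wins
        kept = select_variables(df, {"a": 0.1, "b": 0.9, "c": 0.5})
        assert kept == ["b", "c"]


class _ConstantPredictor:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def _stub_run(p, tss_val):
    return ModelRun("stub", 0, 0, _ConstantPredictor(p), ("v",), tss=tss_val)


class TestEnsemble:
    frame = GridRaster(np.zeros((3, 3)), origin=(0, 3), cell_size=1.0)
    covs = {"v": frame}

    def test_single_passing_member_is_the_ensemble(self):
        runs = [_stub_run(0.3, 0.9), _stub_run(0.9, 0.1)]
        ens = build_ensemble(runs, self.covs, tss_cutoff=0.7)
        np.testing.assert_allclose(ens.mean_surface.values, 0.3)
        np.testing.assert_allclose(ens.cv_surface.values, 0.0)

    def test_members_point_two_and_point_six_give_mean_point_four_cv_point_five(self):
        runs = [_stub_run(0.2, 0.9), _stub_run(0.6, 0.9)]
        ens = build_ensemble(runs, self.covs, tss_cutoff=0.7)
        np.testing.assert_allclose(ens.mean_surface.values, 0.4)
        np.testing.assert_allclose(ens.cv_surface.values, 0.5)  # population sd 0.2 / 0.4

    def test_no_passing_run_raises(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble([_stub_run(0.5, 0.2)], self.covs, tss_cutoff=0.7)

    def test_run_enumeration_matches_the_design_sizes(self):
        assert count_model_runs(8, 5, 5) == 200
        assert count_model_runs(8, 10, 5) == 400
        assert count_model_runs(1, 1, 1) == 1
        specs = enumerate_run_specs([f"alg{i}" for i in range(8)], 5, 5)
        assert len(specs) == 200
        assert len(set(specs)) == 200


class TestResponseCurves:
    def test_flat_for_independent_variable_and_bounded(self, climate_ensemble):
        df = climate_ensemble.response_curve("clim_0", n_points=12)
        assert df.shape == (12, 2)
        assert df["mean_prediction"].between(0, 1).all()

    def test_monotone_learner_gives_monotone_curve(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=400) > 0).astype(int)
        run = fit_single_model("logistic", X, y, np.ones(400), var_names=("a", "b"))
        run.tss = 0.9
        frame = GridRaster(np.zeros((2, 2)))
        ens = build_ensemble([run], {"a": frame, "b": frame}, tss_cutoff=0.7)
        df = response_curve(ens, pd.DataFrame(X, columns=["a", "b"]), "a", n_points=15)
        assert np.all(np.diff(df["mean_prediction"]) >= -1e-12)
        with pytest.raises(KeyError):
            response_curve(ens, pd.DataFrame(X, columns=["a", "b"]), "zz")


class TestFittedEnsembleQuality:
    def test_all_metrics_finite_and_summary_renders(self, climate_ensemble):
        m = climate_ensemble.metrics
        assert len(m) == 2 * 2 * 2
        assert np.isfinite(m["tss"]).all() and np.isfinite(m["auc"]).all()
        text = climate_ensemble.summary()
        assert "runs in ensemble" in text and "logistic" in text

    def test_response_curve_figure_has_one_panel_per_variable(self, climate_ensemble):
        import matplotlib

        matplotlib.use("Agg")
        fig = climate_ensemble.plot_response_curves(n_points=5)
        assert len(fig.axes) == 3

    def test_mean_surface_is_a_probability_field(self, climate_ensemble):
        vals = climate_ensemble.mean_surface.values
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
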