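"""SDM components: cleaning, sampling, Gibbs fit, metrics, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, spearmanr
from shapely.geometry import box

from solarconflict import (
    FeatureBuilder,
    GridSpec,
    PointSet,
    PolygonSet,
    Raster,
    auc,
    best_threshold,
    binarize_and_clip,
    build_features,
    clean_occurrences,
    evaluate,
    fit_maxent,
    permutation_importance_tables,
    predict,
    sample_background,
    score_at_points,
    select_variables,
    split_train_test,
)


class TestCleanOccurrences:
    def test_exact_duplicates_collapse(self, spec6):
        occ = clean_occurrences(PointSet([[1.1, 1.1], [1.1, 1.1]]), spec6, seed=0)
        assert len(occ) == 1

    def test_one_point_per_cell(self, spec6):
        pts = [[0.2, 0.3], [0.4, 0.6], [0.7, 0.1], [0.5, 0.5], [0.9, 0.9], [3.5, 3.5]]
        occ = clean_occurrences(PointSet(pts), spec6, seed=0)
        assert len(occ) == 2

    def test_drops_out_of_extent_and_region(self, spec6):
        region = PolygonSet([box(0, 0, 3, 6)])
        pts = [[1.0, 1.0], [5.0, 5.0], [90.0, 1.0]]
        occ = clean_occurrences(PointSet(pts), spec6, valid_region=region, seed=0)
        assert len(occ) == 1 and occ.points.coords[0, 0] == 1.0

    def test_seed_determinism_and_cell_stability(self, spec6):
        rng = np.random.default_rng(9)
        pts = PointSet(rng.uniform(0, 6, (40, 2)))
        a = clean_occurrences(pts, spec6, seed=1)
        b = clean_occurrences(pts, spec6, seed=1)
        c = clean_occurrences(pts, spec6, seed=2)
        np.testing.assert_array_equal(a.points.coords, b.points.coords)
        cells = lambda o: set(zip(*spec6.point_to_cell(o.points.x, o.points.y)))
        assert cells(a) == cells(c)  # only the within-cell pick may differ

    def test_nothing_survives_errors(self, spec6):
        with pytest.raises(ValueError):
            clean_occurrences(PointSet([[99.0, 99.0]]), spec6, seed=0)


class TestSampleBackground:
    def test_single_cell_grid_repeats_center(self):
        spec = GridSpec(1, 1, 2.0, origin_y=2.0)
        pts = sample_background(spec, 3, seed=0)
        np.testing.assert_array_equal(pts.coords, [[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])

    def test_cell_frequencies_uniform(self):
        spec = GridSpec(10, 10, 1.0, origin_y=10.0)
        pts = sample_background(spec, 50_000, seed=3)
        row, col = spec.point_to_cell(pts.x, pts.y)
        counts = np.bincount(row * 10 + col, minlength=100)
        assert chisquare(counts).pvalue > 0.001

    def test_region_restriction(self):
        spec = GridSpec(4, 4, 1.0, origin_y=4.0)
        region = PolygonSet([box(0, 0, 2, 4)])  # west half
        pts = sample_background(spec, 500, valid_region=region, seed=0)
        assert (pts.x < 2).all()

    def test_no_valid_cells_errors(self):
        spec = GridSpec(4, 4, 1.0, origin_y=4.0)
        region = PolygonSet([box(50, 50, 60, 60)])
        with pytest.raises(ValueError):
            sample_background(spec, 10, valid_region=region, seed=0)


class TestSplit:
    def test_80_20_counts(self, spec6):
        occ = clean_occurrences(
            PointSet(np.column_stack([np.arange(10) * 0.5 + 0.1, np.full(10, 0.5)])),
            GridSpec(1, 10, 0.5, origin_y=0.5),
            seed=0,
        )
        train, test = split_train_test(occ, 0.2, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_union_disjoint_and_determinism(self):
        spec = GridSpec(1, 9, 1.0, origin_y=1.0)
        occ = clean_occurrences(
            PointSet(np.column_stack([np.arange(9) + 0.5, np.full(9, 0.5)])), spec, seed=0
        )
        t1, s1 = split_train_test(occ, 0.25, seed=5)
        t2, s2 = split_train_test(occ, 0.25, seed=5)
        np.testing.assert_array_equal(t1.points.coords, t2.points.coords)
        combined = np.vstack([t1.points.coords, s1.points.coords])
        assert len(np.unique(combined, axis=0)) == 9


class TestFeatures:
    def test_feature_counts_by_class(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        mat, builder = build_features(tab, classes={"linear"})
        assert mat.shape == (50, 2)
        mat2, _ = build_features(tab, classes={"linear", "quadratic"})
        assert mat2.shape == (50, 4)

    def test_hinge_endpoint_identities(self):
        x = np.linspace(0.0, 10.0, 101)
        tab = pd.DataFrame({"a": x})
        _, builder = build_features(tab, classes={"hinge"}, n_hinge_knots=3)
        fwd = [f for f in builder.specs if not f.reverse]
        for fs in fwd:
            at_knot = builder.transform(pd.DataFrame({"a": [fs.knot]}))[0]
            at_max = builder.transform(pd.DataFrame({"a": [10.0]}))
            j = builder.specs.index(fs)
            assert at_knot[j] == 0.0
            assert at_max[0, j] == pytest.approx(1.0)

    def test_zero_variance_dropped_with_warning(self):
        tab = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            _, builder = build_features(tab, classes={"linear"})
        assert builder.variables == ["b"]


class TestFitMaxent:
    def test_zero_features_is_uniform_gibbs(self):
        model = fit_maxent(np.empty((5, 0)), np.empty((100, 0)))
        assert model.entropy_H == pytest.approx(np.log(100))
        assert model.log_partition == pytest.approx(np.log(100))

    def test_single_binary_feature_closed_form(self):
        # with reg -> 0 the optimum is the one-parameter Gibbs solution
        # lambda* = log[(pbar (1 - bbar)) / (bbar (1 - pbar))]
        Fp = np.concatenate([np.ones(90), np.zeros(10)]).reshape(-1, 1)
        Fb = np.concatenate([np.ones(400), np.zeros(600)]).reshape(-1, 1)
        model = fit_maxent(Fp, Fb, reg_scale=1e-10)
        pbar, bbar = 0.9, 0.4
        expected = np.log(pbar * (1 - bbar) / (bbar * (1 - pbar)))
        assert model.lam[0] == pytest.approx(expected, abs=1e-4)

    def test_large_regularization_shrinks_to_zero(self):
        Fp = np.ones((10, 1))
        Fb = np.concatenate([np.ones(50), np.zeros(50)]).reshape(-1, 1)
        model = fit_maxent(Fp, Fb, reg_scale=1000.0)
        assert abs(model.lam[0]) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_and_normalization_at_optimum(self, seed):
        rng = np.random.default_rng(seed)
        Fb = rng.normal(size=(300, 6))
        Fp = rng.normal(loc=0.5, size=(40, 6))
        model = fit_maxent(Fp, Fb, reg_scale=1.0)
        q = model.background_density(Fb)
        assert abs(q.sum() - 1.0) <= 1e-9
        gap = np.abs(Fp.mean(axis=0) - Fb.T @ q)
        assert (gap <= model.reg_beta + 1e-6).all()


class TestPredict:
    def _simple_model(self, spec, classes=("linear",)):
        rng = np.random.default_rng(0)
        r = Raster(spec, rng.normal(size=spec.shape))
        bg = sample_background(spec, 500, seed=0)
        tab_b = pd.DataFrame({"a": score_at_points(r, bg)})
        feats_b, builder = build_features(tab_b, classes=classes)
        pres = PointSet(bg.coords[:40])
        tab_p = pd.DataFrame({"a": score_at_points(r, pres)})
        model = fit_maxent(builder.transform(tab_p), feats_b, builder=builder)
        return model, {"a": r}

    def test_uniform_model_outputs_one_minus_inv_e(self, spec6):
        model = fit_maxent(np.empty((3, 0)), np.empty((50, 0)))
        out = predict(model, {"a": Raster(spec6, np.zeros((6, 6)))})
        np.testing.assert_allclose(out.values, 1 - np.exp(-1))

    def test_output_ranking_matches_linear_predictor(self, spec6):
        model, rasters = self._simple_model(spec6)
        out = predict(model, rasters)
        tab = pd.DataFrame({"a": rasters["a"].values.ravel()})
        eta = model.builder.transform(tab) @ model.lam
        assert (np.argsort(out.values.ravel()) == np.argsort(eta)).all() or (
            spearmanr(out.values.ravel(), eta).statistic == pytest.approx(1.0)
        )

    def test_missing_variable_layer_named(self, spec6):
        model, rasters = self._simple_model(spec6)
        with pytest.raises(KeyError, match="a"):
            predict(model, {})

    def test_missing_covariate_cells_propagate(self, spec6):
        model, rasters = self._simple_model(spec6)
        vals = rasters["a"].values.copy()
        vals[0, 0] = np.nan
        out = predict(model, {"a": Raster(spec6, vals)})
        assert np.isnan(out.values[0, 0]) and np.isfinite(out.values[1:]).all()


class TestImportanceAndSelection:
    def _fit_tables(self, rng, n_vars=3, n_b=400, n_p=60, informative=0):
        bg = pd.DataFrame({f"v{i}": rng.normal(size=n_b) for i in range(n_vars)})
        pres = pd.DataFrame({f"v{i}": rng.normal(size=n_p) for i in range(n_vars)})
        pres[f"v{informative}"] += 1.5
        builder = FeatureBuilder.from_background(bg, classes={"linear"})
        model = fit_maxent(builder.transform(pres), builder.transform(bg), builder=builder)
        return model, pres, bg

    def test_importances_sum_to_100_and_flag_informative(self):
        model, pres, bg = self._fit_tables(np.random.default_rng(0))
        imp = permutation_importance_tables(model, pres, bg, n_reps=3, seed=0)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)
        assert max(imp, key=imp.get) == "v0"

    def test_zero_coefficient_variable_has_zero_importance(self):
        model, pres, bg = self._fit_tables(np.random.default_rng(1))
        # force a dead variable
        j = [i for i, f in enumerate(model.builder.specs) if f.variables[0] == "v2"]
        model.lam[j] = 0.0
        imp = permutation_importance_tables(model, pres, bg, n_reps=3, seed=0)
        assert imp["v2"] == 0.0

    def test_single_variable_model_importance_100(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"only": rng.normal(size=300)})
        pres = pd.DataFrame({"only": rng.normal(loc=1.0, size=40)})
        builder = FeatureBuilder.from_background(bg, classes={"linear"})
        model = fit_maxent(builder.transform(pres), builder.transform(bg), builder=builder)
        imp = permutation_importance_tables(model, pres, bg, n_reps=3, seed=0)
        assert imp["only"] == pytest.approx(100.0)

    def test_duplicated_variable_dropped_keeping_stronger_twin(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=500)
        bg = pd.DataFrame({"signal": base, "twin": base.copy(), "noise": rng.normal(size=500)})
        p_base = rng.normal(loc=1.5, size=80)
        pres = pd.DataFrame({"signal": p_base, "twin": p_base.copy(),
                             "noise": rng.normal(size=80)})
        trace = select_variables(pres, bg, rho_threshold=0.7, seed=0, classes={"linear"})
        assert len([d for d in trace.dropped if d[1] in ("signal", "twin")]) == 1
        assert ("signal" in trace.retained) != ("twin" in trace.retained)

    def test_uncorrelated_variables_all_retained(self):
        rng = np.random.default_rng(4)
        model, pres, bg = self._fit_tables(rng)
        trace = select_variables(pres, bg, rho_threshold=0.7, seed=0, classes={"linear"})
        assert sorted(trace.retained) == ["v0", "v1", "v2"]
        assert trace.dropped == []

    def test_retained_set_satisfies_rho_bound_exhaustively(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=400)
        bg = pd.DataFrame(
            {
                "a": base,
                "b": base + 0.1 * rng.normal(size=400),
                "c": rng.normal(size=400),
                "d": -base + 0.2 * rng.normal(size=400),
            }
        )
        # presences share the covariate structure of the landscape (they are
        # locations on it), shifted along the "a" axis
        p_base = rng.normal(loc=0.8, size=50)
        pres = pd.DataFrame(
            {
                "a": p_base,
                "b": p_base + 0.1 * rng.normal(size=50),
                "c": rng.normal(size=50),
                "d": -p_base + 0.2 * rng.normal(size=50),
            }
        )
        trace = select_variables(pres, bg, rho_threshold=0.7, seed=0, classes={"linear"})
        for i, u in enumerate(trace.retained):
            for v in trace.retained[i + 1 :]:
                rho = spearmanr(bg[u], bg[v]).statistic
                assert abs(rho) <= 0.7


class TestAuc:
    def test_perfect_separation_and_all_ties(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        p, b = [0.7, 0.4], [0.5, 0.3, 0.7]
        wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in p for y in b)
        assert auc(p, b) == pytest.approx(wins / 6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.integers(0, 100), min_size=1, max_size=20),
        b=st.lists(st.integers(0, 100), min_size=1, max_size=20),
    )
    def test_invariant_under_monotone_transform(self, p, b):
        # discrete score grid keeps distinct scores distinct after transform
        p = [x / 100 for x in p]
        b = [x / 100 for x in b]
        cloglog = lambda s: [1 - np.exp(-np.exp(x)) for x in s]
        assert auc(p, b) == pytest.approx(auc(cloglog(p), cloglog(b)), abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestThresholdAndEvaluate:
    def test_separable_scores_give_tss_one(self):
        t, sens, spec_ = best_threshold([0.8, 0.9], [0.1, 0.2])
        assert sens == 1.0 and spec_ == 1.0
        assert t == 0.8  # smallest candidate achieving the optimum

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, width=16), min_size=2, max_size=10),
        b=st.lists(st.floats(0, 1, width=16), min_size=2, max_size=10),
    )
    def test_matches_brute_force_scan(self, p, b):
        t, sens, spec_ = best_threshold(p, b)
        pa, ba = np.asarray(p), np.asarray(b)
        best = max(
            ((pa >= c).mean() + (ba < c).mean(), -c) for c in np.unique(np.r_[pa, ba])
        )
        assert sens + spec_ == pytest.approx(best[0])
        assert t == pytest.approx(-best[1])

    def test_evaluate_reports_consistent_tss(self, spec6):
        rng = np.random.default_rng(0)
        r = Raster(spec6, rng.normal(size=(6, 6)))
        bg = sample_background(spec6, 200, seed=0)
        tab_b = pd.DataFrame({"a": score_at_points(r, bg)})
        feats_b, builder = build_features(tab_b, classes={"linear"})
        pres = PointSet(bg.coords[:20])
        model = fit_maxent(
            builder.transform(pd.DataFrame({"a": score_at_points(r, pres)})),
            feats_b,
            builder=builder,
        )
        rep = evaluate(model, pres, bg, {"a": r})
        assert rep.tss == pytest.approx(rep.sensitivity + rep.specificity - 1.0)
        assert 0.0 <= rep.auc <= 1.0

    def test_random_scores_near_null(self):
        rng = np.random.default_rng(1)
        a = auc(rng.random(2000), rng.random(2000))
        assert a == pytest.approx(0.5, abs=0.05)


class TestBinarizeAndClip:
    def test_threshold_zero_keeps_everything_in_range(self, spec6, ramp6):
        rng_poly = PolygonSet([box(0, 0, 3, 6)])  # west half
        m = binarize_and_clip(ramp6, 0.0, rng_poly)
        assert np.isnan(m.values[:, 3:]).all()
        assert (m.values[:, :3] == 1).all()

    def test_disjoint_range_all_missing(self, spec6, ramp6):
        m = binarize_and_clip(ramp6, 0.5, PolygonSet([box(50, 50, 60, 60)]))
        assert np.isnan(m.values).all()

    def test_matches_cellwise_enumeration(self, spec6, ramp6):
        rng_poly = PolygonSet([box(1, 1, 5, 5)])
        m = binarize_and_clip(ramp6, 20.0, rng_poly)
        for r in range(6):
            for c in range(6):
                x, y = c + 0.5, 6 - (r + 0.5)
                if 1 < x < 5 and 1 < y < 5:
                    assert m.values[r, c] == (1.0 if ramp6.values[r, c] >= 20 else 0.0)
                else:
                    assert np.isnan(m.values[r, c])
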