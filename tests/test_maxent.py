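import numpy as np
import pytest

from nichekit import maxent, synthdata
from nichekit.errors import InputError
from nichekit.maxent import (
    ENMConfig, auc, build_features, fit_maxent, jackknife_contribution,
    permutation_importance, predict_logistic, replicate_cv, sample_background,
    tss, write_lambdas,
)
from nichekit.occurrences import extract_env

from conftest import make_world


@pytest.fixture(scope="module")
def fitted_world():
    stack, niches = make_world(101, n_rows=40, n_cols=40)
    occ = extract_env(synthdata.sample_occurrences(5, stack, niches["wild"], 300), stack)
    pres = occ.valid_env()
    bg = sample_background(stack, 1500, seed=2)
    fs = build_features(bg, classes=("L", "Q"), var_names=stack.names,
                        clamp_env=np.vstack([bg, pres]))
    model = fit_maxent(pres, bg, fs, reg_multiplier=1.0, max_iter=300)
    return stack, niches, pres, bg, fs, model


class TestBuildFeatures:
    def test_single_linear(self):
        bg = np.random.default_rng(0).random((50, 1))
        fs = build_features(bg, classes=("L",))
        assert len(fs) == 1

    def test_lqp_count(self):
        bg = np.random.default_rng(0).random((50, 3))
        fs = build_features(bg, classes=("L", "Q", "P"))
        assert len(fs) == 3 + 3 + 3

    def test_hinge_count(self):
        bg = np.random.default_rng(0).random((200, 2))
        fs = build_features(bg, classes=("H",), hinge_knots_per_var=5)
        assert len(fs) == 2 * 5 * 2

    def test_features_scaled_to_unit_interval(self):
        bg = np.random.default_rng(1).normal(size=(300, 3)) * 10 + 5
        fs = build_features(bg, classes=("L", "Q", "H", "P"), hinge_knots_per_var=4)
        F, _ = fs.evaluate(bg)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12

    def test_constant_variable_drops_qh(self):
        bg = np.column_stack([np.ones(100), np.random.default_rng(0).random(100)])
        fs = build_features(bg, classes=("L", "Q", "H"), hinge_knots_per_var=3)
        kinds = [(f.kind, f.vars) for f in fs.features]
        assert ("Q", (0,)) not in kinds
        assert not any(k == "H" and v == (0,) for k, v in kinds)

    def test_hinge_forward_reverse_pairs(self):
        bg = np.random.default_rng(2).random((500, 1))
        fs = build_features(bg, classes=("H",), hinge_knots_per_var=6)
        fwd = sum(1 for f in fs.features if f.direction > 0)
        rev = sum(1 for f in fs.features if f.direction < 0)
        assert fwd == rev == 6


class TestFitMaxent:
    def test_gibbs_tilt_recovery(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(0, 10, size=(6000, 1))
        fs = build_features(bg, classes=("L",))
        Fb, _ = fs.evaluate(bg)
        w = np.exp(2 * Fb[:, 0]); w /= w.sum()
        pres = bg[rng.choice(len(bg), size=5000, p=w)]
        model = fit_maxent(pres, bg, fs, reg_multiplier=1e-8, max_iter=2000, tol=1e-12,
                           include_presences_in_background=False)
        assert model.lambdas[0] == pytest.approx(2.0, abs=0.15)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(500, 2))
        pres = rng.normal(size=(50, 2))
        fs = build_features(bg, classes=("L", "Q"))
        model = fit_maxent(pres, bg, fs, reg_multiplier=1e9, max_iter=200)
        np.testing.assert_allclose(model.lambdas, 0.0)
        assert model.entropy_H == pytest.approx(np.log(model.n_background), abs=1e-6)

    def test_default_max_iter_500(self):
        import inspect

        assert inspect.signature(fit_maxent).parameters["max_iter"].default == 500

    def test_raw_distribution_sums_to_one(self, fitted_world):
        _, _, pres, bg, _, model = fitted_world
        r, _ = model.raw_scores(np.vstack([bg, pres]))
        assert abs(r.sum() - 1.0) < 1e-8

    def test_objective_monotone(self, fitted_world):
        _, _, _, _, _, model = fitted_world
        assert np.all(np.diff(model.objective_path) >= -1e-12)

    def test_min_presences(self):
        bg = np.random.default_rng(0).random((100, 2))
        fs = build_features(bg, classes=("L",))
        with pytest.raises(InputError):
            fit_maxent(bg[:3], bg, fs)

    def test_non_finite_rejected(self):
        bg = np.random.default_rng(0).random((100, 2))
        fs = build_features(bg, classes=("L",))
        pres = bg[:20].copy()
        pres[0, 0] = np.nan
        with pytest.raises(InputError):
            fit_maxent(pres, bg, fs)

    def test_recovery_spearman(self):
        from scipy.stats import spearmanr

        stack, niches = make_world(55, n_rows=50, n_cols=50)
        occ = extract_env(synthdata.sample_occurrences(7, stack, niches["landrace"], 500), stack)
        pres = occ.valid_env()
        bg = sample_background(stack, 5000, seed=3)
        fs = build_features(bg, classes=("L", "Q"), var_names=stack.names,
                            clamp_env=np.vstack([bg, pres]))
        model = fit_maxent(pres, bg, fs, reg_multiplier=1.0)
        pred = predict_logistic(model, stack)
        true = synthdata.true_suitability_layer(stack, niches["landrace"])
        v = stack.valid_mask
        assert spearmanr(true.values[v], pred.layer.values[v]).statistic >= 0.85


class TestPredictLogistic:
    def test_uniform_model_half(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=(400, 2))
        pres = rng.normal(size=(40, 2))
        fs = build_features(bg, classes=("L",))
        model = fit_maxent(pres, bg, fs, reg_multiplier=1e9)
        # all lambdas 0: logistic = (e^H/N)/(1+e^H/N); H=log N -> 0.5
        r, _ = model.logistic_scores(bg)
        np.testing.assert_allclose(r, 0.5, atol=1e-9)

    def test_hand_computation_single_cell(self, fitted_world):
        _, _, pres, bg, fs, model = fitted_world
        z = bg[7:8]
        F, _ = fs.evaluate(z)
        raw = np.exp(F @ model.lambdas + model.linear_predictor_offset)
        expected = raw * np.exp(model.entropy_H) / (1 + raw * np.exp(model.entropy_H))
        got, _ = model.logistic_scores(z)
        assert got[0] == pytest.approx(expected[0], rel=1e-12)

    def test_clamping_beyond_training_max(self, fitted_world):
        _, _, _, bg, fs, model = fitted_world
        at_max = fs.clamp_max[None, :]
        beyond = at_max + 100.0
        s_max, cl_max = model.logistic_scores(at_max, clamp=True)
        s_beyond, cl_beyond = model.logistic_scores(beyond, clamp=True)
        assert s_beyond[0] == pytest.approx(s_max[0], rel=1e-12)
        assert cl_beyond[0] and not cl_max[0]

    def test_values_in_unit_interval(self, fitted_world):
        stack, _, _, _, _, model = fitted_world
        sm = predict_logistic(model, stack)
        v = stack.valid_mask
        assert sm.layer.values[v].min() >= 0
        assert sm.layer.values[v].max() <= 1

    def test_missing_variable_error(self, fitted_world):
        stack, _, _, _, _, model = fitted_world
        from nichekit.grids import EnvStack

        partial = EnvStack(stack.layers[:1])
        with pytest.raises(InputError):
            predict_logistic(model, partial)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_tied(self):
        assert auc([0.5] * 5, [0.5] * 7) == 0.5

    def test_worked_example(self):
        # pairs: (.9,.5)w (.9,.1)w (.4,.5)l (.4,.1)w -> 3/4
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pres = rng.random(150)
        bg = rng.random(200)
        bg[:30] = pres[:30]  # inject ties
        wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
        assert auc(pres, bg) == pytest.approx(wins / (150 * 200), abs=1e-12)

    def test_empty_error(self):
        with pytest.raises(InputError):
            auc([], [0.5])


class TestTSS:
    def test_perfect_separation(self):
        r = tss([0.9, 0.8], [0.2, 0.1], threshold=0.5)
        assert r.tss == pytest.approx(1.0)

    def test_threshold_zero(self):
        r = tss([0.9, 0.1], [0.5, 0.2], threshold=0.0)
        assert r.tss == pytest.approx(0.0)
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_hand_example_one_third(self):
        r = tss([0.8, 0.6, 0.2], [0.7, 0.3, 0.1], threshold=0.5)
        assert r.tss == pytest.approx(2 / 3 + 2 / 3 - 1)

    def test_max_tss_at_least_pointwise(self):
        rng = np.random.default_rng(4)
        r = tss(rng.random(50) * 0.5 + 0.5, rng.random(50) * 0.6, threshold=0.4)
        assert r.max_tss >= r.tss - 1e-12


class TestPermutationImportance:
    def test_single_informative_variable(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(size=(2000, 2))
        # presences depend only on variable 0
        w = np.exp(3 * bg[:, 0]); w /= w.sum()
        pres = bg[rng.choice(len(bg), 400, p=w)]
        fs = build_features(bg, classes=("L",), var_names=["a", "b"])
        model = fit_maxent(pres, bg, fs, reg_multiplier=0.5)
        imp = permutation_importance(model, pres, bg, seed=0)
        assert imp["a"] > 90.0

    def test_percentages_sum_to_100(self, fitted_world):
        _, _, pres, bg, _, model = fitted_world
        imp = permutation_importance(model, pres, bg, seed=1)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in imp.values())


class TestReplicateCV:
    def test_default_ten_replicates(self):
        import inspect

        assert inspect.signature(replicate_cv).parameters["n_replicates"].default == 10

    def test_replicates_and_maps(self, fitted_world):
        stack, _, pres, bg, _, _ = fitted_world
        config = ENMConfig(classes=("L", "Q"), max_iter=100)
        reps, med, sd = replicate_cv(pres, bg, config, n_replicates=3, seed=1,
                                     stack=stack, var_names=stack.names)
        assert len(reps) == 3
        v = stack.valid_mask
        assert np.all(sd.layer.values[v] >= 0)
        assert np.all((med.layer.values[v] >= 0) & (med.layer.values[v] <= 1))
        for model, report in reps:
            assert 0 <= report.auc_test <= 1

    def test_deterministic(self, fitted_world):
        _, _, pres, bg, _, _ = fitted_world
        config = ENMConfig(classes=("L",), max_iter=50)
        a, _, _ = replicate_cv(pres, bg, config, n_replicates=2, seed=9)
        b, _, _ = replicate_cv(pres, bg, config, n_replicates=2, seed=9)
        np.testing.assert_array_equal(a[0][0].lambdas, b[0][0].lambdas)
        assert a[0][1].auc_test == b[0][1].auc_test


class TestJackknife:
    def test_duplicated_variable_redundant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=3000)
        bg = np.column_stack([x, x + 1e-9 * rng.normal(size=3000), rng.normal(size=3000)])
        w = np.exp(2 * x); w /= w.sum()
        pres = bg[rng.choice(len(bg), 300, p=w)]
        config = ENMConfig(classes=("L",), max_iter=200)
        jk = jackknife_contribution(pres, bg, config, var_names=["a", "a2", "noise"], seed=1)
        only_a, without_a = jk["a"]
        # dropping a duplicated informative variable barely hurts
        assert without_a > 0.5 + (only_a - 0.5) * 0.5

    def test_informative_alone_near_full(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(2000, 2))
        w = np.exp(2.5 * bg[:, 0]); w /= w.sum()
        pres = bg[rng.choice(len(bg), 300, p=w)]
        config = ENMConfig(classes=("L",), max_iter=200)
        jk = jackknife_contribution(pres, bg, config, var_names=["a", "b"], seed=2)
        only_a, _ = jk["a"]
        assert only_a > 0.7

    def test_needs_two_variables(self):
        with pytest.raises(InputError):
            jackknife_contribution(np.random.random((20, 1)), np.random.random((50, 1)), ENMConfig())


class TestBackgroundSampling:
    def test_without_replacement_capped(self, fitted_world):
        stack, _, _, _, _, _ = fitted_world
        n_valid = int(stack.valid_mask.sum())
        bg = sample_background(stack, n=10 ** 6, seed=1)
        assert bg.shape == (n_valid, len(stack))

    def test_seeded(self, fitted_world):
        stack, _, _, _, _, _ = fitted_world
        a = sample_background(stack, 100, seed=5)
        b = sample_background(stack, 100, seed=5)
        np.testing.assert_array_equal(a, b)


def test_write_lambdas(tmp_path, fitted_world):
    _, _, _, _, _, model = fitted_world
    p = tmp_path / "model.lambdas.txt"
    write_lambdas(model, p)
    text = p.read_text()
    assert "entropy_H" in text and "L(bio1)" in text


def test_lambdas_round_trip_predictions(tmp_path):
    """A model rebuilt from its lambdas file gives identical projections."""
    rng = np.random.default_rng(12)
    bg = rng.normal(size=(800, 3)) * 3
    w = np.exp(1.5 * bg[:, 0] - bg[:, 1] ** 2 / 8); w /= w.sum()
    pres = bg[rng.choice(len(bg), 120, p=w)]
    fs = build_features(bg, classes=("L", "Q", "H", "P"), hinge_knots_per_var=5,
                        var_names=["a", "b", "c"], clamp_env=np.vstack([bg, pres]))
    model = fit_maxent(pres, bg, fs, reg_multiplier=1.0, max_iter=200)
    p = tmp_path / "m.lambdas.txt"
    write_lambdas(model, p)
    again = maxent.read_lambdas(p)
    X = rng.normal(size=(200, 3)) * 4  # includes out-of-range values -> clamping
    s1, c1 = model.logistic_scores(X, clamp=True)
    s2, c2 = again.logistic_scores(X, clamp=True)
    np.testing.assert_array_equal(s1, s2)
    np.testing.assert_array_equal(c1, c2)
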