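import numpy as np
import pandas as pd
import pytest

from fluency2ef.prediction_engine import (
    CVConfig,
    FoldPreprocessor,
    compare_feature_sets,
    correlation_p_value,
    followup_spearman,
    oob_permutation_importance,
    residualize_confounds,
    run_repeated_cv,
    screen_targets,
    top_k,
)


def _confounds(n, rng):
    return pd.DataFrame({
        "sex": rng.integers(0, 2, size=n),
        "age": rng.uniform(20, 55, size=n),
        "education": rng.integers(1, 5, size=n),
    })


class TestResidualization:
    def test_perfect_linear_confound_vanishes(self):
        rng = np.random.default_rng(0)
        C = _confounds(100, rng)
        X = (2.0 * C["age"]).to_numpy()[:, None]
        train_r, test_r = residualize_confounds(X[:80], C[:80], X[80:], C[80:])
        assert np.allclose(train_r, 0.0, atol=1e-10)
        assert np.allclose(test_r, 0.0, atol=1e-8)

    def test_train_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(1)
        C = _confounds(200, rng)
        X = rng.normal(size=(200, 5)) + 0.5 * C["age"].to_numpy()[:, None]
        train_r, _ = residualize_confounds(X, C, X, C)
        for j in range(5):
            for col in C.columns:
                r = np.corrcoef(train_r[:, j], C[col])[0, 1]
                assert abs(r) < 1e-10

    def test_independent_feature_survives(self):
        rng = np.random.default_rng(2)
        n = 500
        C = _confounds(n, rng)
        x = rng.normal(size=n)
        train_r, _ = residualize_confounds(x[:, None], C, x[:, None], C)
        r = np.corrcoef(train_r[:, 0], (x - x.mean()) / x.std())[0, 1]
        assert r > 0.95

    def test_zero_variance_feature_passes_through_as_zeros(self):
        rng = np.random.default_rng(3)
        C = _confounds(50, rng)
        X = np.ones((50, 1))
        train_r, test_r = residualize_confounds(X, C, X, C)
        assert np.allclose(train_r, 0.0) and np.allclose(test_r, 0.0)


class TestLeakageGuard:
    def test_mutating_heldout_rows_never_changes_training_parameters(self):
        rng = np.random.default_rng(4)
        n = 80
        X = rng.normal(size=(n, 6))
        X[rng.random((n, 6)) < 0.1] = np.nan  # some missingness
        C = _confounds(n, rng).to_numpy(dtype=float)

        train, test = np.arange(60), np.arange(60, 80)
        prep = FoldPreprocessor().fit(X[train], C[train])
        params = (prep.medians_.copy(), prep.means_.copy(),
                  prep.sds_.copy(), prep.coefs_.copy())
        train_out = prep.transform(X[train], C[train])

        X_mutated = X.copy()
        X_mutated[test] = 1e6  # arbitrarily corrupt held-out rows
        prep2 = FoldPreprocessor().fit(X_mutated[train], C[train])
        for a, b in zip(params, (prep2.medians_, prep2.means_, prep2.sds_,
                                 prep2.coefs_)):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(
            train_out, prep2.transform(X_mutated[train], C[train])
        )


class TestRepeatedCV:
    def _data(self, n=60, p=6, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"p{i}" for i in range(n)], name="participant_id")
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)], index=idx)
        C = _confounds(n, rng).set_index(idx)
        return X, C, rng

    def test_self_prediction_recovers_target(self):
        X, C, _ = self._data(n=150)
        target = X["f0"].rename("t")
        cfg = CVConfig(seed=1, n_repetitions=2, n_trees=50)
        res = run_repeated_cv(X, target, C, cfg)
        assert res.mean_r >= 0.95
        assert res.n_models == 20

    def test_null_target_centres_on_zero(self):
        # single-seed mean_r is noisy at this scale; the null check is on the
        # grand mean over independent simulations
        means = []
        for seed in range(8):
            X, C, rng = self._data(n=120, seed=seed)
            target = pd.Series(rng.normal(size=len(X)), index=X.index, name="t")
            cfg = CVConfig(seed=seed, n_repetitions=1, n_trees=10)
            means.append(run_repeated_cv(X, target, C, cfg).mean_r)
        assert abs(np.mean(means)) < 0.1

    def test_identical_seed_reproduces_mean_r_exactly(self):
        X, C, rng = self._data()
        target = pd.Series(X["f0"] + rng.normal(size=len(X)), name="t")
        cfg = CVConfig(seed=3, n_repetitions=1, n_trees=20)
        r1 = run_repeated_cv(X, target, C, cfg)
        r2 = run_repeated_cv(X, target, C, cfg)
        assert r1.mean_r == r2.mean_r
        np.testing.assert_array_equal(r1.fold_r, r2.fold_r)

    def test_constant_target_skipped_with_reason(self):
        X, C, _ = self._data()
        target = pd.Series(1.0, index=X.index, name="t")
        res = run_repeated_cv(X, target, C, CVConfig(seed=0))
        assert res.skipped == "constant target"
        assert not res.significant

    def test_too_few_participants_skipped(self):
        X, C, _ = self._data(n=10)
        target = pd.Series(np.arange(10.0), index=X.index, name="t")
        res = run_repeated_cv(X, target, C, CVConfig(seed=0))
        assert res.skipped is not None

    def test_parametric_p_matches_correlation_scale(self):
        # a correlation of 0.41 on 230 participants is in the 1e-10 regime
        p = correlation_p_value(0.41, 230)
        assert 1e-11 < p < 1e-9
        assert correlation_p_value(0.0, 230) == pytest.approx(1.0)


class TestImportance:
    def test_planted_feature_dominates_oob_importance(self):
        rng = np.random.default_rng(7)
        n, p = 150, 10
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 3] + rng.normal(scale=0.5, size=n)
        from sklearn.ensemble import RandomForestRegressor
        forest = RandomForestRegressor(n_estimators=50, max_features=1 / 3,
                                       random_state=0).fit(X, y)
        imp = oob_permutation_importance(forest, X, y, rng)
        assert np.argmax(imp) == 3
        # pure-noise features sit near zero relative to the planted one
        noise = np.delete(imp, 3)
        assert np.abs(noise).max() < 0.25 * imp[3]

    def test_top_k_count_and_tie_break(self):
        names = [f"f{j}" for j in range(43)]
        imp = np.zeros(43)
        assert top_k(imp, names, k=5) == sorted(names)[:5]
        imp[7] = 1.0
        assert top_k(imp, names, k=5)[0] == "f7"
        assert len(top_k(imp, names, k=5)) == 5


class TestFollowupAndComparison:
    def test_spearman_rank_invariance(self):
        idx = pd.Index([f"p{i}" for i in range(30)])
        x = pd.Series(np.arange(30.0), index=idx)
        feats = pd.DataFrame({"mono": np.exp(x / 10), "rev": -x}, index=idx)
        table = followup_spearman(feats, x.rename("t"), ["mono", "rev"])
        assert table.loc[0, "spearman_rho"] == pytest.approx(1.0)
        assert table.loc[1, "spearman_rho"] == pytest.approx(-1.0)
        assert bool(table.loc[0, "significant"])

    def test_spearman_undefined_below_three_pairs(self):
        idx = pd.Index(["a", "b", "c"])
        feats = pd.DataFrame({"f": [1.0, np.nan, np.nan]}, index=idx)
        t = pd.Series([1.0, 2.0, np.nan], index=idx, name="t")
        table = followup_spearman(feats, t, ["f"])
        assert np.isnan(table.loc[0, "spearman_rho"])

    def test_identical_arms_have_zero_delta(self):
        rng = np.random.default_rng(8)
        idx = pd.Index([f"p{i}" for i in range(40)], name="participant_id")
        X = pd.DataFrame(rng.normal(size=(40, 4)),
                         columns=list("abcd"), index=idx)
        C = _confounds(40, rng).set_index(idx)
        t = pd.Series(rng.normal(size=40), index=idx, name="y")
        cfg = CVConfig(seed=5, n_repetitions=1, n_trees=10)
        r1 = run_repeated_cv(X, t, C, cfg)
        r2 = run_repeated_cv(X, t, C, cfg)
        comp = compare_feature_sets({"y": r1}, {"y": r2})
        assert comp["delta_mean_r"].iloc[0] == 0.0

    def test_screen_alpha_one_flags_everything(self):
        rng = np.random.default_rng(9)
        idx = pd.Index([f"p{i}" for i in range(40)], name="participant_id")
        X = pd.DataFrame(rng.normal(size=(40, 4)),
                         columns=list("abcd"), index=idx)
        C = _confounds(40, rng).set_index(idx)
        results = {}
        for name in ("y1", "y2"):
            t = pd.Series(rng.normal(size=40), index=idx, name=name)
            results[name] = run_repeated_cv(
                X, t, C, CVConfig(seed=6, n_repetitions=1, n_trees=10)
            )
        screened = screen_targets(results, alpha=1.0)
        assert set(screened["target"]) == {"y1", "y2"}
        assert (screened["mean_r"].diff().dropna() <= 0).all()
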