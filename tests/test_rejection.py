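import math

import numpy as np
import pandas as pd
import pytest

from mitoabc import ReferenceTable, cross_validate, reject, standardize

from conftest import seeded_rng


def make_table(stats, models, params=None):
    df = pd.DataFrame(stats, columns=[f"stat{j}" for j in range(stats.shape[1])])
    df.insert(0, "model", models)
    param_cols = []
    if params is not None:
        for name, col in params.items():
            df[name] = col
            param_cols.append(name)
    return ReferenceTable(df, param_cols=param_cols)


@pytest.fixture
def toy_table():
    """10 rows, 2 statistics, with hand-computable distances to (0, 0)."""
    stats = np.array([
        [0.0, 0.0],   # row 0: the observed point itself
        [1.0, 0.0],
        [0.0, 1.0],
        [1.0, 1.0],
        [2.0, 0.0],
        [0.0, 2.0],
        [2.0, 2.0],
        [3.0, 1.0],
        [1.0, 3.0],
        [3.0, 3.0],
    ])
    models = ["m1"] * 5 + ["m2"] * 5
    return make_table(stats, models), np.zeros(2)


class TestStandardize:
    def test_constant_column_dropped_and_named(self):
        stats = np.column_stack([np.arange(6.0), np.full(6, 7.0)])
        table = make_table(stats, ["a"] * 6)
        _, _, report = standardize(table, np.array([1.0, 7.0]))
        assert report.dropped == ["stat1"]
        assert report.names == ["stat0"]

    def test_standardized_moments(self):
        rng = seeded_rng(30)
        stats = rng.normal(5.0, 3.0, size=(200, 4))
        table = make_table(stats, ["a"] * 200)
        Xs, _, _ = standardize(table, stats[0])
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-12)

    def test_scaling_roundtrips(self):
        rng = seeded_rng(31)
        stats = rng.normal(size=(50, 3)) * [1.0, 10.0, 0.1] + [5.0, -2.0, 0.0]
        table = make_table(stats, ["a"] * 50)
        Xs, obs_s, report = standardize(table, stats[7])
        np.testing.assert_allclose(report.unscale(obs_s), stats[7], atol=1e-12)
        np.testing.assert_allclose(report.unscale(Xs[3]), stats[3], atol=1e-12)

    def test_all_constant_raises(self):
        table = make_table(np.ones((5, 2)), ["a"] * 5)
        with pytest.raises(ValueError, match="zero SD"):
            standardize(table, np.ones(2))

    def test_mad_scaling_is_outlier_robust(self):
        rng = seeded_rng(43)
        stats = rng.normal(size=(100, 2))
        stats[0] = [1e6, -1e6]  # one gross outlier
        table = make_table(stats, ["a"] * 100)
        _, _, rep_sd = standardize(table, stats[1], method="sd")
        _, _, rep_mad = standardize(table, stats[1], method="mad")
        assert (rep_mad.scale < rep_sd.scale).all()
        with pytest.raises(ValueError, match="scaling method"):
            standardize(table, stats[1], method="minmax")


class TestReject:
    def test_toy_table_matches_enumeration(self, toy_table):
        # brute-force oracle: standardize by column mean/SD, sort Euclidean
        table, obs = toy_table
        X = table.stats_matrix()
        Xs = (X - X.mean(0)) / X.std(0)
        obs_s = (obs - X.mean(0)) / X.std(0)
        dist = np.sqrt(((Xs - obs_s) ** 2).sum(1))
        expected_idx = np.argsort(dist, kind="stable")[: math.ceil(0.3 * 10)]

        res = reject(table, obs, tolerance=0.3)
        assert len(res.accepted_idx) == 3
        assert set(res.accepted_idx) == set(expected_idx)
        models = table.df["model"].to_numpy()
        expected_post = pd.Series(models[expected_idx]).value_counts(
            normalize=True
        )
        for m in table.models:
            assert res.model_posteriors[m] == pytest.approx(
                expected_post.get(m, 0.0)
            )

    def test_zero_distance_row_always_accepted(self, toy_table):
        table, obs = toy_table
        res = reject(table, obs, tolerance=0.1)
        assert res.accepted_idx.tolist() == [0]
        assert res.distances[0] == 0.0

    def test_full_tolerance_recovers_row_fractions(self, toy_table):
        table, obs = toy_table
        res = reject(table, obs, tolerance=1.0)
        assert len(res.accepted_idx) == 10
        assert res.model_posteriors["m1"] == pytest.approx(0.5)
        assert res.model_posteriors["m2"] == pytest.approx(0.5)

    def test_posteriors_sum_to_one(self, toy_table):
        table, obs = toy_table
        for tol in (0.05, 0.2, 0.7, 1.0):
            res = reject(table, obs, tolerance=tol)
            assert res.model_posteriors.sum() == pytest.approx(1.0, abs=1e-12)
            assert len(res.accepted_idx) == math.ceil(tol * 10)

    def test_distances_non_decreasing(self, toy_table):
        table, obs = toy_table
        res = reject(table, obs, tolerance=0.8)
        assert (np.diff(res.distances) >= 0).all()

    def test_shuffle_invariant_posteriors(self):
        rng = seeded_rng(32)
        stats = rng.normal(size=(60, 5))
        models = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        table = make_table(stats, models)
        obs = rng.normal(size=5)
        res1 = reject(table, obs, 0.2)
        perm = rng.permutation(60)
        shuffled = ReferenceTable(
            table.df.iloc[perm].reset_index(drop=True), param_cols=[]
        )
        res2 = reject(shuffled, obs, 0.2)
        for m in "abc":
            assert res1.model_posteriors[m] == res2.model_posteriors[m]

    def test_invalid_tolerance(self, toy_table):
        table, obs = toy_table
        for tol in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="tolerance"):
                reject(table, obs, tol)

    def test_param_quantiles_of_accepted_rows(self):
        rng = seeded_rng(33)
        stats = rng.normal(size=(40, 3))
        params = {"lgm_severity": rng.uniform(0.2, 0.6, 40)}
        table = make_table(stats, ["lgm"] * 40, params)
        res = reject(table, stats[0], 0.25)
        q = res.param_quantiles("lgm")
        assert "lgm_severity" in q.columns
        assert (q["lgm_severity"] >= 0.2).all()
        assert (q["lgm_severity"] <= 0.6).all()


class TestCrossValidate:
    def test_separable_models_give_diagonal_confusion(self):
        rng = seeded_rng(34)
        blocks = [rng.normal(loc, 0.1, size=(30, 3))
                  for loc in (0.0, 10.0, 20.0)]
        stats = np.vstack(blocks)
        models = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        table = make_table(stats, models)
        conf = cross_validate(table, n_pseudo=10, tolerance=0.1,
                              rng=seeded_rng(35))
        assert np.array_equal(np.diag(conf), [10, 10, 10])

    def test_rows_sum_to_n_pseudo(self):
        rng = seeded_rng(36)
        stats = rng.normal(size=(80, 4))
        models = ["a"] * 40 + ["b"] * 40
        table = make_table(stats, models)
        conf = cross_validate(table, n_pseudo=8, tolerance=0.2,
                              rng=seeded_rng(37))
        assert (conf.sum(axis=1) == 8).all()

    def test_identical_models_near_uniform(self):
        # all models simulate the same distribution: expected accuracy 1/k
        rng = seeded_rng(38)
        stats = rng.normal(size=(200, 3))
        models = (["a", "b", "c", "d"] * 50)
        table = make_table(stats, models)
        conf = cross_validate(table, n_pseudo=25, tolerance=0.2,
                              rng=seeded_rng(39))
        accuracy = np.diag(conf).sum() / conf.to_numpy().sum()
        # binomial(100, 0.25): 3 sigma is ~0.13
        assert abs(accuracy - 0.25) < 0.15

    def test_too_many_pseudo_rows_rejected(self):
        stats = seeded_rng(40).normal(size=(10, 2))
        table = make_table(stats, ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="n_pseudo"):
            cross_validate(table, n_pseudo=5, tolerance=0.5, rng=seeded_rng(41))


def test_csv_roundtrip(tmp_path):
    rng = seeded_rng(42)
    stats = rng.normal(size=(12, 3))
    params = {"lgm_severity": rng.uniform(0.2, 0.6, 12)}
    table = make_table(stats, ["constant"] * 6 + ["lgm"] * 6, params)
    path = tmp_path / "ref.csv"
    table.to_csv(path)
    back = ReferenceTable.from_csv(path)
    pd.testing.assert_frame_equal(table.df, back.df)
    assert back.param_cols == table.param_cols
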