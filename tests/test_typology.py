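import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from duonet.measures import CRITERION_VARS
from duonet.typology import (
    ScalingError,
    anova_by_cluster,
    cluster_tscores,
    kmeans_cluster,
    linkage_to_newick,
    run_typology,
    select_k,
    standardize,
    ward_cluster,
    ward_then_kmeans,
)


def _profile_frame(values: dict, n: int) -> pd.DataFrame:
    """Frame with all criterion columns, filling unspecified ones with noise."""
    rng = np.random.default_rng(0)
    data = {v: values.get(v, rng.normal(size=n)) for v in CRITERION_VARS}
    return pd.DataFrame(data, index=[f"c{i}" for i in range(n)])


def _blobs(k, per, sep=10.0, seed=3, dims=len(CRITERION_VARS)):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, dims))
    x = np.vstack([centers[i] + rng.normal(size=(per, dims)) for i in range(k)])
    labels = np.repeat(range(k), per)
    df = pd.DataFrame(x, columns=CRITERION_VARS, index=[f"c{i}" for i in range(k * per)])
    return df, labels


class TestStandardize:
    def test_population_sd_convention(self):
        df = _profile_frame({"density": [1.0, 2.0, 3.0]}, 3)
        z = standardize(df)
        np.testing.assert_allclose(z["density"], [-1.224745, 0, 1.224745], atol=1e-6)

    def test_constant_column_raises(self):
        df = _profile_frame({"components": [5.0, 5.0, 5.0]}, 3)
        with pytest.raises(ScalingError, match="components"):
            standardize(df)

    def test_idempotence(self):
        df = _profile_frame({}, 20)
        z1 = standardize(df)
        z2 = standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_missing_rows_excluded_listwise(self):
        df = _profile_frame({}, 10)
        df.iloc[3, 2] = np.nan
        z = standardize(df)
        assert len(z) == 9 and "c3" not in z.index


class TestWard:
    def test_recovers_two_separated_blobs(self):
        z, truth = _blobs(2, 20, sep=10, seed=3)
        labels, _ = ward_cluster(standardize(z), 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_and_bad_k(self):
        z = standardize(_profile_frame({}, 8))
        labels, _ = ward_cluster(z, 8)
        assert labels.nunique() == 8
        with pytest.raises(ValueError):
            ward_cluster(z, 9)

    def test_merge_heights_nondecreasing(self):
        z = standardize(_profile_frame({}, 30))
        _, lk = ward_cluster(z, 3)
        heights = lk[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_export_contains_all_leaves(self):
        z = standardize(_profile_frame({}, 6))
        _, lk = ward_cluster(z, 2)
        tree = linkage_to_newick(lk, z.index)
        assert tree.endswith(";") and all(name in tree for name in z.index)


class TestKMeans:
    def test_wss_matches_exhaustive_two_partition(self):
        pts = np.array([[0.0], [0.2], [0.1], [10.0], [10.3]])
        z = pd.DataFrame(np.repeat(pts, len(CRITERION_VARS), axis=1),
                         columns=CRITERION_VARS)
        labels, centers = kmeans_cluster(z, 2, restarts=10, seed=0)

        def wss_of(assign):
            total = 0.0
            for c in (0, 1):
                grp = z.to_numpy()[np.array(assign) == c]
                if len(grp):
                    total += ((grp - grp.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            wss_of(assign)
            for assign in itertools.product((0, 1), repeat=5)
            if len(set(assign)) == 2
        )
        got = wss_of(labels.to_numpy())
        assert got == pytest.approx(best)

    def test_k1_gives_total_sum_of_squares(self):
        z = standardize(_profile_frame({}, 12))
        labels, _ = kmeans_cluster(z, 1)
        x = z.to_numpy()
        assert ((x - x.mean(axis=0)) ** 2).sum() == pytest.approx(
            ((x - x[labels == 0].mean(axis=0)) ** 2).sum())

    def test_same_seed_same_labels(self):
        z = standardize(_profile_frame({}, 40))
        a, _ = kmeans_cluster(z, 3, seed=5)
        b, _ = kmeans_cluster(z, 3, seed=5)
        assert (a == b).all()

    def test_row_permutation_invariance_up_to_renaming(self):
        z, _ = _blobs(3, 15, sep=8, seed=9)
        z = standardize(z)
        perm = np.random.default_rng(1).permutation(len(z))
        a, _ = ward_then_kmeans(z, 3, seed=0)
        b, _ = ward_then_kmeans(z.iloc[perm], 3, seed=0)
        assert adjusted_rand_score(a.loc[b.index], b) == 1.0


class TestSelectK:
    def test_majority_vote_finds_planted_k(self):
        z, _ = _blobs(3, 25, sep=12, seed=4)
        diag = select_k(standardize(z), k_range=range(2, 7), seed=0, gap_b=20)
        assert diag.attrs["majority_k"] == 3
        assert (np.diff(diag["wss"].to_numpy()) <= 1e-9).all()

    def test_gap_statistic_reproducible(self):
        z = standardize(_profile_frame({}, 30))
        d1 = select_k(z, k_range=range(2, 5), seed=7, gap_b=10)
        d2 = select_k(z, k_range=range(2, 5), seed=7, gap_b=10)
        pd.testing.assert_frame_equal(d1, d2)


class TestTScores:
    def test_cluster_at_overall_mean_scores_100(self):
        df = _profile_frame({}, 24)
        labels = pd.Series(np.tile([0, 1], 12), index=df.index)
        # symmetric labels: both cluster means equal the overall mean in expectation;
        # force exact equality by mirroring values
        df["density"] = np.tile([1.0, 1.0], 12)
        with pytest.raises(ScalingError):
            cluster_tscores(df[["density"]], labels, variables=["density"])
        df["density"] = np.r_[np.tile([2.0, 2.0], 6), np.tile([4.0, 4.0], 6)]
        t = cluster_tscores(df, labels, variables=["density"])
        np.testing.assert_allclose(t["density"], [100.0, 100.0])

    def test_weighted_mean_100_and_sign(self):
        df = _profile_frame({}, 50)
        labels = pd.Series(np.r_[np.zeros(30, int), np.ones(20, int)], index=df.index)
        t = cluster_tscores(df, labels)
        sizes = labels.value_counts().sort_index().to_numpy()
        weighted = (t.to_numpy() * sizes[:, None]).sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(weighted, 100.0, atol=1e-9)
        means = df.groupby(labels).mean()
        overall = df.mean()
        assert ((t > 100).to_numpy() == (means > overall).to_numpy()).all()


class TestAnova:
    def test_perfect_separation_flagged(self):
        df = _profile_frame({"density": [0, 0, 0, 1, 1, 1]}, 6)
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=df.index)
        out = anova_by_cluster(df, labels, variables=["density"])
        row = out.loc["density"]
        assert row["eta_squared"] == pytest.approx(1.0)
        assert np.isinf(row["F"]) and row["degenerate"]

    def test_identical_group_means_give_zero_eta(self):
        df = _profile_frame({"density": [1, 2, 3, 1, 2, 3]}, 6)
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=df.index)
        out = anova_by_cluster(df, labels, variables=["density"])
        assert out.loc["density", "eta_squared"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["density", "p"] == pytest.approx(1.0)

    def test_null_eta_squared_near_expectation(self):
        # random labels: E[eta^2] = (k-1)/(n-1) under exchangeability
        rng = np.random.default_rng(5)
        n, k, reps = 200, 4, 60
        etas = []
        for _ in range(reps):
            df = pd.DataFrame({"density": rng.normal(size=n)})
            df.index = [f"c{i}" for i in range(n)]
            labels = pd.Series(rng.integers(0, k, size=n), index=df.index)
            out = anova_by_cluster(df, labels, variables=["density"])
            etas.append(out.loc["density", "eta_squared"])
        expected = (k - 1) / (n - 1)
        se = np.std(etas, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(etas) - expected) < 4 * se

    def test_singleton_cluster_allowed(self):
        df = _profile_frame({"density": [0.0, 0.1, 0.2, 5.0]}, 4)
        labels = pd.Series([0, 0, 0, 1], index=df.index)
        out = anova_by_cluster(df, labels, variables=["density"])
        assert np.isfinite(out.loc["density", "F"])


def test_full_typology_recovers_archetypes():
    from duonet.pipeline import build_couple_networks, profiles_table
    from duonet.synthetic import generate_cohort

    records, truths = generate_cohort(120, seed=21)
    prof = profiles_table(build_couple_networks(records))
    result = run_typology(prof, k=5, seed=0)
    truth_labels = [t.archetype for t in truths]
    assert adjusted_rand_score(truth_labels, result.labels.to_numpy()) >= 0.9
    # every couple labeled exactly once; tables structurally consistent
    assert result.labels.index.equals(prof.index)
    assert result.tscores.shape == result.within_cluster_means.shape == (5, 10)
    assert (result.anova["eta_squared"] > 0.1).all()
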