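"""Signature scoring, clustering and survival analysis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ccapipe import cin


class TestCPMNormalize:
    def test_single_gene_sample(self):
        m = pd.DataFrame({"s1": [50]}, index=["g1"])
        assert cin.cpm_normalize(m).iloc[0, 0] == pytest.approx(1e6)

    def test_two_gene_split(self):
        m = pd.DataFrame({"s1": [25, 75]}, index=["g1", "g2"])
        out = cin.cpm_normalize(m)
        assert list(out["s1"]) == [pytest.approx(250000), pytest.approx(750000)]

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 1000, size=(30, 8)))
        out = cin.cpm_normalize(m)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_rejected_by_name(self):
        m = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cin.cpm_normalize(m)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cin.cpm_normalize(pd.DataFrame({"s": [-1, 2]}))


class TestSignatureScore:
    def test_identical_samples_score_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = cin.score_signature(m, ["g1", "g2"])
        assert (scores == 0).all()

    def test_two_samples_symmetric(self):
        m = pd.DataFrame({"a": [3.0], "b": [7.0]}, index=["g1"])
        scores = cin.score_signature(m, ["g1"])
        sd = np.std([3.0, 7.0], ddof=1)
        assert scores["b"] == pytest.approx((7 - 5) / sd)
        assert scores["a"] == pytest.approx(-scores["b"])
        assert scores.sum() == pytest.approx(0.0, abs=1e-12)

    def test_worked_matrix_matches_hand_oracle(self):
        m = pd.DataFrame(
            {
                "s1": [2.0, 10.0, 1.0],
                "s2": [4.0, 20.0, 5.0],
                "s3": [6.0, 15.0, 3.0],
                "s4": [8.0, 35.0, 7.0],
            },
            index=["g1", "g2", "g3"],
        )
        expected = pd.Series(0.0, index=m.columns)
        for g in m.index:  # independent per-gene mean/SD computation
            mu = m.loc[g].mean()
            sd = m.loc[g].std(ddof=1)
            expected += (m.loc[g] - mu) / sd
        scores = cin.score_signature(m, ["g1", "g2", "g3"])
        pd.testing.assert_series_equal(scores, expected, atol=1e-12, check_names=False)

    def test_scores_sum_to_zero_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.normal(size=(5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        scores = cin.score_signature(m, m.index)
        assert scores.sum() == pytest.approx(0.0, abs=1e-10)
        perm = m[rng.permutation(m.columns)]
        pd.testing.assert_series_equal(
            cin.score_signature(perm, m.index).sort_index(), scores.sort_index()
        )

    def test_empty_intersection_rejected_listing_genes(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
        with pytest.raises(ValueError, match="gX"):
            cin.score_signature(m, ["gX"])

    def test_default_signature_has_25_genes(self):
        genes = cin.default_signature()
        assert len(genes) == 25
        assert "AURKA" in genes and "FOXM1" in genes


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        blobs = []
        for center in (0.0, 20.0, 40.0):
            blobs.append(rng.normal(center, 0.5, size=(6, 10)))
        data = np.hstack(blobs)
        m = pd.DataFrame(data, index=[f"g{i}" for i in range(6)], columns=[f"s{i}" for i in range(30)])
        labels = cin.kmeans_cluster(m, m.index, k=3, seed=0, scale=False)
        truth = [0] * 10 + [1] * 10 + [2] * 10
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_k1_single_cluster(self):
        m = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 6)))
        labels = cin.kmeans_cluster(m, m.index, k=1, seed=0)
        assert set(labels) == {1}

    def test_duplicated_profiles_one_cluster_each(self):
        profiles = np.array([[0.0, 10.0, 20.0], [0.0, 10.0, 20.0]])
        m = pd.DataFrame(
            np.hstack([np.tile(profiles[:, [j]], (1, 4)) for j in range(3)]),
            index=["g1", "g2"],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = cin.kmeans_cluster(m, m.index, k=3, seed=0, scale=False)
        truth = sum([[j] * 4 for j in range(3)], [])
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_k_exceeding_samples_rejected(self):
        m = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        with pytest.raises(ValueError, match="exceeds"):
            cin.kmeans_cluster(m, m.index, k=3)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, 20)), index=[f"g{i}" for i in range(5)])
        a = cin.kmeans_cluster(m, m.index, k=3, seed=7)
        b = cin.kmeans_cluster(m, m.index, k=3, seed=7)
        pd.testing.assert_series_equal(a, b)


class TestMedianSplit:
    def test_even_cohort(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = cin.median_split(scores)
        assert list(groups) == ["low", "low", "high", "high"]

    def test_median_element_goes_low_for_odd_n(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = cin.median_split(scores)
        assert groups["b"] == "low" and groups["c"] == "high"

    def test_all_equal_all_low_with_warning(self):
        with pytest.warns(UserWarning, match="high group empty"):
            groups = cin.median_split(pd.Series([2.0, 2.0, 2.0]))
        assert (groups == "low").all()


class TestKMCurve:
    def test_no_events_flat_at_one(self):
        curve = cin.km_curve([3, 5, 7], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_two_events_no_censoring(self):
        curve = cin.km_curve([1, 2], [1, 1]).set_index("time")["survival"]
        assert curve[1.0] == pytest.approx(0.5)
        assert curve[2.0] == pytest.approx(0.0)

    def test_mixed_censoring_matches_hand_computed_table(self):
        # events at 1, 3, 5, 6; censored at 2 and 4
        # S: 5/6 = .8333, *3/4 = .625, *1/2 = .3125, *0 = 0
        curve = cin.km_curve([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1]).set_index("time")["survival"]
        assert curve[1.0] == pytest.approx(5 / 6)
        assert curve[3.0] == pytest.approx(0.625)
        assert curve[5.0] == pytest.approx(0.3125)
        assert curve[6.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40)
        curve = cin.km_curve(t, np.ones(40)).set_index("time")["survival"]
        for time in t:
            assert curve[time] == pytest.approx((t > time).mean())

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cin.km_curve([-1, 2], [1, 1])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = cin.logrank({"a": (t, e), "b": (t, e)})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cin.logrank({"a": ([1, 2], [0, 0]), "b": ([3], [0])})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            cin.logrank({"a": ([1], [1])})

    def test_chisquare_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        ta, tb = rng.exponential(10, 10), rng.exponential(18, 10)
        cen = 15.0
        ea, eb = ta <= cen, tb <= cen
        ta, tb = np.minimum(ta, cen), np.minimum(tb, cen)
        res = cin.logrank({"a": (ta, ea), "b": (tb, eb)})
        t = np.concatenate([ta, tb])
        e = np.concatenate([ea, eb])
        hits = 0
        B = 2000
        for _ in range(B):
            idx = rng.permutation(20)
            stat = cin.logrank(
                {"a": (t[idx[:10]], e[idx[:10]]), "b": (t[idx[10:]], e[idx[10:]])}
            ).statistic
            hits += stat >= res.statistic
        assert abs(res.p_value - hits / B) < 0.05

    def test_three_group_df(self):
        rng = np.random.default_rng(1)
        groups = {
            lab: (rng.exponential(s, 15), np.ones(15, bool))
            for lab, s in (("a", 5), ("b", 10), ("c", 20))
        }
        res = cin.logrank(groups)
        assert res.df == 2 and res.p_value < 0.05
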