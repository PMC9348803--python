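"""DM statistics, pairwise Spearman distances and KS comparisons, each
checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from txnoise import (
    GeneSet,
    compare_distributions,
    compute_gene_stats,
    distance_to_median,
    noise_report,
    pairwise_distances,
    select_hvg,
)
from txnoise.variability import DistanceDistribution

from conftest import make_normalized


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dm_oracle(log10_mean, log10_cv2, window):
    """Brute-force windowed median over mean-sorted genes, edge-clipped."""
    order = np.argsort(log10_mean, kind="stable")
    half = window // 2
    n = len(order)
    rolling = np.empty(n)
    for rank, idx in enumerate(order):
        lo, hi = max(0, rank - half), min(n, rank + half + 1)
        rolling[idx] = np.median(np.asarray(log10_cv2)[order[lo:hi]])
    return rolling


def spearman_oracle(x, y):
    """Rank explicitly (average ties) then apply the Pearson formula."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def ks_oracle(a, b):
    """sup |ECDF_a - ECDF_b| by explicit enumeration over pooled points."""
    pooled = np.concatenate([a, b])
    return max(
        abs(np.mean(a <= x) - np.mean(b <= x)) for x in pooled
    )


# ---------------------------------------------------------------------------
# gene stats + DM
# ---------------------------------------------------------------------------

class TestGeneStats:
    def test_cv2_matches_hand_computation(self):
        nm = make_normalized([[1, 2, 3, 4], [1, 1, 1, 1]])
        stats = compute_gene_stats(nm)
        # values [1,2,3,4]: mean 2.5, sample variance 5/3
        assert stats.loc["g0", "cv2"] == pytest.approx((5 / 3) / 6.25, abs=1e-12)
        assert stats.loc["g1", "cv2"] == 0.0

    def test_cv2_is_scale_invariant(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(5, 30))
        nm1 = make_normalized(vals)
        vals2 = vals.copy()
        vals2[2] *= 7.5
        nm2 = make_normalized(vals2)
        s1, s2 = compute_gene_stats(nm1), compute_gene_stats(nm2)
        assert s1.loc["g2", "cv2"] == pytest.approx(s2.loc["g2", "cv2"], rel=1e-12)

    def test_zero_mean_gene_is_rejected(self):
        nm = make_normalized([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero mean"):
            compute_gene_stats(nm)


class TestDistanceToMedian:
    def test_hand_worked_five_gene_example(self):
        # genes ranked by mean carry log10_cv2 [1, 3, 2, 5, 4]; window 3
        stats = pd.DataFrame(
            {
                "mean": [1.0, 2.0, 3.0, 4.0, 5.0],
                "cv2": [1.0] * 5,
                "log10_mean": [0.1, 0.2, 0.3, 0.4, 0.5],
                "log10_cv2": [1.0, 3.0, 2.0, 5.0, 4.0],
            },
            index=pd.Index(list("abcde"), name="gene"),
        )
        out = distance_to_median(stats, window=3)
        assert out["rolling_median"].tolist() == [2, 2, 3, 4, 4.5]
        assert out["dm"].tolist() == [-1, 1, -1, 1, -0.5]

    def test_identical_cv2_gives_zero_dm(self, rng):
        n = 60
        stats = pd.DataFrame(
            {
                "mean": rng.random(n) + 0.5,
                "cv2": np.ones(n),
                "log10_mean": rng.normal(size=n),
                "log10_cv2": np.full(n, 0.7),
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene"),
        )
        out = distance_to_median(stats, window=11)
        np.testing.assert_allclose(out["dm"], 0.0, atol=1e-15)

    def test_shift_invariance_of_dm(self, rng):
        n = 80
        base = pd.DataFrame(
            {
                "mean": rng.random(n) + 0.5,
                "cv2": rng.random(n),
                "log10_mean": rng.normal(size=n),
                "log10_cv2": rng.normal(size=n),
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene"),
        )
        shifted = base.copy()
        shifted["log10_cv2"] = base["log10_cv2"] + 3.7
        a = distance_to_median(base, window=21)["dm"]
        b = distance_to_median(shifted, window=21)["dm"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("window", [3, 11, 51, 199])
    def test_matches_brute_force_oracle_on_200_genes(self, rng, window):
        n = 200
        stats = pd.DataFrame(
            {
                "mean": rng.random(n) + 0.1,
                "cv2": rng.random(n) + 0.1,
                "log10_mean": rng.normal(size=n),
                "log10_cv2": rng.normal(size=n),
            },
            index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene"),
        )
        out = distance_to_median(stats, window=window)
        expected = dm_oracle(
            stats["log10_mean"].to_numpy(), stats["log10_cv2"].to_numpy(), window
        )
        np.testing.assert_allclose(out["rolling_median"], expected, atol=0)

    def test_window_larger_than_gene_count_errors(self):
        stats = pd.DataFrame(
            {
                "mean": [1.0, 2.0],
                "cv2": [1.0, 1.0],
                "log10_mean": [0.0, 0.3],
                "log10_cv2": [0.0, 0.0],
            },
            index=pd.Index(["a", "b"], name="gene"),
        )
        with pytest.raises(ValueError, match="smaller window"):
            distance_to_median(stats, window=3)


class TestSelectHvg:
    def _stats(self, dm, genes):
        return pd.DataFrame(
            {"dm": dm}, index=pd.Index(genes, name="gene")
        )

    def test_top_n_by_dm(self):
        stats = self._stats([0.1, 0.9, 0.5, 0.7], list("abcd"))
        assert select_hvg(stats, n=2).members == {"b", "d"}

    def test_tie_at_cutoff_prefers_lexicographic(self):
        stats = self._stats([0.9, 0.5, 0.5, 0.1], ["w", "z", "a", "b"])
        assert select_hvg(stats, n=2).members == {"w", "a"}

    def test_n_equal_to_total_returns_all(self):
        stats = self._stats([0.1, 0.2], ["a", "b"])
        assert select_hvg(stats, n=2).members == {"a", "b"}

    def test_n_beyond_total_warns_and_returns_all(self):
        stats = self._stats([0.1, 0.2], ["a", "b"])
        with pytest.warns(UserWarning, match="returning all"):
            gs = select_hvg(stats, n=5)
        assert gs.members == {"a", "b"}


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

class TestPairwiseDistances:
    def test_monotone_transform_gives_distance_zero(self):
        x = np.array([0.2, 1.4, 0.9, 2.2, 3.0, 0.1])
        nm = make_normalized(np.vstack([x, np.exp(x)]))
        dd = pairwise_distances(nm, ["g0", "g1"])
        assert dd.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_reverse_ranking_gives_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        nm = make_normalized(np.vstack([x, x[::-1]]))
        dd = pairwise_distances(nm, ["g0", "g1"])
        assert dd.distances[0] == pytest.approx(2.0, abs=1e-12)

    def test_pair_count_formula(self, rng):
        k = 40
        nm = make_normalized(rng.random((k, 10)) + 0.01)
        dd = pairwise_distances(nm, [f"g{i}" for i in range(k)])
        assert len(dd) == k * (k - 1) // 2

    def test_matches_rank_then_pearson_oracle(self, rng):
        # 4 genes x 6 cells with ties included
        vals = np.array(
            [
                [0.0, 1.0, 1.0, 2.0, 3.0, 0.0],
                [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
                [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
                [0.0, 2.0, 0.0, 4.0, 1.0, 5.0],
            ]
        )
        nm = make_normalized(vals)
        genes = ["g0", "g1", "g2", "g3"]
        dd = pairwise_distances(nm, genes)
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                expected.append(1.0 - spearman_oracle(vals[i], vals[j]))
        np.testing.assert_allclose(np.sort(dd.distances), np.sort(expected), atol=1e-12)

    def test_spearman_invariant_under_increasing_transforms(self, rng):
        vals = rng.random((5, 25))
        nm1 = make_normalized(vals)
        transformed = np.vstack(
            [np.exp(vals[0]), vals[1] ** 3 + 1, 2 * vals[2], vals[3], np.sqrt(vals[4])]
        )
        nm2 = make_normalized(transformed)
        genes = [f"g{i}" for i in range(5)]
        d1 = pairwise_distances(nm1, genes).distances
        d2 = pairwise_distances(nm2, genes).distances
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_constant_gene_dropped_with_warning(self, rng):
        vals = rng.random((3, 12))
        vals[1, :] = 0.5
        nm = make_normalized(vals)
        with pytest.warns(UserWarning, match="constant"):
            dd = pairwise_distances(nm, ["g0", "g1", "g2"])
        assert dd.n_genes == 2
        assert len(dd) == 1

    def test_abs_rho_convention_halves_range(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        nm = make_normalized(np.vstack([x, x[::-1]]))
        dd = pairwise_distances(nm, ["g0", "g1"], distance="1-abs-rho")
        assert dd.distances[0] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------

class TestCompareDistributions:
    def test_identical_samples_give_zero_statistic_p_one(self):
        a = np.array([0.3, 0.5, 0.9, 1.2])
        res = compare_distributions(a, a.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports_give_statistic_one(self):
        res = compare_distributions(np.array([0.1, 0.2]), np.array([1.5, 1.9]))
        assert res.statistic == 1.0

    def test_hand_worked_one_third(self):
        res = compare_distributions(
            np.array([0.1, 0.2, 0.3]), np.array([0.2, 0.3, 0.4])
        )
        assert res.statistic == pytest.approx(1 / 3, abs=1e-15)

    def test_matches_pooled_ecdf_oracle(self, rng):
        a = rng.normal(size=400)
        b = rng.normal(0.15, 1.1, size=600)
        res = compare_distributions(a, b)
        assert res.statistic == pytest.approx(ks_oracle(a, b), abs=1e-12)
        assert res.n_a == 400 and res.n_b == 600

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            compare_distributions(np.array([]), np.array([0.1]))

    def test_one_sided_alternative_orientation(self, rng):
        small = rng.random(300)
        large = small + 0.5
        up = compare_distributions(large, small, alternative="greater")
        down = compare_distributions(large, small, alternative="less")
        assert up.p_value < 1e-6
        assert down.p_value > 0.5


# ---------------------------------------------------------------------------
# grouped report
# ---------------------------------------------------------------------------

class TestNoiseReport:
    def test_duplicated_group_compares_as_identical(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(120, 40))
        nm = make_normalized(vals)
        groups = {"a": np.arange(40), "b": np.arange(40)}
        rep = noise_report(nm, groups, hvg_n=30, window=11)
        row = rep.comparisons.iloc[0]
        assert row["ks_statistic"] == 0.0
        assert row["p_value"] == 1.0

    def test_fixed_gene_set_policy_ignores_dm(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(50, 30))
        nm = make_normalized(vals)
        groups = {"a": np.arange(15), "b": np.arange(15, 30)}
        gs = GeneSet("fixed", frozenset(f"g{i}" for i in range(10)))
        rep = noise_report(nm, groups, gene_set=gs, window=11)
        for dd in rep.distributions.values():
            assert dd.n_genes == 10
            assert dd.gene_desc == "fixed"

    def test_small_group_excluded_with_warning(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(40, 21))
        nm = make_normalized(vals)
        groups = {
            "a": np.arange(10),
            "b": np.arange(10, 20),
            "tiny": np.array([20]),
        }
        with pytest.warns(UserWarning, match="excluded"):
            rep = noise_report(nm, groups, hvg_n=20, window=11)
        assert set(rep.distributions) == {"a", "b"}

    def test_single_group_is_error(self, rng):
        nm = make_normalized(rng.random((30, 10)))
        with pytest.raises(ValueError, match="2 groups"):
            noise_report(nm, {"only": np.arange(10)})


def test_distance_distribution_validates_pair_count():
    with pytest.raises(ValueError, match="pair distances"):
        DistanceDistribution(np.array([0.5, 0.5]), "g", "x", 3)
    with pytest.raises(ValueError, match=r"\[0, 2\]"):
        DistanceDistribution(np.array([0.5, 0.5, 2.5]), "g", "x", 3)
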