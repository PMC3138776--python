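"""MPD/MNTD metrics, permutation nulls, and the exact enumeration oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ethnophylo as ep
from ethnophylo.signal import MetricUndefinedError, NullModelConfig


def brute_force_metric(sample, dmat, metric):
    """Independent oracle: metrics by explicit pair enumeration."""
    labels = sorted(sample)
    if metric == "mpd":
        pairs = list(itertools.combinations(labels, 2))
        return sum(dmat.loc[a, b] for a, b in pairs) / len(pairs)
    total = 0.0
    for a in labels:
        total += min(dmat.loc[a, b] for b in labels if b != a)
    return total / len(labels)


class TestMetrics:
    def test_pair_sample_equals_pairwise_distance(self, three_tip_dmat):
        assert ep.mpd(["A", "B"], three_tip_dmat) == pytest.approx(2.0)
        assert ep.mntd(["A", "B"], three_tip_dmat) == pytest.approx(2.0)

    def test_three_tip_hand_values(self, three_tip_dmat):
        assert ep.mpd(["A", "B", "C"], three_tip_dmat) == pytest.approx(10 / 3)
        assert ep.mntd(["A", "B", "C"], three_tip_dmat) == pytest.approx(8 / 3)

    def test_singleton_and_unknown_tip_errors(self, three_tip_dmat):
        with pytest.raises(MetricUndefinedError):
            ep.mpd(["A"], three_tip_dmat)
        with pytest.raises(ValueError, match="Z"):
            ep.mntd(["A", "Z"], three_tip_dmat)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8))
    def test_mntd_le_mpd_and_matches_brute_force(self, seed, n):
        tree = ep.simulate_yule_tree(12, seed=seed)
        dmat = tree.patristic_matrix()
        rng = np.random.default_rng(seed + 1)
        sample = list(rng.choice(tree.tip_labels, size=n, replace=False))
        m1, m2 = ep.mpd(sample, dmat), ep.mntd(sample, dmat)
        assert m2 <= m1 + 1e-12
        assert m1 == pytest.approx(brute_force_metric(sample, dmat, "mpd"))
        assert m2 == pytest.approx(brute_force_metric(sample, dmat, "mntd"))


class TestNullDistribution:
    def test_degenerate_full_pool(self, three_tip_dmat):
        cfg = NullModelConfig(runs=25, seed=1)
        null = ep.null_distribution("mpd", 3, three_tip_dmat, cfg)
        np.testing.assert_allclose(null, 10 / 3)

    def test_reproducible_for_fixed_seed(self, caterpillar5_dmat):
        cfg = NullModelConfig(runs=100, seed=7)
        a = ep.null_distribution("mntd", 3, caterpillar5_dmat, cfg)
        b = ep.null_distribution("mntd", 3, caterpillar5_dmat, cfg)
        np.testing.assert_array_equal(a, b)

    def test_null_mpd_mean_matches_pool_average(self):
        # E[MPD of a uniform pair sample] = mean of all pairwise distances
        tree = ep.simulate_yule_tree(15, seed=3)
        dmat = tree.patristic_matrix()
        D = dmat.to_numpy()
        pool_mean = D[np.triu_indices_from(D, k=1)].mean()
        cfg = NullModelConfig(runs=20_000, seed=3)
        null = ep.null_distribution("mpd", 2, dmat, cfg)
        se = null.std(ddof=1) / math.sqrt(len(null))
        assert abs(null.mean() - pool_mean) < 4 * se

    def test_invalid_sizes(self, three_tip_dmat):
        cfg = NullModelConfig(runs=10, seed=0)
        with pytest.raises(ValueError):
            ep.null_distribution("mpd", 4, three_tip_dmat, cfg)
        with pytest.raises(ValueError):
            ep.null_distribution("mpd", 1, three_tip_dmat, cfg)


class TestExactOracle:
    def test_caterpillar_sister_pair_is_unique_minimum(self, caterpillar5_dmat):
        assert ep.exact_signal_p(["A", "B"], caterpillar5_dmat, "mpd") == pytest.approx(1 / 10)

    def test_full_pool_p_is_one(self, caterpillar5_dmat):
        tips = list(caterpillar5_dmat.index)
        assert ep.exact_signal_p(tips, caterpillar5_dmat, "mpd") == pytest.approx(1.0)

    def test_enumeration_cap(self, caterpillar5_dmat):
        with pytest.raises(ValueError, match="cap"):
            ep.exact_signal_p(["A", "B"], caterpillar5_dmat, "mpd", cap=5)

    @pytest.mark.parametrize("metric", ["mpd", "mntd"])
    def test_permutation_converges_to_exact(self, metric):
        # permutation estimate within 3 MC standard errors of enumeration
        tree = ep.simulate_yule_tree(12, seed=11)
        dmat = tree.patristic_matrix()
        rng = np.random.default_rng(5)
        sample = list(rng.choice(tree.tip_labels, size=4, replace=False))
        exact = ep.exact_signal_p(sample, dmat, metric)
        R = 20_000
        cfg = NullModelConfig(runs=R, seed=2)
        null = ep.null_distribution(metric, 4, dmat, cfg)
        obs = (ep.mpd if metric == "mpd" else ep.mntd)(sample, dmat)
        k = int(np.count_nonzero(null <= obs + 1e-12))
        p_hat = (k + 1) / (R + 1)
        se = math.sqrt(exact * (1 - exact) / R)
        assert abs(p_hat - exact) <= 3 * se + 1 / R


class TestSignalTest:
    def _matrix(self, samples):
        taxa = sorted({t for s in samples.values() for t in s})
        mat = pd.DataFrame(0, index=list(samples), columns=taxa, dtype=int)
        for name, tips in samples.items():
            mat.loc[name, list(tips)] = 1
        return mat

    def test_table_shape_and_skipping(self, caterpillar5):
        mat = self._matrix({"pair": {"A", "B"}, "solo": {"E"}, "trio": {"A", "B", "C"}})
        with pytest.warns(UserWarning, match="solo"):
            out = ep.signal_test(mat, caterpillar5, NullModelConfig(runs=99, seed=0))
        assert sorted(out.index) == ["pair", "trio"]
        assert (out["p_mpd"] > 0).all() and (out["p_mpd"] <= 1).all()
        assert (out["mntd_obs"] <= out["mpd_obs"] + 1e-12).all()

    def test_no_usable_sample_errors(self, caterpillar5):
        mat = self._matrix({"solo": {"E"}})
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            ep.signal_test(mat, caterpillar5, NullModelConfig(runs=9, seed=0))

    def test_relabeling_invariance(self):
        # permuting tip names consistently in tree and matrix leaves p unchanged
        tree = ep.simulate_yule_tree(10, seed=21)
        labels = tree.tip_labels
        mapping = dict(zip(labels, labels[::-1]))
        tree2 = ep.parse_newick(tree.to_newick(precision=17))
        for leaf in tree2._tree.leaf_node_iter():
            leaf.taxon.label = "tmp_" + mapping[leaf.taxon.label]
        for leaf in tree2._tree.leaf_node_iter():
            leaf.taxon.label = leaf.taxon.label[4:]
        tree2._refresh_index()
        sample = labels[:4]
        mat1 = self._matrix({"s": set(sample)})
        mat2 = self._matrix({"s": {mapping[t] for t in sample}})
        cfg = NullModelConfig(runs=499, seed=9)
        out1 = ep.signal_test(mat1, tree, cfg)
        out2 = ep.signal_test(mat2, tree2, cfg)
        assert out1.loc["s", "p_mpd"] == out2.loc["s", "p_mpd"]
        assert out1.loc["s", "p_mntd"] == out2.loc["s", "p_mntd"]

    def test_scale_invariance(self, caterpillar5):
        mat = self._matrix({"pair": {"A", "B"}, "trio": {"A", "C", "E"}})
        cfg = NullModelConfig(runs=199, seed=4)
        out1 = ep.signal_test(mat, caterpillar5, cfg)
        scaled = ep.parse_newick(
            "((((A:10,B:10):10,C:20):10,D:30):10,E:40);"
        )
        out2 = ep.signal_test(mat, scaled, cfg)
        for col in ("p_mpd", "p_mntd", "ses_mpd", "ses_mntd"):
            np.testing.assert_allclose(out1[col], out2[col], rtol=1e-9)

    def test_ses_sign_positive_for_clumped_sample(self, caterpillar5):
        # sister pair is maximally clumped: SES should be positive
        mat = self._matrix({"pair": {"A", "B"}})
        out = ep.signal_test(mat, caterpillar5, NullModelConfig(runs=999, seed=0))
        assert out.loc["pair", "ses_mpd"] > 0

    def test_bh_column_monotone(self, caterpillar5):
        mat = self._matrix({"a": {"A", "B"}, "b": {"A", "E"}, "c": {"C", "D"}})
        out = ep.signal_test(
            mat, caterpillar5, NullModelConfig(runs=199, seed=1), bh_correction=True
        )
        assert (out["p_mpd_bh"] >= out["p_mpd"] - 1e-12).all()
        assert (out["p_mpd_bh"] <= 1.0).all()
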