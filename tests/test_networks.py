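"""Correlation network machinery: edge statistics against independent
oracles, filter semantics, closure artifacts, and network comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylloload import (
    FeatureTable,
    build_network,
    compare_networks,
    pearson_edge,
    permutation_pvalue,
    prevalence_filter,
    total_sum_scale,
)
from phylloload.networks import NetworkError


def make_table(values, taxa=None, mode="clr"):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    return FeatureTable(
        pd.DataFrame(values, index=taxa,
                     columns=[f"s{j}" for j in range(values.shape[1])]),
        mode,
    )


class TestPearsonEdge:
    def test_perfect_positive_linearity(self):
        x = np.arange(5.0)
        e = pearson_edge(x, 2 * x)
        assert e.r == 1.0 and e.p == 0.0

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        e = pearson_edge(x, -x)
        assert e.r == -1.0 and e.p == 0.0

    def test_t_and_p_at_r_08_n_10(self):
        """r = 0.8 at n = 10 gives t = 3.7712 and p = 0.005456 (frozen from
        the t(8) distribution)."""
        # construct a pair with sample r exactly 0.8: orthogonal design
        x = np.array([1.0, -1.0] * 5)
        z = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, -1.0])  # orthogonal to x
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x  # exact orthogonalization
        y = 0.8 * x / np.linalg.norm(x) + 0.6 * z / np.linalg.norm(z)
        e = pearson_edge(x, y)
        assert e.r == pytest.approx(0.8, abs=1e-12)
        assert e.t_stat == pytest.approx(3.7712361663, abs=1e-9)
        assert e.p == pytest.approx(0.005456, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 20))
        e = pearson_edge(x, y)
        ref = stats.pearsonr(x, y)
        assert e.r == pytest.approx(ref.statistic, abs=1e-12)
        assert e.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 15))
        a = pearson_edge(x, y)
        b = pearson_edge(y, x)
        assert a.r == b.r and a.p == b.p

    def test_constant_vector_rejected(self):
        with pytest.raises(NetworkError, match="constant"):
            pearson_edge(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(NetworkError, match="at least 3"):
            pearson_edge(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestTwoTaxonClosure:
    @pytest.mark.parametrize("seed", range(5))
    def test_closure_forces_perfect_anticorrelation(self, seed):
        """Any two-taxon table closed by TSS yields r = -1 exactly."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.5, 100, size=(2, 12))
        rel = total_sum_scale(make_table(vals, mode="raw_counts"))
        e = pearson_edge(rel.values[0], rel.values[1])
        assert e.r == pytest.approx(-1.0, abs=1e-12)


class TestPrevalenceFilter:
    def make_boundary_table(self, n_hits):
        row = [1000] * n_hits + [999] * (15 - n_hits)
        other = [2000] * 15
        return make_table([row, other], ["edge", "bulk"], mode="raw_counts")

    def test_boundary_inclusive(self):
        kept = prevalence_filter(self.make_boundary_table(10), 1000, 10)
        assert "edge" in kept

    def test_below_boundary_dropped(self):
        kept = prevalence_filter(self.make_boundary_table(9), 1000, 10)
        assert "edge" not in kept and "bulk" in kept

    def test_zero_thresholds_keep_everything(self):
        t = self.make_boundary_table(0)
        assert prevalence_filter(t, 0, 0) == ["edge", "bulk"]


class TestBuildNetwork:
    def test_filter_conjunction(self):
        """Edges need BOTH r2 >= threshold and p < alpha."""
        rng = np.random.default_rng(1)
        n = 60
        z = rng.standard_normal(n)
        strong = z + 0.3 * rng.standard_normal(n)  # high r2, tiny p
        weak = z + 2.5 * rng.standard_normal(n)  # low r2
        table = make_table([z, strong, weak], ["z", "strong", "weak"])
        net = build_network(table, r2_min=0.2, alpha=0.05)
        assert net.find_edge("z", "strong") is not None
        assert net.find_edge("z", "weak") is None

    def test_all_pairs_scored(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.standard_normal((6, 30)))
        net = build_network(table, r2_min=0.0, alpha=1.01)
        assert len(net.edges) == 6 * 5 // 2

    def test_fewer_than_two_taxa_rejected(self):
        table = make_table(np.ones((3, 4)) + np.arange(4))
        with pytest.raises(NetworkError, match="at least 2"):
            build_network(table, taxa=["T0"])

    def test_constant_taxon_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        vals = np.vstack([np.full(20, 7.0), rng.standard_normal((2, 20))])
        with caplog.at_level("WARNING", logger="phylloload"):
            net = build_network(make_table(vals), r2_min=0.0, alpha=1.01)
        assert all("T0" not in (e.taxon_a, e.taxon_b) for e in net.edges)
        assert any("constant" in r.message for r in caplog.records)

    def test_node_ranks_follow_mean_abundance(self):
        vals = np.array([[1.0, 1.0, 1.0], [5.0, 6.0, 7.0], [2.0, 2.5, 3.0]])
        net = build_network(make_table(vals), r2_min=0.0, alpha=1.01)
        assert net.node_rank["T1"] == 1
        assert net.node_rank["T2"] == 2
        assert net.node_rank["T0"] == 3

    def test_threshold_on_r_option(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(50)
        partner = z + 2.2 * rng.standard_normal(50)
        table = make_table([z, partner])
        e = pearson_edge(table.values[0], table.values[1])
        assert 0.2 < abs(e.r) < np.sqrt(0.2)  # between the two semantics
        on_r2 = build_network(table, r2_min=0.2, alpha=0.05, threshold_on="r2")
        on_r = build_network(table, r2_min=0.2, alpha=0.05, threshold_on="r")
        assert len(on_r2.edges) == 0 and len(on_r.edges) == 1


class TestCompareNetworks:
    def build_pair(self, r_sign=1.0):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(40)
        a = make_table([z, z + 0.2 * rng.standard_normal(40)])
        b = make_table([z, r_sign * z + 0.2 * rng.standard_normal(40)])
        return build_network(a), build_network(b)

    def test_identical_networks(self):
        net, _ = self.build_pair()
        cmp = compare_networks(net, net)
        assert cmp.sign_flipped == 0 and cmp.jaccard == 1.0
        assert cmp.lost == cmp.gained == 0

    def test_sign_flip_detected(self):
        net_a, net_b = self.build_pair(r_sign=-1.0)
        cmp = compare_networks(net_a, net_b)
        assert cmp.sign_flipped == 1 and cmp.retained == 1

    def test_mismatched_universe_rejected(self):
        net_a, _ = self.build_pair()
        rng = np.random.default_rng(6)
        other = build_network(make_table(rng.standard_normal((2, 40)),
                                         taxa=["X", "Y"]))
        with pytest.raises(NetworkError, match="universes differ"):
            compare_networks(net_a, other)


class TestPermutationPvalue:
    def test_extreme_statistic_minimal_p(self):
        # n = 12 makes re-drawing the identity/reversal permutation
        # vanishingly unlikely, so only the +1 smoothing remains
        x = np.arange(12.0)
        p = permutation_pvalue(x, x, n_perm=500, seed=0)
        assert p <= 2 / 501

    def test_agrees_with_student_t(self):
        """Permutation oracle and t(n-2) p-values agree within Monte-Carlo
        error on random n = 12 vectors."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            x, y = rng.standard_normal((2, 12))
            e = pearson_edge(x, y)
            p_perm = permutation_pvalue(x, y, n_perm=4000, seed=rng)
            se = np.sqrt(e.p * (1 - e.p) / 4000)
            assert abs(p_perm - e.p) < 4 * se + 1e-3

    def test_uniform_under_null(self):
        """Under independence the permutation p-value is uniform (KS test
        over replicates)."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            x, y = rng.standard_normal((2, 10))
            pvals.append(permutation_pvalue(x, y, n_perm=300, seed=rng))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        with pytest.raises(NetworkError, match="n_perm"):
            permutation_pvalue(np.arange(5.0), np.arange(5.0), n_perm=10)
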