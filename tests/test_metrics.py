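"""UniFrac family and Bray-Curtis: worked values, oracles, metric axioms."""

import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_instance
from unifracx import synthdata
from unifracx.metrics import (
    METRICS,
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    information_unifrac,
    information_weight,
    ratio_unifrac,
    unweighted_unifrac,
    weighted_unifrac,
)
from unifracx.tables import replace_zeros, to_proportions
from unifracx.treekit import parse_newick


class TestInformationWeight:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 0.0)])
    def test_pinned_values(self, p, expected):
        assert information_weight(p) == pytest.approx(expected, abs=1e-12)

    def test_maximum_at_one_over_e(self):
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda p: -information_weight(p), bounds=(1e-6, 1 - 1e-6),
                              method="bounded", options={"xatol": 1e-12})
        assert res.x == pytest.approx(1 / np.e, abs=1e-9)
        assert information_weight(1 / np.e) == pytest.approx(np.log2(np.e) / np.e, abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            information_weight(p)

    def test_steeper_than_identity_at_low_abundance(self, rng):
        """Surprisal weighting amplifies small-abundance differences: the
        curve sits above the identity on (0, 0.2], and its increments beat
        the raw proportion increments throughout the low-abundance regime
        (the derivative -log2(p) - log2(e) stays above 1 up to
        p = 2**-(1+log2 e) ~ 0.184)."""
        p_curve = rng.uniform(1e-4, 0.2, size=200)
        assert np.all(information_weight(p_curve) > p_curve)
        hi = 2.0 ** (-(1.0 + np.log2(np.e)))
        q = rng.uniform(1e-4, hi, size=200)
        p = q + rng.uniform(1e-6, hi, size=200)
        mask = p <= hi
        q, p = q[mask], p[mask]
        assert mask.sum() > 50
        assert np.all(information_weight(p) - information_weight(q) > p - q)


class TestPairwiseWorkedValues:
    def test_unweighted_boundary_cases(self):
        for tree, a, b, expected in synthdata.make_boundary_cases():
            assert unweighted_unifrac(tree, a, b) == expected

    def test_weighted_identical_profiles_zero(self):
        t = parse_newick("((A:1,B:2):1,C:1);")
        p = pd.Series({"A": 0.2, "B": 0.3, "C": 0.5})
        assert weighted_unifrac(t, p, p) == 0.0

    def test_weighted_two_leaf_swap_is_one(self):
        t = parse_newick("(A:1,B:1);")
        a = pd.Series({"A": 1.0, "B": 0.0})
        b = pd.Series({"A": 0.0, "B": 1.0})
        assert weighted_unifrac(t, a, b) == pytest.approx(1.0)

    def test_weighted_depends_only_on_proportion_difference(self):
        """A 0.005 vs 0.010 change weighs the same as 0.095 vs 0.100."""
        t = parse_newick("(X:1,Y:1);")
        d_low = weighted_unifrac(
            t, pd.Series({"X": 0.005, "Y": 0.995}), pd.Series({"X": 0.010, "Y": 0.990})
        )
        d_high = weighted_unifrac(
            t, pd.Series({"X": 0.095, "Y": 0.905}), pd.Series({"X": 0.100, "Y": 0.900})
        )
        assert d_low == pytest.approx(d_high, abs=1e-12)

    def test_information_two_leaf_hand_value(self):
        t = parse_newick("(A:1,B:1);")
        a = pd.Series({"A": 0.5, "B": 0.5})
        b = pd.Series({"A": 1.0, "B": 0.0})
        assert information_unifrac(t, a, b) == pytest.approx(0.5)

    def test_information_blind_to_distinct_monocultures(self):
        """Two pure monocultures transform to zero surprisal everywhere."""
        t = parse_newick("(A:1,B:1);")
        a = pd.Series({"A": 1.0, "B": 0.0})
        b = pd.Series({"A": 0.0, "B": 1.0})
        assert information_unifrac(t, a, b) == 0.0

    def test_ratio_identical_profiles_zero(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        p = pd.Series({"A": 0.25, "B": 0.35, "C": 0.4})
        assert ratio_unifrac(t, p, p) == 0.0

    def test_ratio_uniform_composition_zero(self):
        """Equal parts: every collapsed geometric mean equals each part."""
        t = parse_newick("((A:1,B:1):1,C:2);")
        u = pd.Series({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3})
        a = pd.Series({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3})
        lengths_sum = t.total_length
        assert lengths_sum > 0
        # internal branch mass 2/3 vs gm of (2/3, 1/3): nonzero centred mass,
        # but equal in both samples -> every contribution cancels
        assert ratio_unifrac(t, u, a) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_symmetry_random(self, rng):
        t = synthdata.random_tree(8, 3)
        pa = pd.Series(rng.dirichlet(np.ones(8)), index=list(t.leaf_names))
        pb = pd.Series(rng.dirichlet(np.ones(8)), index=list(t.leaf_names))
        assert ratio_unifrac(t, pa, pb) == pytest.approx(ratio_unifrac(t, pb, pa))

    def test_ratio_requires_positive_proportions(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="zero replacement"):
            ratio_unifrac(t, pd.Series({"A": 1.0, "B": 0.0}), pd.Series({"A": 0.5, "B": 0.5}))

    def test_bray_curtis_worked_values(self):
        same = pd.Series({"X": 4, "Y": 1})
        assert bray_curtis(same, same) == 0.0
        assert bray_curtis(pd.Series({"X": 3, "Y": 0}), pd.Series({"X": 0, "Y": 7})) == 1.0
        assert bray_curtis(pd.Series({"X": 6, "Y": 2}), pd.Series({"X": 2, "Y": 2})) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            unweighted_unifrac(t, pd.Series({"A": 0, "B": 0}), pd.Series({"A": 1, "B": 0}))
        with pytest.raises(ValueError):
            bray_curtis(pd.Series({"X": 0}), pd.Series({"X": 1}))


class TestOracleEquivalence:
    """Vectorized implementations vs naive set-enumeration references."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_unifrac_flavours_match_brute_force(self, seed):
        tree, table = random_instance(seed)
        nwk = tree.to_newick()
        ca = table.iloc[0].to_dict()
        cb = table.iloc[1].to_dict()
        assert unweighted_unifrac(tree, table.iloc[0], table.iloc[1]) == pytest.approx(
            oracles.unweighted(nwk, ca, cb), abs=1e-10
        )
        pa, pb = to_proportions(table).iloc[0], to_proportions(table).iloc[1]
        assert weighted_unifrac(tree, pa, pb) == pytest.approx(
            oracles.weighted(nwk, ca, cb), abs=1e-10
        )
        assert information_unifrac(tree, pa, pb) == pytest.approx(
            oracles.information(nwk, ca, cb), abs=1e-10
        )
        pos = replace_zeros(table)
        assert ratio_unifrac(tree, pos.iloc[0], pos.iloc[1]) == pytest.approx(
            oracles.ratio(nwk, pos.iloc[0].to_dict(), pos.iloc[1].to_dict()), abs=1e-10
        )
        assert bray_curtis(table.iloc[0], table.iloc[1]) == pytest.approx(
            oracles.bray_curtis(ca, cb), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scikit_bio(self, seed):
        """Unweighted equals skbio's; weighted equals skbio's raw earth-mover
        divided by total branch length (this package's normalization)."""
        from io import StringIO

        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        tree, table = random_instance(seed + 100, n_samples=4)
        names = list(table.columns)
        sk_tree = TreeNode.read(StringIO(tree.to_newick()))
        sk_u = beta_diversity("unweighted_unifrac", table.to_numpy(),
                              ids=list(table.index), tree=sk_tree, taxa=names)
        mine_u = distance_matrix(tree, table, "unweighted", rarefy=False)
        assert np.allclose(sk_u.data, mine_u.data, atol=1e-10)
        sk_w = beta_diversity("weighted_unifrac", table.to_numpy(),
                              ids=list(table.index), tree=sk_tree, taxa=names)
        mine_w = distance_matrix(tree, table, "weighted", rarefy=False)
        assert np.allclose(sk_w.data / tree.total_length, mine_w.data, atol=1e-10)


class TestDistanceMatrix:
    def test_single_sample_zero_matrix(self):
        t = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"A": [3], "B": [1]}, index=["only"])
        dm = distance_matrix(t, table, "weighted")
        assert dm.shape == (1, 1) and dm.data[0, 0] == 0.0

    @pytest.mark.parametrize("metric", METRICS)
    def test_sample_permutation_consistency(self, metric):
        tree, table = random_instance(13, n_samples=4)
        dm = distance_matrix(tree, table, metric, rarefy=False, seed=1)
        shuffled = table.iloc[[2, 0, 3, 1]]
        dm2 = distance_matrix(tree, shuffled, metric, rarefy=False, seed=1)
        assert np.allclose(dm2.reorder(dm.ids).data, dm.data, atol=1e-12)

    def test_matrix_entries_equal_pairwise_calls(self):
        tree, table = random_instance(21, n_samples=5)
        dm = distance_matrix(tree, table, "unweighted", rarefy=False)
        for i, j in itertools.combinations(range(5), 2):
            direct = unweighted_unifrac(tree, table.iloc[i], table.iloc[j])
            assert dm.data[i, j] == pytest.approx(direct, abs=1e-12)

    def test_rarefaction_default_only_for_unweighted(self):
        tree, table = random_instance(31, n_samples=3)
        table = table * 3  # unequal totals
        dm_w1 = distance_matrix(tree, table, "weighted", seed=1)
        dm_w2 = distance_matrix(tree, table, "weighted", seed=2)
        assert np.allclose(dm_w1.data, dm_w2.data)  # no resampling involved
        dm_u1 = distance_matrix(tree, table, "unweighted", seed=1)
        dm_u1b = distance_matrix(tree, table, "unweighted", seed=1)
        assert np.allclose(dm_u1.data, dm_u1b.data)  # seeded, reproducible

    def test_unknown_otu_label_rejected(self):
        t = parse_newick("(A:1,B:1);")
        table = pd.DataFrame({"A": [1], "C": [2]}, index=["s"])
        with pytest.raises(KeyError, match="C"):
            distance_matrix(t, table, "unweighted")

    def test_symmetry_and_zero_diagonal_flags(self):
        tree, table = random_instance(41, n_samples=4)
        for metric in METRICS:
            dm = distance_matrix(tree, table, metric, rarefy=False)
            assert np.allclose(dm.data, dm.data.T)
            assert np.all(np.diag(dm.data) == 0)
            assert np.all(dm.data >= 0)
        assert distance_matrix(tree, table, "unweighted", rarefy=False).is_metric
        assert not distance_matrix(tree, table, "ratio", rarefy=False).is_metric

    def test_tsv_round_trip(self, tmp_path):
        tree, table = random_instance(51, n_samples=3)
        dm = distance_matrix(tree, table, "weighted", rarefy=False)
        p = tmp_path / "dm.tsv"
        dm.write_tsv(p)
        back = DistanceMatrix.read_tsv(p, metric="weighted")
        assert back.ids == dm.ids
        assert np.allclose(back.data, dm.data, atol=1e-9)


def _triangle_holds(d: np.ndarray, tol: float = 1e-9) -> bool:
    n = d.shape[0]
    for i, j, k in itertools.permutations(range(n), 3):
        if d[i, j] > d[i, k] + d[k, j] + tol:
            return False
    return True


class TestMetricAxioms:
    @pytest.mark.parametrize("metric", ["unweighted", "weighted"])
    def test_triangle_inequality_without_pruning(self, metric):
        for seed in range(40):
            tree, table = random_instance(seed, n_samples=3)
            dm = distance_matrix(tree, table, metric, rarefy=False)
            assert _triangle_holds(dm.data), f"seed {seed}"

    def test_pruning_breaks_weighted_triangle_inequality(self):
        """Per-pair tree pruning shrinks each pair's denominator differently,
        so a sample pair with disjoint two-leaf support can reach distance 1
        while a heavy out-group taxon keeps the other two pairs cheap."""
        tree = parse_newick("((X:1,Y:1):1,Z:10);")
        table = pd.DataFrame(
            {"X": [1, 49, 0], "Y": [0, 49, 1], "Z": [0, 2, 0]},
            index=["A", "B", "C"],
        )
        dm = distance_matrix(tree, table, "weighted", prune=True, rarefy=False)
        assert not dm.is_metric and dm.pruned
        assert dm[("A", "C")] > dm[("A", "B")] + dm[("B", "C")] + 0.5
        # the same data without pruning respects the triangle inequality
        dm0 = distance_matrix(tree, table, "weighted", prune=False, rarefy=False)
        assert _triangle_holds(dm0.data)
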