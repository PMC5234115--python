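"""UniFrac against independent oracles, metric properties, group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import TreeNode

from microtrace.data_io import OtuTable, OtuTableError
from microtrace.phylo_distance import (
    TreeIndex,
    delay_distance_profile,
    group_compare,
    unifrac_matrix,
    unweighted_unifrac,
    weighted_unifrac,
)
from microtrace.synthetic_household import random_coalescent_tree


# -- independent oracle: explicit per-branch leaf-set summation -------------

def _branches(tree: TreeNode):
    """(length, leaf name set) per non-root branch, by naive recursion."""
    out = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        out.append((float(node.length or 0.0), leaves))
    return out


def oracle_unweighted(a: dict, b: dict, tree: TreeNode) -> float:
    pres_a = {k for k, v in a.items() if v > 0}
    pres_b = {k for k, v in b.items() if v > 0}
    num = den = 0.0
    for length, leaves in _branches(tree):
        in_a = bool(leaves & pres_a)
        in_b = bool(leaves & pres_b)
        num += length * (in_a != in_b)
        den += length * (in_a or in_b)
    return num / den if den else 0.0


def oracle_weighted(a: dict, b: dict, tree: TreeNode, normalized=False) -> float:
    ta, tb = sum(a.values()), sum(b.values())
    num = den = 0.0
    for length, leaves in _branches(tree):
        pa = sum(a.get(k, 0.0) for k in leaves) / ta
        pb = sum(b.get(k, 0.0) for k in leaves) / tb
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den if normalized else num


def _random_instance(rng, n_leaves):
    names = [f"L{i}" for i in range(n_leaves)]
    tree = random_coalescent_tree(names, rng)
    a = {n: float(rng.integers(0, 5)) for n in names}
    b = {n: float(rng.integers(0, 5)) for n in names}
    if sum(a.values()) == 0:
        a[names[0]] = 1.0
    if sum(b.values()) == 0:
        b[names[-1]] = 1.0
    return names, tree, a, b


class TestUnifracOracle:
    def test_identical_samples_distance_zero(self):
        rng = np.random.default_rng(0)
        names, tree, a, _ = _random_instance(rng, 12)
        va = pd.Series(a)
        assert unweighted_unifrac(va, va, tree) == pytest.approx(0.0, abs=1e-12)
        assert weighted_unifrac(va, va, tree) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_two_leaf_tree_distance_one(self):
        tree = TreeNode.read(["(A:1.0,B:2.0):0;"])
        a = pd.Series({"A": 3.0, "B": 0.0})
        b = pd.Series({"A": 0.0, "B": 1.0})
        assert unweighted_unifrac(a, b, tree) == pytest.approx(1.0)

    def test_star_tree_weighted_is_scaled_l1(self):
        # all leaves at depth l: d_w = l * sum |p_a - p_b|
        length = 2.5
        tree = TreeNode.read([f"(A:{length},B:{length},C:{length}):0;"])
        a = pd.Series({"A": 2.0, "B": 1.0, "C": 1.0})
        b = pd.Series({"A": 0.0, "B": 1.0, "C": 3.0})
        pa, pb = a / a.sum(), b / b.sum()
        expected = length * np.abs(pa - pb).sum()
        assert weighted_unifrac(a, b, tree) == pytest.approx(expected)

    def test_agrees_with_branch_summation_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n = int(rng.integers(3, 17))
            _, tree, a, b = _random_instance(rng, n)
            va, vb = pd.Series(a), pd.Series(b)
            assert unweighted_unifrac(va, vb, tree) == pytest.approx(
                oracle_unweighted(a, b, tree), abs=1e-10
            )
            assert weighted_unifrac(va, vb, tree) == pytest.approx(
                oracle_weighted(a, b, tree), abs=1e-10
            )
            assert weighted_unifrac(va, vb, tree, normalized=True) == pytest.approx(
                oracle_weighted(a, b, tree, normalized=True), abs=1e-10
            )

    def test_agrees_with_scikit_bio(self):
        # cross-check against an established implementation
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(7)
        names = [f"L{i}" for i in range(10)]
        tree = random_coalescent_tree(names, rng)
        counts = rng.integers(0, 6, size=(4, 10))
        counts[counts.sum(axis=1) == 0, 0] = 1
        ids = [f"s{i}" for i in range(4)]
        for metric in ("unweighted_unifrac", "weighted_unifrac"):
            ref = beta_diversity(metric, counts, ids=ids, taxa=names, tree=tree)
            table = OtuTable(pd.DataFrame(counts, index=ids, columns=names))
            ours = unifrac_matrix(table, tree, metric=metric.split("_")[0])
            np.testing.assert_allclose(
                ours.to_numpy(), ref.data, atol=1e-10
            )

    def test_missing_leaf_raises_naming_otu(self):
        tree = TreeNode.read(["(A:1,B:1):0;"])
        a = pd.Series({"A": 1.0, "ghost": 2.0})
        b = pd.Series({"B": 1.0})
        with pytest.raises(OtuTableError, match="ghost"):
            unweighted_unifrac(a, b, tree)


class TestMetricProperties:
    def test_unweighted_satisfies_triangle_inequality(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            names, tree, a, b = _random_instance(rng, 10)
            c = {n: float(rng.integers(0, 3)) for n in names}
            if sum(c.values()) == 0:
                c[names[0]] = 1.0
            va, vb, vc = pd.Series(a), pd.Series(b), pd.Series(c)
            dab = unweighted_unifrac(va, vb, tree)
            dbc = unweighted_unifrac(vb, vc, tree)
            dac = unweighted_unifrac(va, vc, tree)
            assert dac <= dab + dbc + 1e-12
            assert dab == pytest.approx(unweighted_unifrac(vb, va, tree), abs=1e-12)

    def test_branch_scaling_behaviour(self):
        rng = np.random.default_rng(5)
        names, tree, a, b = _random_instance(rng, 8)
        va, vb = pd.Series(a), pd.Series(b)
        raw = weighted_unifrac(va, vb, tree)
        norm = weighted_unifrac(va, vb, tree, normalized=True)
        for node in tree.traverse(include_self=False):
            node.length *= 3.0
        assert weighted_unifrac(va, vb, tree) == pytest.approx(3.0 * raw, rel=1e-10)
        assert weighted_unifrac(va, vb, tree, normalized=True) == pytest.approx(
            norm, rel=1e-10
        )


class TestDelayProfile:
    def _toy(self):
        # 2 residences x 2 seasons, one skin and one surface sample each
        meta = pd.DataFrame(
            {
                "type": ["skin", "skin", "surface", "surface"] * 2,
                "residence": ["R1"] * 4 + ["R2"] * 4,
                "site": ["palm", "palm", "desk", "desk"] * 2,
                "individual": ["R1a", "R1a", None, None, "R2a", "R2a", None, None],
                "season": [1, 2, 1, 2] * 2,
            },
            index=[f"s{i}" for i in range(8)],
        )
        ids = meta.index
        dm = pd.DataFrame(np.zeros((8, 8)), index=ids, columns=ids)
        vals = {}
        k = 1
        for i, j in itertools.combinations(range(8), 2):
            dm.iloc[i, j] = dm.iloc[j, i] = k
            vals[(i, j)] = k
            k += 1
        return dm, meta, vals

    def test_toy_means_match_hand_calculation(self):
        dm, meta, vals = self._toy()
        prof = delay_distance_profile(dm, meta)

        def v(i, j):
            return vals[(min(i, j), max(i, j))]

        # delay 0 pairs: R1 (skin s0/surface s2, skin s1/surface s3),
        #                R2 (skin s4/surface s6, skin s5/surface s7)
        expected0 = np.mean([v(0, 2), v(1, 3), v(4, 6), v(5, 7)])
        expected_plus = np.mean([v(0, 3), v(4, 7)])
        expected_minus = np.mean([v(1, 2), v(5, 6)])
        assert prof.loc[0, "mean"] == pytest.approx(expected0)
        assert prof.loc[1, "mean"] == pytest.approx(expected_plus)
        assert prof.loc[-1, "mean"] == pytest.approx(expected_minus)
        assert prof.loc[0, "n_pairs"] == 4

    def test_single_season_only_delay_zero(self):
        dm, meta, _ = self._toy()
        season1 = meta[meta["season"] == 1]
        prof = delay_distance_profile(dm.loc[season1.index, season1.index], season1)
        assert list(prof.index) == [0]


class TestGroupCompare:
    def test_identical_large_groups_non_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        stat, p = group_compare({"a": x, "b": x.copy()}, "mann_whitney")
        assert p > 0.9

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(10, 1, 50)}
        _, p = group_compare(groups, "mann_whitney")
        assert p < 1e-6
        _, p_kw = group_compare(groups, "kruskal_wallis")
        assert p_kw < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(OtuTableError, match="empty"):
            group_compare({"a": [1.0], "b": []})

    def test_asymptotic_p_close_to_exact_permutation(self):
        # exhaustive enumeration of all C(10,5) label assignments
        rng = np.random.default_rng(3)
        pooled = rng.normal(0, 1, 10)
        pooled[:5] += 1.2
        x, y = pooled[:5], pooled[5:]

        def u_stat(a, b):
            return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

        observed = u_stat(x, y)
        n = len(pooled)
        count = total = 0
        for idx in itertools.combinations(range(n), 5):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            u = u_stat(pooled[sel], pooled[~sel])
            # two-sided: as or more extreme in either direction
            if abs(u - 12.5) >= abs(observed - 12.5) - 1e-12:
                count += 1
            total += 1
        exact_p = count / total
        _, asym_p = group_compare({"a": x, "b": y}, "mann_whitney")
        assert abs(asym_p - exact_p) < 0.1
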