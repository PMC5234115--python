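"""Weighted and unweighted UniFrac and delay-resolved distance profiles.

UniFrac measures dissimilarity between two communities as the fraction of
phylogenetic branch length unique to one of them.  The unweighted form
compares branch *presence*:

    d_u(A, B) = sum_b l_b |1[A under b] - 1[B under b]|
                / sum_b l_b 1[A or B under b]

where a sample is "under" branch b when the subtree below b contains a
leaf at which the sample has positive abundance.  The weighted form
compares abundance mass:

    d_w(A, B) = sum_b l_b |p_A(b) - p_B(b)|

with p_X(b) the fraction of X's reads on leaves below b; the normalized
variant divides by sum_b l_b (p_A(b) + p_B(b)).  The raw (non-normalized)
weighted form is the default.

Distances are computed on a single post-order indexing of the tree so a
full distance matrix reuses one traversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from microtrace.data_io import OtuTable, OtuTableError

__all__ = [
    "TreeIndex",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "delay_distance_profile",
    "group_compare",
]


@dataclass
class TreeIndex:
    """Post-order array form of a rooted tree for fast branch sums.

    ``parent[i]`` is the post-order position of node i's parent
    (root's parent is -1), ``lengths[i]`` its branch length (root 0),
    ``leaf_positions`` the positions of the leaves in ``leaf_names``
    order.
    """

    leaf_names: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    leaf_positions: np.ndarray

    @classmethod
    def build(cls, tree: TreeNode) -> "TreeIndex":
        nodes = list(tree.postorder(include_self=True))
        pos = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        leaf_names: list[str] = []
        leaf_positions: list[int] = []
        for i, node in enumerate(nodes):
            if node.parent is not None:
                parent[i] = pos[id(node.parent)]
                lengths[i] = float(node.length or 0.0)
            if node.is_tip():
                leaf_names.append(node.name)
                leaf_positions.append(i)
        if len(set(leaf_names)) != len(leaf_names):
            raise OtuTableError("tree has duplicate leaf labels")
        return cls(leaf_names, parent, lengths, np.asarray(leaf_positions))

    def node_mass(self, abundances: np.ndarray) -> np.ndarray:
        """Per-node subtree mass for one or more samples.

        ``abundances`` has shape (..., n_leaves) in ``leaf_names`` order;
        returns shape (..., n_nodes) by accumulating children into
        parents in post-order.
        """
        out = np.zeros(abundances.shape[:-1] + (len(self.parent),))
        out[..., self.leaf_positions] = abundances
        for i in range(len(self.parent) - 1):  # root (last) excluded
            out[..., self.parent[i]] += out[..., i]
        return out


def _align(vec, tree_index: TreeIndex) -> np.ndarray:
    if isinstance(vec, pd.Series):
        missing = [o for o in vec.index if o not in set(tree_index.leaf_names) and vec[o] > 0]
        if missing:
            raise OtuTableError(f"OTU {missing[0]!r} is not a leaf of the tree")
        return vec.reindex(tree_index.leaf_names, fill_value=0.0).to_numpy(dtype=float)
    arr = np.asarray(vec, dtype=float)
    if arr.shape[-1] != len(tree_index.leaf_names):
        raise OtuTableError("abundance vector length does not match tree leaves")
    return arr


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex.build(tree)


def unweighted_unifrac(a, b, tree) -> float:
    """Unweighted UniFrac between two presence/abundance vectors.

    Vectors may be ``pandas.Series`` indexed by OTU id or arrays in the
    tree's leaf order; any positive entry marks presence.
    """
    ti = _as_index(tree)
    av, bv = _align(a, ti), _align(b, ti)
    if av.sum() <= 0 or bv.sum() <= 0:
        raise OtuTableError("UniFrac requires at least one positive entry per sample")
    under_a = ti.node_mass(av) > 0
    under_b = ti.node_mass(bv) > 0
    lengths = ti.lengths
    unique = (lengths * (under_a ^ under_b)).sum()
    total = (lengths * (under_a | under_b)).sum()
    return float(unique / total) if total > 0 else 0.0


def weighted_unifrac(a, b, tree, normalized: bool = False) -> float:
    """Weighted UniFrac between two abundance vectors (raw by default)."""
    ti = _as_index(tree)
    av, bv = _align(a, ti), _align(b, ti)
    if av.sum() <= 0 or bv.sum() <= 0:
        raise OtuTableError("UniFrac requires at least one positive entry per sample")
    pa = ti.node_mass(av / av.sum())
    pb = ti.node_mass(bv / bv.sum())
    num = (ti.lengths * np.abs(pa - pb)).sum()
    if not normalized:
        return float(num)
    den = (ti.lengths * (pa + pb)).sum()
    return float(num / den) if den > 0 else 0.0


def unifrac_matrix(
    table: OtuTable,
    tree,
    metric: str = "weighted",
    normalized: bool = False,
) -> pd.DataFrame:
    """All-pairs UniFrac distance matrix for the samples of a table.

    Samples with zero total are dropped.  Returns a symmetric DataFrame
    with zero diagonal.
    """
    if metric not in ("weighted", "unweighted"):
        raise OtuTableError(f"unknown metric {metric!r}")
    ti = _as_index(tree)
    totals = table.data.sum(axis=1)
    ids = [s for s in table.sample_ids if totals[s] > 0]
    mat = table.data.loc[ids]
    missing = [o for o in mat.columns if o not in set(ti.leaf_names) and mat[o].sum() > 0]
    if missing:
        raise OtuTableError(f"OTU {missing[0]!r} is not a leaf of the tree")
    aligned = (
        mat.T.reindex(ti.leaf_names, fill_value=0.0).T.to_numpy(dtype=float)
    )
    lengths = ti.lengths
    n = len(ids)
    out = np.zeros((n, n))
    if metric == "unweighted":
        under = ti.node_mass(aligned) > 0
        for i in range(n):
            sym = lengths * (under[i] ^ under[i + 1 :])
            both = lengths * (under[i] | under[i + 1 :])
            tot = both.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(tot > 0, sym.sum(axis=1) / tot, 0.0)
            out[i, i + 1 :] = d
    else:
        props = aligned / aligned.sum(axis=1, keepdims=True)
        mass = ti.node_mass(props)
        for i in range(n):
            diff = (lengths * np.abs(mass[i] - mass[i + 1 :])).sum(axis=1)
            if normalized:
                den = (lengths * (mass[i] + mass[i + 1 :])).sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    diff = np.where(den > 0, diff / den, 0.0)
            out[i, i + 1 :] = diff
    out = out + out.T
    return pd.DataFrame(out, index=ids, columns=ids)


def delay_distance_profile(dm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of within-residence skin<->surface distances per sampling delay.

    Sampling delay = surface season - skin season: positive when the
    surface was sampled after the skin.  All pairwise combinations of one
    skin and one surface sample from the same residence are aggregated.
    Delays with no pairs are absent from the result (not reported as 0).
    """
    present = [s for s in dm.index if s in meta.index]
    sub = meta.loc[present]
    skin = sub[sub["type"] == "skin"]
    surface = sub[sub["type"] == "surface"]
    records: dict[int, list[float]] = {}
    for res, skin_grp in skin.groupby("residence"):
        surf_grp = surface[surface["residence"] == res]
        if surf_grp.empty:
            continue
        block = dm.loc[skin_grp.index, surf_grp.index].to_numpy()
        skin_seasons = skin_grp["season"].to_numpy(dtype=int)
        surf_seasons = surf_grp["season"].to_numpy(dtype=int)
        delays = surf_seasons[None, :] - skin_seasons[:, None]
        for d in np.unique(delays):
            records.setdefault(int(d), []).extend(block[delays == d].tolist())
    rows = {
        d: {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n_pairs": len(v),
        }
        for d, v in sorted(records.items())
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "delay"
    return out


def group_compare(groups: dict[str, np.ndarray], test: str = "mann_whitney"):
    """Rank-based comparison of value groups.

    ``mann_whitney`` requires exactly two groups (two-sided, normal
    approximation with tie correction); ``kruskal_wallis`` accepts two or
    more.  Returns ``(statistic, p_value)``.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise OtuTableError("group comparison needs at least two groups")
    for name, arr in arrays.items():
        if arr.size == 0:
            raise OtuTableError(f"group {name!r} is empty")
    if test == "mann_whitney":
        if len(arrays) != 2:
            raise OtuTableError("mann_whitney requires exactly two groups")
        g1, g2 = arrays.values()
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    elif test == "kruskal_wallis":
        res = stats.kruskal(*arrays.values())
    else:
        raise OtuTableError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
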