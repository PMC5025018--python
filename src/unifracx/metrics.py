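"""Pairwise beta-diversity metrics on (tree, count table) inputs.

Five dissimilarities, all sharing the branch-centric machinery of
:mod:`unifracx.treekit`:

``unweighted``
    branch length unique to one sample / branch length covered by either,
    on presence/absence of OTUs per branch. A true metric on a fixed tree.
``weighted``
    sum over branches of ``b_i * |pA_i - pB_i|`` divided by the total
    branch length, where ``p_i`` is a sample's branch mass (subtree
    proportional abundance). A scaled L1 distance on branch-mass vectors.
``information``
    same L1 form but on Shannon-surprisal-transformed masses
    ``-p * log2(p)`` — sensitive to mid-abundance taxa, blind to both
    abundance extremes.
``ratio``
    same L1 form on masses divided by a per-branch geometric mean of the
    collapsed composition (the branch's subtree merged into one part plus
    every outside leaf separately). Accentuates taxa far above baseline;
    requires strictly positive (zero-replaced) proportions. A
    dissimilarity, not a distance.
``braycurtis``
    1 - 2 * sum(min) / (sum A + sum B) on raw counts; tree-free.

Tree pruning (per-pair reduction of the tree to the union of the pair's
taxa, as done by QIIME/GUniFrac) is available but off by default: pruned
weighted UniFrac violates the triangle inequality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from . import tables as _tables
from .treekit import PhyloTree

__all__ = [
    "METRICS",
    "DistanceMatrix",
    "information_weight",
    "unweighted_unifrac",
    "weighted_unifrac",
    "information_unifrac",
    "ratio_unifrac",
    "bray_curtis",
    "distance_matrix",
]

METRICS = ("unweighted", "weighted", "information", "ratio", "braycurtis")

#: metrics that satisfy all metric axioms on an un-pruned tree
_TRUE_METRICS = frozenset({"unweighted", "weighted"})


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample labels.

    ``is_metric`` records whether the configuration is guaranteed to
    satisfy the triangle inequality (pruning or a ratio/information/
    Bray-Curtis weighting forfeits the guarantee).
    """

    ids: tuple[str, ...]
    data: np.ndarray
    metric: str
    pruned: bool = False
    is_metric: bool = True

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("data must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "data", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.data[i, j])

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.data, ids=list(self.ids))

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return replace(self, ids=tuple(ids), data=self.data[np.ix_(idx, idx)])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def read_tsv(cls, path: Union[str, Path], metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(ids=tuple(df.columns.astype(str)), data=df.to_numpy(), metric=metric,
                   is_metric=metric in _TRUE_METRICS)


# ---------------------------------------------------------------------------
# elementary weights


def information_weight(p):
    """Shannon surprisal weight ``-p * log2(p)`` in bits.

    Zero at both abundance extremes (p=0 and p=1, with the p=0 limit taken
    as 0) and maximal at p = 1/e, where it equals log2(e)/e.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    if out.ndim == 0:
        return float(out)
    return out


def _as_leaf_vector(tree: PhyloTree, values) -> np.ndarray:
    if isinstance(values, np.ndarray):
        return np.asarray(values, dtype=float)
    return tree.leaf_vector(values)


def _presence_profile(tree: PhyloTree, counts) -> np.ndarray:
    vec = _as_leaf_vector(tree, counts)
    if not np.any(vec > 0):
        raise ValueError("sample has no positive counts")
    _, incidence, _ = tree.branch_structure()
    return (incidence @ (vec > 0)) > 0


def _mass_profile(tree: PhyloTree, props) -> np.ndarray:
    vec = _as_leaf_vector(tree, props)
    return tree.branch_mass(vec)


# ---------------------------------------------------------------------------
# pairwise metrics


def unweighted_unifrac(tree: PhyloTree, counts_a, counts_b) -> float:
    """Fraction of covered branch length not shared by the two samples.

    A branch belongs to a sample when at least one OTU in the leaves below
    it has a non-zero count. Returns (symmetric difference) / (union) of
    branch length; 0 for identical taxon sets, 1 for samples sharing no
    branch.
    """
    lengths, _, _ = tree.branch_structure()
    in_a = _presence_profile(tree, counts_a)
    in_b = _presence_profile(tree, counts_b)
    union = float(lengths[in_a | in_b].sum())
    if union == 0:
        return 0.0
    unshared = float(lengths[in_a ^ in_b].sum())
    return unshared / union


def weighted_unifrac(tree: PhyloTree, props_a, props_b) -> float:
    """Branch-length-weighted L1 distance between branch-mass profiles,
    normalized by the tree's total branch length."""
    lengths, _, _ = tree.branch_structure()
    total = lengths.sum()
    if total == 0:
        return 0.0
    ma = _mass_profile(tree, props_a)
    mb = _mass_profile(tree, props_b)
    return float((lengths * np.abs(ma - mb)).sum() / total)


def information_unifrac(tree: PhyloTree, props_a, props_b) -> float:
    """Weighted UniFrac on surprisal-transformed branch masses.

    Each branch mass p is replaced by ``-p * log2(p)`` (0 log 0 := 0)
    before taking branch-length-weighted absolute differences; normalized
    by total branch length.
    """
    lengths, _, _ = tree.branch_structure()
    total = lengths.sum()
    if total == 0:
        return 0.0
    ia = information_weight(_mass_profile(tree, props_a))
    ib = information_weight(_mass_profile(tree, props_b))
    return float((lengths * np.abs(ia - ib)).sum() / total)


def _ratio_profile(tree: PhyloTree, props) -> np.ndarray:
    """Per-branch mass divided by the geometric mean of the collapsed
    composition (subtree merged into one part + each outside leaf)."""
    vec = _as_leaf_vector(tree, props)
    if np.any(vec <= 0):
        raise ValueError(
            "ratio UniFrac needs strictly positive proportions on every tree "
            "leaf; run zero replacement (tables.replace_zeros) first"
        )
    _, incidence, _ = tree.branch_structure()
    n_leaves = vec.size
    mass = incidence @ vec
    logp = np.log(vec)
    sub_logsum = incidence @ logp
    sub_size = incidence @ np.ones(n_leaves)
    total_logsum = logp.sum()
    n_parts = 1.0 + (n_leaves - sub_size)
    log_gm = (np.log(mass) + (total_logsum - sub_logsum)) / n_parts
    return mass / np.exp(log_gm)


def ratio_unifrac(tree: PhyloTree, props_a, props_b) -> float:
    """Weighted UniFrac on geometric-mean-centred branch masses.

    For each branch, the sample's composition is collapsed (the branch's
    whole subtree becomes a single part; every leaf outside it stays a
    separate part), and the branch mass is divided by the geometric mean
    of that collapsed composition. Differences of these centred masses are
    branch-length weighted and normalized by total branch length. Not a
    distance — the triangle inequality can fail.
    """
    lengths, _, _ = tree.branch_structure()
    total = lengths.sum()
    if total == 0:
        return 0.0
    ra = _ratio_profile(tree, props_a)
    rb = _ratio_profile(tree, props_b)
    return float((lengths * np.abs(ra - rb)).sum() / total)


def bray_curtis(counts_a, counts_b) -> float:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min)/(S_A + S_B)`` on counts.

    0 for identical count vectors, 1 for samples sharing no species.
    """
    a = np.asarray(pd.Series(counts_a), dtype=float)
    b = np.asarray(pd.Series(counts_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same species set")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("each sample needs at least one positive count")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / (sa + sb))


# ---------------------------------------------------------------------------
# all-pairs matrices


def _profiles_matrix(tree: PhyloTree, table: pd.DataFrame, kind: str,
                     props: pd.DataFrame | None = None) -> np.ndarray:
    """samples x branches profile matrix for the vectorized paths."""
    lengths, incidence, leaf_index = tree.branch_structure()
    cols = list(table.columns)
    order = [leaf_index[c] for c in cols]
    n_leaves = len(leaf_index)

    def expand(mat: np.ndarray) -> np.ndarray:
        full = np.zeros((mat.shape[0], n_leaves))
        full[:, order] = mat
        return full

    if kind == "presence":
        pres = expand((table.to_numpy() > 0).astype(float))
        return (incidence @ pres.T).T > 0
    p = expand(props.to_numpy())
    mass = (incidence @ p.T).T
    if kind == "mass":
        return mass
    if kind == "information":
        return information_weight(mass)
    if kind == "ratio":
        if p.shape[1] != len(cols):
            raise ValueError(
                "ratio UniFrac requires every tree leaf to appear in the "
                "table (strictly positive after zero replacement)"
            )
        return np.vstack([_ratio_profile(tree, row) for row in p])
    raise ValueError(kind)


def _check_labels(tree: PhyloTree, table: pd.DataFrame) -> None:
    missing = sorted(set(table.columns) - set(tree.leaf_names))
    if missing:
        raise KeyError(
            f"{len(missing)} table OTU(s) missing from the tree: "
            + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        )


def distance_matrix(
    tree: PhyloTree | None,
    table: pd.DataFrame,
    metric: str,
    *,
    prune: bool = False,
    rarefy: bool | None = None,
    depth: int | None = None,
    seed: int = 0,
    zero_method: str = "bayesian",
    pseudocount: float = 0.5,
) -> DistanceMatrix:
    """All pairwise dissimilarities of one metric for a count table.

    ``rarefy=None`` applies the field default: rarefaction (to ``depth``,
    or the minimum sample total) before unweighted UniFrac only, since the
    presence/absence weighting assumes a common sequencing depth; the
    abundance-weighted metrics use the table as given. Pass ``True`` /
    ``False`` to force either behavior for any metric.

    With ``prune=True`` the tree is reduced, for every pair, to the union
    of the pair's observed taxa and proportions are recomputed on the
    pruned leaf set (QIIME/GUniFrac behavior); the result is then flagged
    as a dissimilarity (``is_metric=False``).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    _tables.validate_count_table(table)
    if metric != "braycurtis":
        if tree is None:
            raise ValueError("tree required for UniFrac metrics")
        _check_labels(tree, table)

    if rarefy is None:
        rarefy = metric == "unweighted"
    work = table
    if rarefy:
        d = int(table.sum(axis=1).min()) if depth is None else int(depth)
        work = _tables.rarefy(table, d, seed)

    ids = tuple(str(s) for s in work.index)
    n = len(ids)
    is_metric = metric in _TRUE_METRICS and not prune

    if metric == "braycurtis":
        counts = work.to_numpy(dtype=float)
        if np.any(counts.sum(axis=1) == 0):
            raise ValueError("sample with no positive counts")
        sums = counts.sum(axis=1)
        mins = np.minimum(counts[:, None, :], counts[None, :, :]).sum(axis=2)
        data = 1.0 - 2.0 * mins / (sums[:, None] + sums[None, :])
        np.fill_diagonal(data, 0.0)
        data = (data + data.T) / 2.0
        return DistanceMatrix(ids, data, metric, pruned=False, is_metric=False)

    if prune:
        data = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            data[i, j] = data[j, i] = _pairwise_pruned(
                tree, work.iloc[i], work.iloc[j], metric,
                zero_method=zero_method, pseudocount=pseudocount,
            )
        return DistanceMatrix(ids, data, metric, pruned=True, is_metric=False)

    lengths, _, _ = tree.branch_structure()
    total = lengths.sum()
    if metric == "unweighted":
        profiles = _profiles_matrix(tree, work, "presence").astype(float)
        weighted_profiles = profiles * lengths
        covered = weighted_profiles.sum(axis=1)
        cross = profiles @ (profiles * lengths).T  # shared branch length
        union = covered[:, None] + covered[None, :] - cross
        unshared = union - cross
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.where(union > 0, unshared / union, 0.0)
    else:
        if metric == "ratio":
            props = _tables.replace_zeros(work, method=zero_method, pseudocount=pseudocount)
        else:
            props = _tables.to_proportions(work)
        profiles = _profiles_matrix(tree, work, {"weighted": "mass"}.get(metric, metric), props)
        if total == 0:
            data = np.zeros((n, n))
        else:
            data = squareform(pdist(profiles * lengths, metric="cityblock")) / total
    np.fill_diagonal(data, 0.0)
    data = (data + data.T) / 2.0
    return DistanceMatrix(ids, data, metric, pruned=False, is_metric=is_metric)


def _pairwise_pruned(tree: PhyloTree, counts_a: pd.Series, counts_b: pd.Series,
                     metric: str, *, zero_method: str, pseudocount: float) -> float:
    """One pruned-tree pairwise value: tree sheared to the pair's union
    taxa, proportions recomputed on the pruned leaf set."""
    taxa = set(counts_a[counts_a > 0].index) | set(counts_b[counts_b > 0].index)
    sub = tree.prune_to_taxa(taxa)
    keep = sorted(taxa)
    pair = pd.DataFrame([counts_a[keep], counts_b[keep]], index=["_a", "_b"])
    if metric == "unweighted":
        return unweighted_unifrac(sub, pair.loc["_a"], pair.loc["_b"])
    if metric == "ratio":
        props = _tables.replace_zeros(pair, method=zero_method, pseudocount=pseudocount)
    else:
        props = _tables.to_proportions(pair)
    fn = {"weighted": weighted_unifrac, "information": information_unifrac,
          "ratio": ratio_unifrac}[metric]
    return fn(sub, props.loc["_a"], props.loc["_b"])
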