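"""Phylogenetic tree handling for UniFrac-style metrics.

A :class:`PhyloTree` wraps a rooted :class:`skbio.TreeNode` and exposes the
branch-centric view the UniFrac family needs: every non-root node owns the
branch (edge) leading to its parent, and each branch subtends a set of leaf
OTUs. Sample abundances are propagated onto branches as "branch mass": the
sum of the proportional abundances of all OTUs below the branch.

The root carries no branch; all branch sums run over non-root edges only.
Zero-length branches are retained (they contribute 0 to every sum).
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from skbio import TreeNode
from skbio.io import NewickFormatError, UnrecognizedFormatError

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "midpoint_root",
    "branch_mass",
    "prune_to_taxa",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input (unbalanced parentheses,
    duplicate leaf labels, empty string)."""


class PhyloTree:
    """Rooted phylogenetic tree whose leaves are OTU identifiers.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree. Branch lengths of ``None`` are coerced to 0.0 with a
        warning; negative lengths raise.

    Notes
    -----
    The branch structure (lengths, branch-by-leaf incidence) is computed
    lazily and cached; a PhyloTree is treated as immutable after
    construction.
    """

    def __init__(self, tree: TreeNode):
        self._tree = tree
        self._validate()
        self._branch_cache: tuple | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        if not text or not text.strip():
            raise NewickParseError("empty Newick string")
        try:
            tree = TreeNode.read(io.StringIO(text), format="newick")
        except (NewickFormatError, UnrecognizedFormatError, ValueError) as exc:
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue()

    def _validate(self) -> None:
        seen: set[str] = set()
        n_missing = 0
        for node in self._tree.postorder():
            if node.is_tip():
                if not node.name:
                    raise NewickParseError("leaf with empty label")
                if node.name in seen:
                    raise NewickParseError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)
            if node.is_root():
                node.length = None
                continue
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.length} at {node.name!r}"
                )
        if n_missing:
            warnings.warn(
                f"{n_missing} branch(es) had no length; set to 0.0",
                stacklevel=3,
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def skbio_tree(self) -> TreeNode:
        return self._tree

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(tip.name for tip in self._tree.tips())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.tips())

    @property
    def total_length(self) -> float:
        return float(sum(n.length for n in self._tree.postorder() if not n.is_root()))

    @property
    def n_branches(self) -> int:
        return sum(1 for n in self._tree.postorder() if not n.is_root())

    def leaf_distances(self) -> pd.DataFrame:
        """All pairwise leaf-to-leaf path lengths (tree distance matrix)."""
        dm = self._tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.copy())

    def summary(self) -> str:
        return (
            f"PhyloTree: {self.n_leaves} leaves, {self.n_branches} branches, "
            f"total length {self.total_length:.6g}"
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.summary()}>"

    # -- branch structure --------------------------------------------------

    def branch_structure(self):
        """Return ``(lengths, incidence, leaf_index)``.

        ``lengths``
            1-D float array, one entry per non-root branch (postorder).
        ``incidence``
            CSR boolean matrix, branches x leaves; entry (i, j) is True when
            leaf j lies in the subtree below branch i.
        ``leaf_index``
            dict mapping leaf name -> column index.
        """
        if self._branch_cache is None:
            leaves = self.leaf_names
            leaf_index = {name: j for j, name in enumerate(leaves)}
            lengths: list[float] = []
            rows: list[int] = []
            cols: list[int] = []
            below: dict[int, list[int]] = {}
            i = 0
            for node in self._tree.postorder():
                if node.is_tip():
                    node_leaves = [leaf_index[node.name]]
                else:
                    node_leaves = []
                    for child in node.children:
                        node_leaves.extend(below.pop(id(child)))
                below[id(node)] = node_leaves
                if node.is_root():
                    continue
                lengths.append(node.length)
                rows.extend([i] * len(node_leaves))
                cols.extend(node_leaves)
                i += 1
            incidence = sparse.csr_matrix(
                (np.ones(len(rows), dtype=bool), (rows, cols)),
                shape=(i, len(leaves)),
            )
            self._branch_cache = (np.asarray(lengths, dtype=float), incidence, leaf_index)
        return self._branch_cache

    def leaf_vector(self, values: Mapping[str, float] | pd.Series) -> np.ndarray:
        """Align a per-OTU mapping to this tree's leaf order.

        OTUs absent from the tree raise; tree leaves absent from ``values``
        get 0.
        """
        if isinstance(values, pd.Series):
            values = values.to_dict()
        _, _, leaf_index = self.branch_structure()
        missing = sorted(k for k in values if k not in leaf_index)
        if missing:
            raise KeyError(
                f"{len(missing)} OTU(s) not found among tree leaves: "
                + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else "")
            )
        vec = np.zeros(len(leaf_index))
        for name, v in values.items():
            vec[leaf_index[name]] = v
        return vec

    # -- operations --------------------------------------------------------

    def midpoint_root(self) -> "PhyloTree":
        """Re-root at the midpoint of the longest leaf-to-leaf path.

        Total branch length is conserved. Raises ``ValueError`` when every
        branch has zero length (the midpoint is undefined) or the tree has
        fewer than two leaves.
        """
        if self.n_leaves < 2:
            raise ValueError("midpoint rooting needs at least two leaves")
        if self.total_length <= 0:
            raise ValueError("midpoint undefined: all branch lengths are zero")
        if self.n_leaves == 2:
            # skbio's root_at_midpoint degenerates on two-leaf trees; the
            # midpoint of the single path is placed directly.
            a, b = self._tree.tips()
            half = (a.distance(b)) / 2.0
            return PhyloTree.from_newick(f"({a.name}:{half:.12g},{b.name}:{half:.12g});")
        rooted = self._tree.copy().root_at_midpoint()
        return PhyloTree(rooted)

    def prune_to_taxa(self, taxa: Iterable[str]) -> "PhyloTree":
        """Keep only the given leaves; collapse degree-2 nodes, summing lengths.

        Pairwise path lengths among the retained leaves are preserved.
        """
        taxa = set(taxa)
        present = taxa & set(self.leaf_names)
        if not present:
            raise ValueError("no requested taxa are leaves of this tree")
        sheared = self._tree.shear(sorted(present))
        return PhyloTree(sheared)

    def branch_mass(
        self,
        proportions: Mapping[str, float] | pd.Series | np.ndarray,
        *,
        check_sum: bool = True,
    ) -> np.ndarray:
        """Propagate one sample's OTU proportions onto branches.

        Each branch's mass is the sum of proportions of the leaves in its
        subtree. ``proportions`` may be a mapping / Series keyed by OTU id
        or an array already aligned to ``leaf_names``. Proportions must sum
        to 1 (within 1e-6) or be all zero.
        """
        lengths, incidence, leaf_index = self.branch_structure()
        if isinstance(proportions, np.ndarray):
            vec = np.asarray(proportions, dtype=float)
            if vec.shape != (len(leaf_index),):
                raise ValueError(
                    f"expected array of length {len(leaf_index)}, got {vec.shape}"
                )
        else:
            vec = self.leaf_vector(proportions)
        if np.any(vec < 0):
            raise ValueError("proportions must be non-negative")
        total = vec.sum()
        if check_sum and total > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}, expected 1 (or all zero)")
        return incidence @ vec


# ---------------------------------------------------------------------------
# functional surface


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Midpoint-root ``tree`` (see :meth:`PhyloTree.midpoint_root`)."""
    return tree.midpoint_root()


def branch_mass(
    tree: PhyloTree, proportions: Mapping[str, float] | pd.Series | np.ndarray
) -> np.ndarray:
    """Per-branch subtree mass for one sample (see :meth:`PhyloTree.branch_mass`)."""
    return tree.branch_mass(proportions)


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Prune ``tree`` to the given leaves (see :meth:`PhyloTree.prune_to_taxa`)."""
    return tree.prune_to_taxa(taxa)
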