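"""Independent brute-force reference implementations.

Deliberately naive: trees are re-parsed with dendropy (not the package's
tree stack), subtree leaf sets are enumerated explicitly per edge, and
every formula is evaluated with plain Python loops and ``math``. Used only
to cross-check the package's vectorized implementations.
"""

from __future__ import annotations

import math

import dendropy


def edges_with_leafsets(newick: str):
    """[(branch_length, frozenset(leaf labels below))] for every non-root edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append((float(length), leaves))
    return out


def unweighted(newick: str, counts_a: dict, counts_b: dict) -> float:
    present_a = {k for k, v in counts_a.items() if v > 0}
    present_b = {k for k, v in counts_b.items() if v > 0}
    unshared = union = 0.0
    for length, leaves in edges_with_leafsets(newick):
        in_a = bool(leaves & present_a)
        in_b = bool(leaves & present_b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unshared += length
    return unshared / union if union else 0.0


def _props(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def weighted(newick: str, counts_a: dict, counts_b: dict) -> float:
    pa, pb = _props(counts_a), _props(counts_b)
    num = den = 0.0
    for length, leaves in edges_with_leafsets(newick):
        mass_a = sum(pa.get(l, 0.0) for l in leaves)
        mass_b = sum(pb.get(l, 0.0) for l in leaves)
        num += length * abs(mass_a - mass_b)
        den += length
    return num / den if den else 0.0


def _surprisal(p: float) -> float:
    return -p * math.log2(p) if p > 0 else 0.0


def information(newick: str, counts_a: dict, counts_b: dict) -> float:
    pa, pb = _props(counts_a), _props(counts_b)
    num = den = 0.0
    for length, leaves in edges_with_leafsets(newick):
        mass_a = sum(pa.get(l, 0.0) for l in leaves)
        mass_b = sum(pb.get(l, 0.0) for l in leaves)
        num += length * abs(_surprisal(mass_a) - _surprisal(mass_b))
        den += length
    return num / den if den else 0.0


def _gm(parts: list[float]) -> float:
    prod = 1.0
    for p in parts:
        prod *= p
    return prod ** (1.0 / len(parts))


def ratio(newick: str, props_a: dict, props_b: dict) -> float:
    """Ratio UniFrac from strictly positive proportions.

    For each branch the composition is collapsed: the subtree's leaves
    merge into one part, every outside leaf stays separate; the branch
    mass is divided by the geometric mean of that collapsed composition.
    """
    all_leaves = set(props_a)
    num = den = 0.0
    for length, leaves in edges_with_leafsets(newick):
        outside = all_leaves - leaves
        term = []
        for props in (props_a, props_b):
            mass = sum(props[l] for l in leaves)
            parts = [mass] + [props[l] for l in outside]
            term.append(mass / _gm(parts))
        num += length * abs(term[0] - term[1])
        den += length
    return num / den if den else 0.0


def bray_curtis(counts_a: dict, counts_b: dict) -> float:
    keys = set(counts_a) | set(counts_b)
    cmin = sum(min(counts_a.get(k, 0), counts_b.get(k, 0)) for k in keys)
    sa = sum(counts_a.values())
    sb = sum(counts_b.values())
    return 1.0 - 2.0 * cmin / (sa + sb)
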