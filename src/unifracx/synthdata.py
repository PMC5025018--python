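"""Synthetic microbiome data generators.

Every experiment in this package runs on generated inputs: random
coalescent-style trees with exponential branch lengths (optionally with
injected long pendant branches, the structure that destabilizes
presence/absence metrics under rarefaction), single-site "uniform" tables
with no group structure, two-group tables with clade-concentrated effects,
near-monoculture tables (97% dominated by one taxon), and the worked
boundary cases of the unweighted UniFrac definition.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .treekit import PhyloTree, parse_newick

__all__ = [
    "SyntheticSpec",
    "LongBranchScenario",
    "random_tree",
    "make_boundary_cases",
    "monoculture_template",
    "simulate_monocultures",
    "simulate_longbranch_flip",
    "simulate_uniform_dataset",
    "simulate_two_group_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study designs.

    Defaults mirror the single-site study conditions: 60 samples over 554
    OTUs with per-sample depths log-uniform between 659 and 17176 reads, a
    long-tailed (lognormal sigma=2) rank-abundance composition, a 97%
    dominant for monocultures, and 10 long pendant branches at 10x the
    median pendant length.
    """

    n_samples: int = 60
    n_otus: int = 554
    dominant_proportion: float = 0.97
    depth_min: int = 659
    depth_max: int = 17176
    composition_sigma: float = 2.0
    dispersion: float = 50.0
    n_long_branches: int = 10
    long_branch_factor: float = 10.0
    effect_size: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.dominant_proportion < 1:
            raise ValueError("dominant proportion must be in (0, 1)")
        if min(self.n_samples, self.n_otus, self.depth_min, self.depth_max) <= 0:
            raise ValueError("sizes and depths must be positive")
        if self.depth_max < self.depth_min:
            raise ValueError("depth_max < depth_min")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect size must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (use inf for no dispersion)")


def _otu_names(n: int) -> list[str]:
    return [f"OTU.{i + 1:04d}" for i in range(n)]


def random_tree(
    n_leaves: int,
    seed: int,
    *,
    names: Sequence[str] | None = None,
    mean_length: float = 0.1,
    n_long_branches: int = 0,
    long_branch_factor: float = 10.0,
) -> PhyloTree:
    """Random rooted binary tree with exponential branch lengths.

    Topology is built by random sequential joining (coalescent-style):
    starting from the leaves, pairs of surviving lineages are merged
    uniformly at random. ``n_long_branches`` pendant edges (chosen at
    random) are stretched by ``long_branch_factor`` to create isolated
    long branches.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    if names is None:
        names = _otu_names(n_leaves)
    elif len(names) != n_leaves:
        raise ValueError("names length must equal n_leaves")
    rng = np.random.default_rng(seed)
    if n_leaves == 1:
        return parse_newick(f"({names[0]}:{rng.exponential(mean_length):.8g});")
    lineages = [f"{nm}:{rng.exponential(mean_length):.8g}" for nm in names]
    while len(lineages) > 2:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(f"({a},{b}):{rng.exponential(mean_length):.8g}")
    tree = parse_newick(f"({lineages[0]},{lineages[1]});")
    if n_long_branches > 0:
        tips = list(tree.skbio_tree.tips())
        picks = rng.choice(len(tips), size=min(n_long_branches, len(tips)), replace=False)
        for k in picks:
            tips[k].length *= long_branch_factor
        tree = PhyloTree(tree.skbio_tree)
    return tree


def make_boundary_cases() -> list[tuple[PhyloTree, pd.Series, pd.Series, float]]:
    """Three worked boundary cases of unweighted UniFrac.

    Returns (tree, counts_a, counts_b, expected) with expected values 1
    (disjoint clades, no shared branch), 0.5 (half of the covered branch
    length shared), and 0 (identical taxon sets).
    """
    cases = []
    # no shared branches -> 1
    t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    cases.append((t, pd.Series({"A": 5, "B": 3}), pd.Series({"C": 2, "D": 9}), 1.0))
    # shared branch length (2 via C) equals unshared (A + B) -> 0.5
    t = parse_newick("(A:1,B:1,C:2);")
    cases.append((t, pd.Series({"A": 4, "C": 6}), pd.Series({"B": 1, "C": 3}), 0.5))
    # identical taxon sets (counts differ) -> 0
    t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    cases.append((t, pd.Series({"A": 10, "C": 1}), pd.Series({"A": 2, "C": 7}), 0.0))
    return cases


def monoculture_template(
    n_otus: int = 115,
    total: int = 50_000,
    dominant_proportion: float = 0.97,
    seed: int = 0,
) -> pd.Series:
    """One near-monoculture sample: a 97% dominant plus a sparse
    long-tailed 3% remainder.

    Emulates an infected-host community profile: one taxon at
    ``dominant_proportion`` and a Zipf-decaying remainder whose top
    subdominants reach ~1-2% of the sample — abundances whose surprisal
    weight exceeds the dominant's (I(0.97) is near zero), the regime in
    which surprisal-weighted comparisons lose the monoculture identity.
    Roughly half the OTUs are absent so that shuffling produces distinct
    presence patterns.
    """
    rng = np.random.default_rng(seed)
    names = _otu_names(n_otus)
    counts = np.zeros(n_otus, dtype=np.int64)
    dominant_count = int(round(total * dominant_proportion))
    remainder = total - dominant_count
    n_minor = max(2, n_otus // 2)
    weights = 1.0 / np.arange(1, n_minor + 1) ** 2.0
    minor = rng.multinomial(remainder, weights / weights.sum())
    counts[0] = dominant_count
    counts[1 : 1 + n_minor] = minor
    return pd.Series(counts, index=names, name="template")


def simulate_monocultures(
    template: pd.Series,
    dominants: Sequence[str],
    group_size: int,
    seed: int,
) -> pd.DataFrame:
    """Shuffled-template monoculture groups.

    Each sample carries exactly the template's multiset of counts with the
    taxa shuffled uniformly at random; the maximal count is then swapped
    into the group's dominant OTU, producing ``len(dominants)`` groups of
    ``group_size`` near-monocultures. Sample ids are ``{dominant}_{k:02d}``.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if len(set(dominants)) != len(dominants):
        raise ValueError("dominant OTU ids must be distinct")
    missing = [d for d in dominants if d not in template.index]
    if missing:
        raise KeyError(f"dominant id(s) not in template OTU set: {missing}")
    rng = np.random.default_rng(seed)
    otus = list(template.index)
    values = template.to_numpy()
    rows = {}
    for dom in dominants:
        dom_idx = otus.index(dom)
        for k in range(group_size):
            shuffled = values[rng.permutation(len(values))]
            top = int(np.argmax(shuffled))
            shuffled[top], shuffled[dom_idx] = shuffled[dom_idx], shuffled[top]
            rows[f"{dom}_{k + 1:02d}"] = shuffled.copy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=otus).astype(np.int64)


@dataclass(frozen=True)
class LongBranchScenario:
    """A tree with a long isolated branch plus a two-sample table where
    rarefaction flips the flagged OTU between zero and non-zero."""

    tree: PhyloTree
    table: pd.DataFrame
    flagged_otu: str
    depth: int
    p_zero: float  # hypergeometric P(flagged OTU rarefied to 0)


def simulate_longbranch_flip(
    spec: SyntheticSpec | None = None,
    *,
    flagged_count: int = 5,
    deep_total: int = 1075,
    shallow_total: int = 221,
) -> LongBranchScenario:
    """Two-sample table + tree reproducing the rarefaction-flip hazard.

    The flagged OTU sits on a pendant branch at least 5x the median branch
    length and has ``flagged_count`` reads in the deep sample; rarefying
    the deep sample to the shallow sample's total zeroes it with
    hypergeometric probability required to lie in (0.2, 0.8), so different
    rarefaction instances disagree on its presence and unweighted UniFrac
    swings accordingly.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_otus = 8
    names = _otu_names(n_otus)
    flagged = names[4]
    depth = shallow_total
    p_zero = float(hypergeom.pmf(0, deep_total, flagged_count, depth))
    if not 0.2 < p_zero < 0.8:
        raise ValueError(
            f"infeasible: P(rarefied to zero) = {p_zero:.3f} outside (0.2, 0.8); "
            "adjust flagged_count or totals"
        )
    # deep sample: long-tailed remainder around the low flagged count
    weights = rng.lognormal(0.0, 1.2, size=n_otus - 1)
    rest = rng.multinomial(deep_total - flagged_count, weights / weights.sum())
    deep = np.insert(rest, 4, flagged_count)
    # shallow sample: flagged OTU abundant here, remainder spread
    sh_weights = rng.lognormal(0.0, 1.0, size=n_otus - 1)
    sh_rest = rng.multinomial(shallow_total - 59, sh_weights / sh_weights.sum())
    shallow = np.insert(sh_rest, 4, 59)
    table = pd.DataFrame([deep, shallow], index=["A", "B"], columns=names).astype(np.int64)
    tree = random_tree(n_otus, spec.seed + 1, names=names)
    tips = {t.name: t for t in tree.skbio_tree.tips()}
    pendant = np.array([t.length for n, t in tips.items() if n != flagged])
    tips[flagged].length = max(tips[flagged].length, 5.0 * float(np.median(pendant)))
    tree = PhyloTree(tree.skbio_tree)
    return LongBranchScenario(tree=tree, table=table, flagged_otu=flagged,
                              depth=depth, p_zero=p_zero)


def _base_composition(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse long-tailed rank-abundance composition (lognormal weights)."""
    w = rng.lognormal(mean=0.0, sigma=spec.composition_sigma, size=spec.n_otus)
    w = np.sort(w)[::-1]
    return w / w.sum()


def _depths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = np.log(spec.depth_min), np.log(spec.depth_max)
    d = np.exp(rng.uniform(lo, hi, size=spec.n_samples)).astype(np.int64)
    d = np.clip(d, spec.depth_min, spec.depth_max)
    # anchor the stated min/max so the realized depth span matches the design
    if spec.n_samples >= 2:
        d[0], d[-1] = spec.depth_min, spec.depth_max
    return d


def _sample_composition(base: np.ndarray, dispersion: float,
                        rng: np.random.Generator) -> np.ndarray:
    """One sample's composition: Dirichlet around the site's centre.

    ``dispersion`` is the Dirichlet concentration (higher = samples closer
    to the common centre); ``inf`` returns the centre itself, i.e. every
    sample shares literally one composition.
    """
    if not np.isfinite(dispersion):
        return base
    comp = rng.dirichlet(np.maximum(base * dispersion, 1e-12))
    if comp.sum() == 0:  # pragma: no cover - numerically unreachable
        return base
    return comp


def simulate_uniform_dataset(spec: SyntheticSpec | None = None) -> tuple[PhyloTree, pd.DataFrame]:
    """Single-site design: no group structure, one common centre.

    Every sample's composition is drawn from a Dirichlet around one sparse
    long-tailed centre (concentration = ``spec.dispersion``), emulating
    inter-individual variation at a single body site; depths are
    log-uniform between the spec's bounds. With ``dispersion = inf`` all
    samples share literally the same composition and differ only by
    counting noise. Either way there is no group structure, so any
    apparent clustering downstream is a metric artifact.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    comp = _base_composition(spec, rng)
    depths = _depths(spec, rng)
    counts = np.vstack([
        rng.multinomial(d, _sample_composition(comp, spec.dispersion, rng))
        for d in depths
    ])
    names = _otu_names(spec.n_otus)
    table = pd.DataFrame(counts, columns=names,
                         index=[f"S{i + 1:03d}" for i in range(spec.n_samples)])
    tree = random_tree(
        spec.n_otus, spec.seed + 1, names=names,
        n_long_branches=spec.n_long_branches,
        long_branch_factor=spec.long_branch_factor,
    )
    return tree, table.astype(np.int64)


def simulate_two_group_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[PhyloTree, pd.DataFrame, list[str]]:
    """Two-site design: two groups concentrated on disjoint clades.

    Each group's composition is ``(1 - e) * base + e * clade_mass`` where
    ``e`` is the spec's effect size and the clade masses live on the two
    halves of the tree below the root, so the groups differ both in
    abundance and in phylogenetic placement. ``e = 0`` reduces to the
    uniform (single-site) generator's design.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    names = _otu_names(spec.n_otus)
    tree = random_tree(
        spec.n_otus, spec.seed + 1, names=names,
        n_long_branches=spec.n_long_branches,
        long_branch_factor=spec.long_branch_factor,
    )
    base = _base_composition(spec, rng)
    # the two clades below the root partition the leaves
    root_children = tree.skbio_tree.children
    clade1 = {t.name for t in root_children[0].tips()} or {root_children[0].name}
    leaf_order = list(names)
    in1 = np.array([nm in clade1 for nm in leaf_order])
    comps = []
    for mask in (in1, ~in1):
        focus = np.where(mask, base, 0.0)
        if focus.sum() == 0:
            raise ValueError("degenerate clade split")
        comps.append((1 - spec.effect_size) * base + spec.effect_size * focus / focus.sum())
    depths = _depths(spec, rng)
    half = spec.n_samples // 2
    labels = ["group1"] * half + ["group2"] * (spec.n_samples - half)
    counts = np.vstack([
        rng.multinomial(d, _sample_composition(
            comps[0] if lab == "group1" else comps[1], spec.dispersion, rng))
        for d, lab in zip(depths, labels)
    ])
    table = pd.DataFrame(counts, columns=names,
                         index=[f"{lab}_{i + 1:03d}" for i, lab in enumerate(labels)])
    return tree, table.astype(np.int64), labels
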