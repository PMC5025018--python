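"""OTU count-table handling: I/O, filtering, rarefaction, zero replacement.

Convention: a *count table* is a :class:`pandas.DataFrame` with samples as
rows and OTUs as columns, holding non-negative integers. A *proportion
table* has the same labels with rows summing to 1.

16S rRNA gene tag counts are compositional — the per-sample total is an
instrument artifact — so downstream metrics work on proportions (optionally
after rarefaction, which subsamples without replacement to a common depth).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "read_count_table",
    "write_count_table",
    "validate_count_table",
    "filter_rare_otus",
    "rarefy",
    "to_proportions",
    "replace_zeros",
    "load_worked_example",
]

PathLike = Union[str, Path]


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the samples-x-OTUs count-table contract, returning the table.

    All cells must be non-negative integers; sample and OTU labels unique.
    """
    if table.index.has_duplicates:
        raise ValueError("duplicate sample ids")
    if table.columns.has_duplicates:
        raise ValueError("duplicate OTU ids")
    arr = table.to_numpy()
    if arr.size == 0:
        raise ValueError("empty count table")
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"negative or non-finite count at sample {table.index[i]!r}, "
            f"OTU {table.columns[j]!r}"
        )
    frac = arr.astype(float) - np.floor(arr.astype(float))
    if np.any(frac != 0):
        i, j = np.argwhere(frac != 0)[0]
        raise ValueError(
            f"non-integer count at sample {table.index[i]!r}, OTU {table.columns[j]!r}"
        )
    return table.astype(np.int64)


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Read a TSV count table, auto-detecting orientation.

    QIIME-classic layout (first header token ``#OTU ID``, OTUs as rows,
    samples as columns) is transposed to the samples-x-OTUs convention;
    any other header is taken as samples-x-OTUs already.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    qiime_classic = first.split("\t")[0].strip().lstrip("#").upper().startswith("OTU")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if qiime_classic:
        df = df.T
    df.index.name = None
    df.columns.name = None
    return validate_count_table(df)


def write_count_table(table: pd.DataFrame, path: PathLike, *, qiime_classic: bool = True) -> None:
    """Write a count table as TSV (QIIME-classic OTUs-x-samples by default)."""
    out = table.T if qiime_classic else table
    out = out.copy()
    out.index.name = "#OTU ID" if qiime_classic else "sample"
    out.to_csv(path, sep="\t")


def load_worked_example(full: bool = False) -> pd.DataFrame:
    """Load the packaged two-sample worked example (8 OTUs).

    Samples A (1075 total counts) and B (221). With ``full=True`` the two
    recorded 221-deep rarefaction instances (A.R1/B.R1, A.R2/B.R2) are
    included as extra samples; the low-count OTU.37990 drops to zero in one
    instance but not the other, the pattern that destabilizes unweighted
    UniFrac under rarefaction.
    """
    with resources.files("unifracx.data").joinpath("rarefaction_example.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0).T
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    if not full:
        df = df.loc[["A", "B"]]
    return validate_count_table(df)


def filter_rare_otus(table: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Drop OTUs whose total count across all samples is below ``min_total``.

    A common preprocessing threshold is 100. Raises if nothing survives.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.sum(axis=0) >= min_total
    if not keep.any():
        raise ValueError(f"min_total={min_total} removes every OTU")
    return table.loc[:, keep]


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Each sample's rarefied counts are one multivariate-hypergeometric draw
    from its observed counts. Samples are processed in label-sorted order
    from a single generator seeded with ``seed``, so results are
    bit-reproducible for a given (table, depth, seed).
    """
    totals = table.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"rarefaction depth {depth} exceeds total count of sample(s): "
            + ", ".join(f"{s} ({t})" for s, t in short.items())
        )
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0, index=table.index, columns=table.columns, dtype=np.int64)
    for sample in sorted(table.index):
        counts = table.loc[sample].to_numpy()
        out.loc[sample] = rng.multivariate_hypergeometric(counts, depth)
    return out


def to_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to within-sample proportional abundances."""
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            "zero-total sample(s): " + ", ".join(map(str, zero.index))
        )
    return table.div(totals, axis=0).astype(float)


def replace_zeros(
    table: pd.DataFrame, method: str = "bayesian", pseudocount: float = 0.5
) -> pd.DataFrame:
    """Strictly positive proportions via Bayesian-multiplicative replacement.

    Each zero cell is imputed as ``pseudocount / sample_total`` (a uniform
    posterior pseudocount on the counts) and the positive parts are shrunk
    by one common factor per sample so the row still sums to 1 — ratios
    among originally positive parts are untouched. Tables with no zeros
    come back identical to :func:`to_proportions`.

    This follows the count-zero-multiplicative family of replacement
    strategies used in compositional microbiome analysis; a log-ratio
    transform (or ratio UniFrac's geometric means) is only defined on
    strictly positive parts.
    """
    if method not in ("bayesian", "multiplicative"):
        raise ValueError(f"unknown zero-replacement method {method!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    props = to_proportions(table)
    arr = props.to_numpy()
    counts = table.to_numpy().astype(float)
    totals = counts.sum(axis=1)
    out = arr.copy()
    for i in range(arr.shape[0]):
        zero = counts[i] == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            continue
        delta = pseudocount / totals[i]
        imputed = n_zero * delta
        if imputed >= 1.0:  # pathological: nearly-all-zero ultra-shallow sample
            delta = 0.5 / n_zero / totals[i]
            imputed = n_zero * delta
        out[i, zero] = delta
        out[i, ~zero] = arr[i, ~zero] * (1.0 - imputed)
    return pd.DataFrame(out, index=table.index, columns=table.columns)
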