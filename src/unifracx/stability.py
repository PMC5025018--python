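"""Rarefaction-instance stability diagnostics.

Rarefaction is a random subsample, so any downstream ordination is a
random variable. The diagnostic here repeats rarefaction ``n`` times,
computes a distance matrix and PCoA per instance, Procrustes-overlays each
instance onto the first, and measures the per-sample relative deviation of
the first principal coordinate:

    V_res = |V1 - Vi| / range(V1, Vi)

where ``V1`` is the reference PC1, ``Vi`` the i-th instance's aligned PC1,
and the range is max - min of the two vectors pooled (one scalar per
instance). Each instance is summarized by its maximum and median V_res;
a metric whose (max, median) cloud sits high is unstable to rarefaction.
Samples whose PC1 sign flips between the first two instances are flagged
as migrations (the arrow plot of the original analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import tables as _tables
from .metrics import distance_matrix
from .ordination import pcoa, procrustes
from .treekit import PhyloTree

__all__ = [
    "StabilityResult",
    "EllipseSummary",
    "relative_deviation",
    "rarefaction_stability",
    "summarize_ellipse",
]


def relative_deviation(v1: np.ndarray, vi: np.ndarray) -> np.ndarray:
    """Per-sample relative PC1 deviation ``|V1 - Vi| / range(V1, Vi)``.

    The range is max - min over the pooled values of both vectors, so the
    result is invariant to scaling both vectors by a common positive
    factor. Raises on zero pooled range (degenerate ordination).
    """
    v1 = np.asarray(v1, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if v1.shape != vi.shape:
        raise ValueError("PC1 vectors must have equal length")
    pooled = np.concatenate([v1, vi])
    rng = pooled.max() - pooled.min()
    if rng == 0:
        raise ValueError("zero pooled range: degenerate ordination")
    return np.abs(v1 - vi) / rng


@dataclass(frozen=True)
class StabilityResult:
    """Per-rarefaction stability summary for one metric."""

    metric: str
    n_rarefactions: int
    sample_ids: tuple[str, ...]
    vres: np.ndarray  # (n_rarefactions, n_samples); row 0 is all zeros
    max_vres: np.ndarray
    median_vres: np.ndarray
    migrations: tuple[str, ...]  # PC1 sign flips, instance 1 vs 2

    @property
    def mean_max(self) -> float:
        return float(self.max_vres[1:].mean())

    @property
    def mean_median(self) -> float:
        return float(self.median_vres[1:].mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rarefaction": np.arange(1, self.n_rarefactions + 1),
                "max_vres": self.max_vres,
                "median_vres": self.median_vres,
            }
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def rarefaction_stability(
    table: pd.DataFrame,
    tree: PhyloTree,
    metric: str,
    n: int = 100,
    depth: int | None = None,
    seed: int = 0,
    *,
    n_axes: int = 2,
) -> StabilityResult:
    """Repeat rarefaction ``n`` times and trace PC1 deviation per instance.

    Every instance i uses seed ``seed + i`` (i = 1..n) so individual
    rarefactions are auditable. Each rarefied table feeds the chosen
    metric directly (no second rarefaction inside ``distance_matrix``),
    then PCoA, then a Procrustes overlay of the first ``n_axes`` axes onto
    the first instance. V_res is computed on the aligned PC1.
    """
    if n < 2:
        raise ValueError("need at least two rarefaction instances")
    if depth is None:
        depth = int(table.sum(axis=1).min())
    ref_ord = None
    ref_pc1 = None
    vres_rows = []
    max_v = np.zeros(n)
    med_v = np.zeros(n)
    migrations: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()
    for i in range(1, n + 1):
        rare = _tables.rarefy(table, depth, seed + i)
        dm = distance_matrix(tree, rare, metric, rarefy=False, seed=seed + i)
        ordn = pcoa(dm)
        if i == 1:
            ref_ord = ordn
            ref_pc1 = ordn.axis(0)
            sample_ids = ordn.ids
            vres_rows.append(np.zeros(len(sample_ids)))
            continue
        k = min(n_axes, ref_ord.n_axes, ordn.n_axes)
        aligned, _ = procrustes(ref_ord.coordinates[:, :k], ordn.coordinates[:, :k], k)
        vi = aligned[:, 0]
        v = relative_deviation(ref_pc1, vi)
        vres_rows.append(v)
        max_v[i - 1] = v.max()
        med_v[i - 1] = float(np.median(v))
        if i == 2:
            flips = np.sign(ref_pc1) * np.sign(vi) < 0
            migrations = tuple(np.asarray(sample_ids)[flips])
    return StabilityResult(
        metric=metric,
        n_rarefactions=n,
        sample_ids=sample_ids,
        vres=np.vstack(vres_rows),
        max_vres=max_v,
        median_vres=med_v,
        migrations=migrations,
    )


@dataclass(frozen=True)
class EllipseSummary:
    """Bivariate-normal confidence ellipse of a 2-D point cloud."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_deg: float  # major-axis angle, counter-clockwise from +x
    level: float
    degenerate: bool
    _cov_inv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership mask: squared Mahalanobis radius within the level's
        chi-square quantile (2 dof)."""
        if self._cov_inv is None:
            raise ValueError("degenerate ellipse has no interior")
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        r2 = np.einsum("ij,jk,ik->i", pts, self._cov_inv, pts)
        return r2 <= chi2.ppf(self.level, df=2)


def summarize_ellipse(points: np.ndarray, level: float = 0.95) -> EllipseSummary:
    """Confidence ellipse (sample mean + covariance) of (max, median) pairs.

    Semi-axes are ``sqrt(chi2_quantile * eigenvalue)`` of the covariance;
    a singular covariance (collinear points) is flagged degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = cov.trace() if cov.trace() > 0 else 1.0
    degenerate = eigvals[-1] <= 1e-12 * scale
    q = chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(eigvals, 0, None) * q)
    angle = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
    return EllipseSummary(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_deg=angle,
        level=level,
        degenerate=degenerate,
        _cov_inv=None if degenerate else np.linalg.inv(cov),
    )
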