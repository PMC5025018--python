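"""Principal coordinates analysis and Procrustes overlay.

PCoA here is classical (Torgerson) scaling: double-centre ``-D**2 / 2``,
eigendecompose, and scale eigenvectors by the square root of their
(positive) eigenvalues. Negative eigenvalues — the signature of a
non-Euclidean dissimilarity such as pruned-tree or ratio UniFrac — are
reported but their axes are dropped, and variance fractions are taken over
the positive eigenvalues only.

Procrustes overlay translates, rotates/reflects and (optionally) scales a
target configuration onto a reference, which is how repeated-rarefaction
ordinations are made comparable before measuring per-sample deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes

from .metrics import DistanceMatrix

__all__ = ["Ordination", "pcoa", "procrustes"]


@dataclass(frozen=True)
class Ordination:
    """PCoA result: centred coordinates, eigenvalues, variance fractions.

    ``eigenvalues`` holds the full descending spectrum (negatives
    included); ``coordinates`` and ``proportion_explained`` cover the
    retained positive axes only.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis(self, k: int) -> np.ndarray:
        """k-th principal coordinate (0-based), one value per sample."""
        return self.coordinates[:, k]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(f"{e:.10g}" for e in self.eigenvalues) + "\n")
            fh.write(
                "# proportion_explained\t"
                + "\t".join(f"{p:.10g}" for p in self.proportion_explained)
                + "\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index_label="sample")

    def plot(self, path: Union[str, Path], labels: Sequence[str] | None = None) -> None:
        """PC1-vs-PC2 scatter with % variance in the axis labels."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        x = self.axis(0)
        y = self.axis(1) if self.n_axes > 1 else np.zeros_like(x)
        if labels is None:
            ax.scatter(x, y, s=18)
        else:
            for lab in sorted(set(labels)):
                mask = np.asarray([l == lab for l in labels])
                ax.scatter(x[mask], y[mask], s=18, label=lab)
            ax.legend(fontsize=8)
        pe = self.proportion_explained
        ax.set_xlabel(f"PC1 ({100 * pe[0]:.1f}%)" if len(pe) else "PC1")
        ax.set_ylabel(f"PC2 ({100 * pe[1]:.1f}%)" if len(pe) > 1 else "PC2")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def pcoa(dmatrix: DistanceMatrix, *, eig_tol_factor: float = 1e-12) -> Ordination:
    """Classical scaling of a symmetric zero-diagonal dissimilarity matrix.

    Axis signs are fixed by forcing the largest-magnitude loading on each
    axis positive, so repeated runs (and Procrustes inputs) are
    deterministic. A matrix with no positive eigenvalue (e.g. all-zero
    distances) yields a single all-zero axis.
    """
    d = np.asarray(dmatrix.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * eig_tol_factor if n else 0.0
    pos = eigvals > tol
    if not pos.any():
        return Ordination(
            ids=tuple(dmatrix.ids),
            coordinates=np.zeros((n, 1)),
            eigenvalues=eigvals,
            proportion_explained=np.zeros(1),
        )
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # deterministic sign: largest |loading| per axis made positive
    flips = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(coords.shape[1])])
    flips[flips == 0] = 1.0
    coords = coords * flips
    prop = eigvals[pos] / eigvals[pos].sum()
    return Ordination(
        ids=tuple(dmatrix.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def procrustes(
    reference: np.ndarray,
    target: np.ndarray,
    n_axes: int | None = None,
    *,
    scaling: bool = True,
) -> tuple[np.ndarray, float]:
    """Overlay ``target`` onto ``reference`` by translation + orthogonal
    rotation/reflection (+ isotropic scaling unless ``scaling=False``).

    Both inputs are (n_samples, n_axes_available) coordinate arrays with
    identical sample order; the first ``n_axes`` columns are used. Returns
    the aligned target expressed in the reference's coordinate frame and
    the disparity: the minimized sum of squared differences after both
    configurations are standardized (centred, unit Frobenius norm) —
    scipy's convention, 0 for configurations identical up to the allowed
    transform.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.ndim != 2 or tgt.ndim != 2 or ref.shape[0] != tgt.shape[0]:
        raise ValueError("configurations must share the sample dimension")
    if n_axes is None:
        n_axes = min(ref.shape[1], tgt.shape[1])
    if n_axes > ref.shape[1] or n_axes > tgt.shape[1]:
        raise ValueError(f"n_axes={n_axes} exceeds available axes")
    x = ref[:, :n_axes]
    y = tgt[:, :n_axes]
    mu_x, mu_y = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - mu_x, y - mu_y
    nx, ny = np.linalg.norm(x0), np.linalg.norm(y0)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate (all-coincident) configuration")
    xs, ys = x0 / nx, y0 / ny
    rot, s = orthogonal_procrustes(ys, xs)
    scale = s if scaling else 1.0
    aligned_std = ys @ rot * scale
    disparity = float(np.sum((xs - aligned_std) ** 2))
    aligned = aligned_std * nx + mu_x
    return aligned, disparity
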