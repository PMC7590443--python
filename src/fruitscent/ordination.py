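"""Bray-Curtis dissimilarity, principal coordinates, hierarchical clustering.

Scent composition is zero-inflated and far from multivariate normal, so
species are compared with the Bray-Curtis semimetric and embedded by
classical scaling (PCoA); the resulting scores feed the phylogenetic-signal
statistics.  A dendrogram built from the same distances supports tanglegram
comparison with the phylogeny (export only; no drawing here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from fruitscent.voctable import SpeciesProfile

LINKAGES = {"UPGMA": "average", "complete": "complete", "single": "single", "ward": "ward"}


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal labelled distance matrix."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


@dataclass
class OrdinationScores:
    """PCoA scores: one row per species, axes ordered by decreasing eigenvalue."""

    labels: list[str]
    scores: np.ndarray            # n x k
    eigenvalues: np.ndarray       # k retained (positive) eigenvalues
    all_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    reconstruction_residual: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


def bray_curtis(profile: SpeciesProfile) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between species profiles.

    d(i, j) = sum_c |x_ic - x_jc| / sum_c (x_ic + x_jc), in [0, 1] on
    relative amounts.  A pair of all-zero rows has an undefined quotient; it
    is reported as distance 0 with a warning (identical emptiness).
    """
    x = profile.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative values")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero_pairs = den == 0
    np.fill_diagonal(zero_pairs, False)
    if zero_pairs.any():
        warnings.warn("all-zero profile pair(s): Bray-Curtis set to 0", stacklevel=2)
    d = np.divide(num, den, out=np.zeros_like(num), where=den != 0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(profile.values.index), d)


def pcoa(dist: DistanceMatrix, eigen_tolerance: float = 1e-8) -> OrdinationScores:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres ``-0.5 * D**2``, eigendecomposes, and scales eigenvectors
    by the square root of their eigenvalues.  Axes with eigenvalue at or
    below ``eigen_tolerance`` times the largest eigenvalue are dropped;
    negative eigenvalues (Bray-Curtis is only a semimetric) are always
    dropped, and the squared-distance mass they carried is reported as
    ``reconstruction_residual``.  No Cailliez/Lingoes correction is applied
    by default — the scores are used as ordinary coordinates downstream.
    """
    D = dist.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.size == 0 or eigval[0] <= 0:
        return OrdinationScores(dist.labels, np.zeros((n, 0)), np.empty(0),
                                all_eigenvalues=eigval)
    keep = eigval > eigen_tolerance * eigval[0]
    scores = eigvec[:, keep] * np.sqrt(eigval[keep])
    residual = float(np.abs(eigval[eigval < 0]).sum())
    return OrdinationScores(dist.labels, scores, eigval[keep],
                            all_eigenvalues=eigval,
                            reconstruction_residual=residual)


@dataclass
class Dendrogram:
    """Rooted ultrametric dendrogram from agglomerative clustering."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    def newick(self) -> str:
        """Serialise with branch lengths so root-to-tip distance = merge height / 2."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for k, (a, b, dist, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            h = dist / 2.0
            node = n + k
            height[node] = h
            text[node] = (
                f"({text[a]}:{h - height[a]:.10g},{text[b]}:{h - height[b]:.10g})"
            )
        return text[n + len(self.linkage_matrix) - 1] + ";"

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cophenetic(self) -> DistanceMatrix:
        d = squareform(hierarchy.cophenet(self.linkage_matrix))
        return DistanceMatrix(self.labels, d)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "UPGMA") -> Dendrogram:
    """Agglomerative clustering of a species distance matrix.

    ``linkage`` is one of UPGMA (average), complete, single, ward.  Input
    rows are sorted by label before clustering so equal-distance merges are
    resolved identically regardless of input order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(LINKAGES)}")
    if len(dist.labels) < 2:
        raise ValueError("need at least 2 species to cluster")
    order = np.argsort(np.asarray(dist.labels, dtype=object))
    labels = [dist.labels[i] for i in order]
    d = dist.d[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(d, checks=False), method=LINKAGES[linkage])
    return Dendrogram(labels, Z, linkage)
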