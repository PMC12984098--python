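"""Multivariate structure of codon usage: PCA of the species × codon
RSCU matrix, and k-means clustering of species in two-gene CAI space.

PCA treats species as observations and the 59 synonymous-analysis
codons as variables, column-centered without unit-variance scaling by
default (RSCU is already a common scale); loadings get a deterministic
sign (largest-magnitude element positive) and each codon's contribution
to the first plane is summarized by the loading distance
d = sqrt(loading_PC1² + loading_PC2²).

k-means follows the classic R-style recipe: standardize each CAI
column, run Lloyd's algorithm from ``n_starts`` random partitions, keep
the lowest within-cluster sum of squares. Empty clusters are repaired
by splitting the largest cluster at its farthest point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .genetic_code import GeneticCodeTable, standard_table
from .metrics import GeneCodonProfile

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "KmeansResult", "rscu_matrix", "pca", "kmeans_cai"]


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame            # species × PCk
    loadings: pd.DataFrame          # codon × PCk
    variance_explained: np.ndarray  # fraction per component
    loading_distance: pd.Series     # d over the PC1/PC2 plane

    def top_codons(self, n: int = 10) -> pd.Index:
        """Codons ranked by loading distance d (the highlight set)."""
        return self.loading_distance.sort_values(ascending=False).index[:n]


@dataclass(frozen=True)
class KmeansResult:
    assignments: pd.Series  # species -> label in 1..k
    centers: np.ndarray     # k × d, standardized space
    k: int
    n_starts: int
    seed: int
    inertia: float          # best total within-cluster sum of squares
    standardized: pd.DataFrame


def rscu_matrix(profiles: Iterable[GeneCodonProfile],
                code: GeneticCodeTable | None = None,
                max_undefined_fraction: float = 0.2,
                ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Assemble the species × 59-codon RSCU matrix for one gene.

    Undefined entries (amino acid absent in a species) are imputed with
    the neutral value 1.0 and reported in the returned flag dict;
    species with more than ``max_undefined_fraction`` undefined codons
    are dropped with a warning.
    """
    code = code or standard_table()
    codons = list(code.synonymous_codons)
    rows: dict[str, list[float]] = {}
    imputed: dict[str, list[str]] = {}
    for p in profiles:
        vals = [p.rscu.rscu[c] for c in codons]
        nan_codons = [c for c, v in zip(codons, vals) if math.isnan(v)]
        if len(nan_codons) > max_undefined_fraction * len(codons):
            logger.warning("species %s dropped from RSCU matrix: %d/%d codons undefined",
                           p.species_id, len(nan_codons), len(codons))
            continue
        if nan_codons:
            imputed[p.species_id] = nan_codons
        rows[p.species_id] = [1.0 if math.isnan(v) else v for v in vals]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=codons)
    return matrix.sort_index(), imputed


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False,
        n_components: int | None = None) -> PcaResult:
    """Principal components of an observations × variables matrix.

    Components are ordered by decreasing variance; rank-deficient input
    simply yields fewer components. Each loading vector is flipped so
    its largest-magnitude element is positive, making scores and
    loadings reproducible across runs and row orders.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 observations")
    X = matrix.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_  # k × p

    # deterministic sign: largest-|loading| element positive per component
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0

    names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=names)
    loadings_df = pd.DataFrame(loadings.T, index=matrix.columns, columns=names)
    if k >= 2:
        d = np.sqrt(loadings_df["PC1"] ** 2 + loadings_df["PC2"] ** 2)
    else:
        d = loadings_df["PC1"].abs()
    return PcaResult(scores=scores_df, loadings=loadings_df,
                     variance_explained=model.explained_variance_ratio_,
                     loading_distance=d.rename("d"))


# ---------------------------------------------------------------------------
# k-means in CAI space
# ---------------------------------------------------------------------------

def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from a random partition; returns (labels, centers, ss)."""
    n = len(X)
    labels = rng.integers(0, k, size=n)
    # make sure every cluster starts non-empty
    labels[rng.choice(n, size=k, replace=False)] = np.arange(k)
    centers = np.empty((k, X.shape[1]))
    for _ in range(max_iter):
        for j in range(k):
            mask = labels == j
            if not mask.any():
                # split the largest cluster at its farthest point
                big = np.bincount(labels, minlength=k).argmax()
                pts = np.where(labels == big)[0]
                far = pts[np.argmax(((X[pts] - centers[big]) ** 2).sum(axis=1))]
                labels[far] = j
                mask = labels == j
            centers[j] = X[mask].mean(axis=0)
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    ss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, ss


def kmeans_cai(cai_table: pd.DataFrame, k: int = 3, n_starts: int = 100,
               seed: int = 0) -> KmeansResult:
    """Cluster species on standardized CAI values.

    ``cai_table`` is species (rows) × genes (columns of CAI values);
    each column is standardized to mean 0, SD 1 before clustering.
    Runs ``n_starts`` seeded Lloyd restarts and keeps the best.
    """
    if k > len(cai_table):
        raise ValueError(f"k={k} exceeds the number of species ({len(cai_table)})")
    if cai_table.isna().any().any():
        raise ValueError("CAI table contains undefined entries; complete cases required")
    X = cai_table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_starts):
        labels, centers, ss = _lloyd(Z, k, rng)
        if best is None or ss < best[2]:
            best = (labels, centers, ss)
    labels, centers, ss = best
    assignments = pd.Series(labels + 1, index=cai_table.index, name="cluster")
    zdf = pd.DataFrame(Z, index=cai_table.index, columns=cai_table.columns)
    return KmeansResult(assignments=assignments, centers=centers, k=k,
                        n_starts=n_starts, seed=seed, inertia=ss,
                        standardized=zdf)
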