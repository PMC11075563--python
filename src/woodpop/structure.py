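"""Sample-structure summaries: genotype PCA and IBS hierarchical clustering.

PCA follows the population-genetic convention: each site is centered by its
mean dosage (2 * allele frequency) and scaled by the binomial standard
deviation sqrt(2 p (1 - p)); missing genotypes are mean-imputed for the PCA
only.  The dissimilarity between two samples is one minus their mean
identity-by-state proportion over pairwise-complete sites; clustering is
agglomerative with average linkage (UPGMA) and groups are read off by
cutting the dendrogram at a fixed height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .variants import MISSING, GenotypeMatrix

__all__ = ["PcaResult", "DissimilarityMatrix", "genotype_pca",
           "ibs_dissimilarity", "hclust_cut", "to_newick"]


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray              # (n_samples, k)
    explained_variance: np.ndarray  # (k,) proportions, non-increasing
    n_sites_used: int
    sample_ids: list[str]


@dataclass(frozen=True)
class DissimilarityMatrix:
    values: np.ndarray              # (n, n) symmetric, zero diagonal, [0, 1]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")


def genotype_pca(gm: GenotypeMatrix, k: int = 2,
                 max_missing: float = 0.2) -> PcaResult:
    """Top-k principal components of the scaled genotype matrix.

    Sites monomorphic after imputation, or with a missing fraction above
    `max_missing`, are dropped.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if k >= gm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    g = gm.genotypes.astype(np.float64)
    miss = gm.genotypes == MISSING
    g[miss] = np.nan
    miss_frac = miss.mean(axis=0)
    col_mean = np.nanmean(np.where(miss, np.nan, g), axis=0)
    # mean-impute for the decomposition only
    g = np.where(np.isnan(g), col_mean[None, :], g)
    p = col_mean / 2.0
    keep = (miss_frac <= max_missing) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic sites available for PCA")
    x = (g[:, keep] - 2.0 * p[keep]) / np.sqrt(2.0 * p[keep] * (1.0 - p[keep]))
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    # fewer sites than requested components: trailing components carry nothing
    scores = np.zeros((gm.n_samples, k))
    ev = np.zeros(k)
    r = min(k, s.size)
    scores[:, :r] = u[:, :r] * s[:r]
    ev[:r] = var[:r] / var.sum()
    return PcaResult(
        scores=scores,
        explained_variance=ev,
        n_sites_used=int(keep.sum()),
        sample_ids=list(gm.sample_ids),
    )


def ibs_dissimilarity(gm: GenotypeMatrix) -> DissimilarityMatrix:
    """1 - mean identity-by-state over pairwise-complete sites.

    Per-site IBS between dosages a and b is 1 - |a - b| / 2 (1 for identical
    genotypes, 0 for opposite homozygotes).
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    g = gm.genotypes
    obs = g != MISSING
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = obs[a] & obs[b]
            if not both.any():
                raise ValueError(
                    f"samples {gm.sample_ids[a]!r} and {gm.sample_ids[b]!r} "
                    "share no genotyped sites")
            ibs = 1.0 - np.abs(g[a, both] - g[b, both]) / 2.0
            d[a, b] = d[b, a] = 1.0 - float(ibs.mean())
    return DissimilarityMatrix(values=d, sample_ids=list(gm.sample_ids))


def hclust_cut(d: DissimilarityMatrix, height: float
               ) -> tuple[np.ndarray, np.ndarray, str]:
    """Average-linkage tree cut at `height`.

    Returns (labels, linkage matrix, newick string).  Labels are 1-based
    cluster ids; cutting below the first merge yields all singletons.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=height, criterion="distance")
    return labels, z, to_newick(z, d.sample_ids)


def to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage as newick with merge heights as node depths.

    Branch lengths are the differences between successive merge heights, so
    the tree is ultrametric with leaf depth equal to the root merge height.
    """
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
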