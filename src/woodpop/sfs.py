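"""Folded site frequency spectrum and its flattening transform.

For a sample of n diploids (2n allele copies) the folded SFS is the vector
eta with eta_i = number of sites whose minor allele is present in i copies,
i = 1..n.  The transform reweights each class by

    w_i = i (2n - i) / (2n)   for i < n,        w_n = n,

and renormalizes to sum 1.  Under a constant-size neutral coalescent the
expected unfolded spectrum is proportional to 1/i, so the folded expectation
is proportional to 2n / (i (2n - i)) for i < n and 1/n at i = n; the weights
cancel this exactly and the expected transformed spectrum is flat at
1/n — e.g. 1/11 for 11 diploids.  An excess in the first transformed class
relative to flat is the classic signature of population expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import MISSING, GenotypeMatrix

__all__ = ["FoldedSFS", "TransformedSFS", "fold_counts", "folded_sfs",
           "transform", "plot_spectra"]


@dataclass(frozen=True)
class FoldedSFS:
    """Minor-allele-frequency class counts for n_diploids samples.

    eta has n_diploids entries (classes i = 1..n); sum(eta) is the number of
    polymorphic sites consumed.  n_skipped_missing counts sites excluded
    because a selected genotype was missing.
    """

    eta: np.ndarray
    n_diploids: int
    n_skipped_missing: int = 0

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta)
        if eta.shape != (self.n_diploids,):
            raise ValueError(f"eta must have {self.n_diploids} classes")
        if (eta < 0).any():
            raise ValueError("eta counts must be non-negative")

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_diploids

    @property
    def n_classes(self) -> int:
        return self.n_diploids

    @property
    def S(self) -> int:
        return int(np.sum(self.eta))


@dataclass(frozen=True)
class TransformedSFS:
    """Normalized flattening transform; phi sums to 1."""

    phi: np.ndarray
    n_diploids: int

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi)
        if phi.shape != (self.n_diploids,):
            raise ValueError(f"phi must have {self.n_diploids} classes")
        if (phi < 0).any():
            raise ValueError("phi must be non-negative")


def fold_counts(xi: np.ndarray, n_alleles: int) -> np.ndarray:
    """Fold an unfolded spectrum xi (classes 1..2n-1) to eta (classes 1..n).

    eta_i = xi_i + xi_{2n-i} for i < n and eta_n = xi_n; counts at exactly
    50% frequency stay in class n.
    """
    xi = np.asarray(xi)
    if n_alleles % 2 != 0:
        raise ValueError("n_alleles must be even (diploid samples)")
    if xi.shape != (n_alleles - 1,):
        raise ValueError(f"xi must have {n_alleles - 1} classes")
    n = n_alleles // 2
    eta = np.empty(n, dtype=xi.dtype)
    for i in range(1, n):
        eta[i - 1] = xi[i - 1] + xi[n_alleles - i - 1]
    eta[n - 1] = xi[n - 1]
    return eta


def folded_sfs(gm: GenotypeMatrix, samples: list[str] | None = None) -> FoldedSFS:
    """Folded SFS of the selected samples.

    Sites with any missing genotype among the subset are skipped (and
    counted); monomorphic-in-subset sites are skipped.
    """
    idx = gm.sample_indices(samples)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    n = idx.size
    g = gm.genotypes[idx, :]
    complete = ~np.any(g == MISSING, axis=0)
    n_skipped = int(np.sum(~complete))
    alt = g[:, complete].sum(axis=0).astype(np.int64)
    minor = np.minimum(alt, 2 * n - alt)
    minor = minor[minor > 0]
    eta = np.bincount(minor, minlength=n + 1)[1:n + 1]
    return FoldedSFS(eta=eta.astype(np.int64), n_diploids=n,
                     n_skipped_missing=n_skipped)


def transform(f: FoldedSFS) -> TransformedSFS:
    """Apply the flattening weights and normalize to sum 1."""
    eta = np.asarray(f.eta, dtype=np.float64)
    if eta.sum() == 0:
        raise ValueError("cannot transform an all-zero spectrum")
    n = f.n_diploids
    i = np.arange(1, n + 1, dtype=np.float64)
    w = i * (2 * n - i) / (2 * n)
    w[-1] = n
    r = eta * w
    return TransformedSFS(phi=r / r.sum(), n_diploids=n)


def plot_spectra(f: FoldedSFS, t: TransformedSFS, out: str) -> None:
    """Two-panel bar figure: raw eta counts (left), transformed phi with the
    flat constant-size reference line at 1/n (right)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = np.arange(1, f.n_classes + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.bar(classes, f.eta, color="#3b6ea5")
    ax1.set_xlabel("minor allele copies")
    ax1.set_ylabel(r"$\eta_i$ (site count)")
    ax1.set_title("Folded SFS")
    ax2.bar(classes, t.phi, color="#a53b3b")
    ax2.axhline(1.0 / f.n_classes, color="k", ls="--", lw=1,
                label=f"constant size: 1/{f.n_classes}")
    ax2.set_xlabel("minor allele copies")
    ax2.set_ylabel(r"$\phi_i$")
    ax2.set_title("Transformed")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
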