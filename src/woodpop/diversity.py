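"""Per-partition diversity statistics: S, s, pi, and Watterson's theta.

Statistics are computed on the 2*n haplotype copies of the diploid samples.
Missing genotypes reduce the local allele-copy count m at a site
(pairwise-complete) rather than dropping the site.  Watterson's estimator is

    Theta_W = S / (a_{n-1} * L),   a_k = sum_{j=1}^{k} 1/j,

with n the number of sequences (2 x diploids for nuclear data, individuals
for mitochondrial data) and L the effective sequence length in bp.
Nucleotide diversity is Nei's pi: the mean per-site pairwise difference,

    pi = (1/L) * sum_sites 2 j (m - j) / (m (m - 1)),

with j the alternate-allele copy count and m the non-missing copies at the
site (the unbiased per-site heterozygosity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import MISSING, GenotypeMatrix

__all__ = ["PartitionSpec", "DiversitySummary", "harmonic_number",
           "segregating_sites", "watterson_theta", "nucleotide_diversity",
           "summarize"]


def harmonic_number(k: int) -> float:
    """a_k = 1 + 1/2 + ... + 1/k (a_0 = 0)."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


@dataclass(frozen=True)
class PartitionSpec:
    """A chromosome partition (total / autosomes / Z) with its callable length."""

    name: str
    chrom_set: frozenset[str]
    effective_length: float

    def __post_init__(self) -> None:
        if self.effective_length <= 0:
            raise ValueError("effective_length must be positive")
        if not self.chrom_set:
            raise ValueError("chrom_set must be non-empty")


@dataclass(frozen=True)
class DiversitySummary:
    partition: str
    group: str
    S: int
    s: float
    pi: float
    theta_w: float
    n_sequences: int


def _partition_mask(gm: GenotypeMatrix, partition: PartitionSpec) -> np.ndarray:
    known = set(np.unique(gm.chrom)) | set(gm.contig_lengths)
    unknown = partition.chrom_set - known
    if unknown and gm.n_variants > 0:
        raise ValueError(f"partition {partition.name!r} references unknown "
                         f"chromosomes: {sorted(unknown)}")
    return np.isin(gm.chrom, sorted(partition.chrom_set))


def _allele_counts(gm: GenotypeMatrix, variant_mask: np.ndarray,
                   sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies j, non-missing copies m) per selected variant."""
    g = gm.genotypes[np.ix_(sample_idx, np.flatnonzero(variant_mask))]
    obs = g != MISSING
    j = np.where(obs, g, 0).sum(axis=0).astype(np.int64)
    m = 2 * obs.sum(axis=0).astype(np.int64)
    return j, m


def segregating_sites(gm: GenotypeMatrix, partition: PartitionSpec,
                      group: list[str] | None = None) -> int:
    """Number of variants polymorphic within the selected samples.

    A site counts iff both alleles are present (0 < j < m) among non-missing
    genotypes of the subset; all-missing or subset-monomorphic sites do not.
    """
    idx = gm.sample_indices(group)
    j, m = _allele_counts(gm, _partition_mask(gm, partition), idx)
    return int(np.sum((j > 0) & (j < m)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site estimator S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L <= 0:
        raise ValueError("L must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / (harmonic_number(n - 1) * L)


def nucleotide_diversity(gm: GenotypeMatrix, partition: PartitionSpec,
                         L: float | None = None,
                         group: list[str] | None = None) -> float:
    """Nei's per-site pi over the partition's variants.

    L defaults to the partition's effective_length.  Sites with fewer than two
    observed allele copies contribute nothing.
    """
    idx = gm.sample_indices(group)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    j, m = _allele_counts(gm, _partition_mask(gm, partition), idx)
    if j.size and not np.any(m >= 2):
        raise ValueError("all genotypes missing at every selected site")
    L = partition.effective_length if L is None else L
    ok = m >= 2
    j, m = j[ok].astype(np.float64), m[ok].astype(np.float64)
    per_site = 2.0 * j * (m - j) / (m * (m - 1.0))
    return float(per_site.sum() / L)


def summarize(gm: GenotypeMatrix, partitions: list[PartitionSpec],
              groups: dict[str, list[str]] | None = None):
    """One DiversitySummary row per (partition x group plus 'all').

    `groups` maps group label -> sample ids; the 'all' group (every sample)
    is always included.  Returns a tidy pandas DataFrame.
    """
    import pandas as pd

    group_map: dict[str, list[str] | None] = {"all": None}
    if groups:
        for label, ids in groups.items():
            unknown = set(ids) - set(gm.sample_ids)
            if unknown:
                raise KeyError(f"group {label!r} has unknown samples: "
                               f"{sorted(unknown)}")
            group_map[label] = list(ids)

    rows = []
    for part in partitions:
        for label, ids in group_map.items():
            n_dip = gm.n_samples if ids is None else len(ids)
            n_seq = 2 * n_dip
            S = segregating_sites(gm, part, ids)
            pi = nucleotide_diversity(gm, part, group=ids)
            rows.append(DiversitySummary(
                partition=part.name,
                group=label,
                S=S,
                s=S / part.effective_length,
                pi=pi,
                theta_w=watterson_theta(S, n_seq, part.effective_length),
                n_sequences=n_seq,
            ))
    return pd.DataFrame([vars(r) for r in rows])
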