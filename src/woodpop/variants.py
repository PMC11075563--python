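"""Genotype matrices and the depth-based variant retention rule.

A variant is retained iff its depth of coverage lies in the closed interval
``[min_dp, ceiling]`` where the ceiling is the empirical `ceiling_quantile`
(default 90th percentile, nearest-rank) of the observed depth distribution —
the standard one-pass outlier filter applied after genotype calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = ["MISSING", "GenotypeMatrix", "DepthFilterSpec", "FilterReport",
           "read_vcf", "depth_ceiling", "apply_depth_filter", "write_filter_report"]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: samples x biallelic variants.

    genotypes holds alternate-allele dosages {0, 1, 2} with -1 for missing.
    chrom/pos/dp are per-variant; positions are strictly increasing within a
    chromosome.  sample_group optionally maps sample id -> group label
    (e.g. historical / contemporary).
    """

    genotypes: np.ndarray          # (n_samples, n_variants) int8
    chrom: np.ndarray              # (n_variants,) str
    pos: np.ndarray                # (n_variants,) int64, 1-based
    dp: np.ndarray                 # (n_variants,) float64
    sample_ids: list[str]
    sample_group: dict[str, str] | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)
    dp_source: str = "INFO/DP"
    n_dropped_nonbiallelic: int = 0
    n_dropped_indel: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,missing}")
        if (np.asarray(self.dp) < 0).any():
            raise ValueError("dp must be non-negative")
        for c in np.unique(np.asarray(self.chrom)):
            p = np.asarray(self.pos)[np.asarray(self.chrom) == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def sample_indices(self, ids: list[str] | None) -> np.ndarray:
        if ids is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.int64)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[:, mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            dp=self.dp[mask],
            sample_ids=list(self.sample_ids),
            sample_group=self.sample_group,
            contig_lengths=dict(self.contig_lengths),
            dp_source=self.dp_source,
        )


@dataclass(frozen=True)
class DepthFilterSpec:
    """Retention rule: keep variants with min_dp <= DP <= percentile ceiling."""

    min_dp: float = 10.0
    ceiling_quantile: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.ceiling_quantile < 1):
            raise ValueError("ceiling_quantile must be in (0, 1)")
        if self.min_dp < 0:
            raise ValueError("min_dp must be non-negative")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    dp_ceiling: float
    retained_interval: tuple[float, float]
    dp_source: str = "INFO/DP"

    def __post_init__(self) -> None:
        if self.n_retained > self.n_input:
            raise ValueError("cannot retain more variants than supplied")


def read_vcf(path: str, sample_group: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF (optionally bgzipped) into a GenotypeMatrix.

    Only biallelic SNPs are kept; multiallelic and indel records are dropped
    and counted.  Missing genotypes become the missing code.  Per-variant DP
    is taken from INFO/DP when present, otherwise the sum of sample FORMAT/DP
    values; the source used is recorded on the matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples / GT fields")
    contig_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        contig_lengths[name] = length

    rows: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    dps: list[float] = []
    n_multi = 0
    n_indel = 0
    dp_source = "INFO/DP"
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if not var.is_snp:
            n_indel += 1
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        dp = var.INFO.get("DP")
        if dp is None:
            fmt_dp = var.format("DP")
            if fmt_dp is None:
                raise ValueError(
                    f"{path}: record {var.CHROM}:{var.POS} has neither INFO/DP "
                    "nor FORMAT/DP")
            dp = float(np.sum(np.clip(fmt_dp, 0, None)))
            dp_source = "sum(FORMAT/DP)"
        rows.append(dosage.astype(np.int8))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        dps.append(float(dp))
    vcf.close()

    if rows:
        genotypes = np.stack(rows, axis=1)
    else:
        genotypes = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(
        genotypes=genotypes,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        dp=np.asarray(dps, dtype=np.float64),
        sample_ids=samples,
        sample_group=sample_group,
        contig_lengths=contig_lengths,
        dp_source=dp_source,
        n_dropped_nonbiallelic=n_multi,
        n_dropped_indel=n_indel,
    )


def depth_ceiling(dp_values: np.ndarray, q: float = 0.90) -> float:
    """Nearest-rank (inverse-ECDF) empirical quantile of the depth values.

    The smallest observed value x such that at least a fraction q of the
    sample is <= x; reproducible on integer depths.
    """
    dp = np.asarray(dp_values, dtype=np.float64)
    dp = dp[np.isfinite(dp)]
    if dp.size == 0:
        raise ValueError("no finite depth values")
    if not (0 < q < 1):
        raise ValueError("quantile must be in (0, 1)")
    rank = math.ceil(q * dp.size)  # 1-based
    return float(np.sort(dp)[rank - 1])


def apply_depth_filter(gm: GenotypeMatrix,
                       spec: DepthFilterSpec = DepthFilterSpec(),
                       ceiling: float | None = None
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain variants with depth in [min_dp, ceiling].

    The ceiling is computed once on the full pre-filter depth distribution
    (one pass), then every variant is compared against the closed interval.
    Passing `ceiling` reuses a previously computed value instead, e.g. to
    re-apply an already-determined interval.
    """
    if gm.n_variants == 0:
        report = FilterReport(0, 0, float("nan"), (spec.min_dp, float("nan")),
                              gm.dp_source)
        return gm, report
    if ceiling is None:
        ceiling = depth_ceiling(gm.dp, spec.ceiling_quantile)
    keep = (gm.dp >= spec.min_dp) & (gm.dp <= ceiling)
    report = FilterReport(
        n_input=gm.n_variants,
        n_retained=int(keep.sum()),
        dp_ceiling=ceiling,
        retained_interval=(spec.min_dp, ceiling),
        dp_source=gm.dp_source,
    )
    return gm.subset_variants(keep), report


def write_filter_report(report: FilterReport, path: str) -> None:
    import pandas as pd

    pd.DataFrame([{
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "dp_ceiling": report.dp_ceiling,
        "interval_low": report.retained_interval[0],
        "interval_high": report.retained_interval[1],
        "dp_source": report.dp_source,
    }]).to_csv(path, sep="\t", index=False)
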