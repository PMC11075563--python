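"""Synthetic inputs with the statistical structure the downstream analyses assume.

The generator produces coalescent genotypes written as VCF, per-variant
sequencing depth with a heavy right tail, mitogenome multiple alignments, and
rearranged two-genome alignment coordinate tables with known truth.

The genealogical engine is a Hudson coalescent per independent locus, with no
intra-locus recombination.  Time is measured in units of 2N generations, so a
pair of lineages in a constant-size population coalesces after an Exp(1)
waiting time, the expected number of segregating sites among k haplotypes is
``theta * a_{k-1}`` (a_k the k-th harmonic number), and the expected per-locus
average pairwise difference equals ``theta``.  Mutations fall as a Poisson
process of rate ``theta/2`` per unit branch length under the infinite-sites
model: every mutation opens a new column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Constant",
    "ExponentialGrowth",
    "TwoDeme",
    "SimulationSpec",
    "DepthModel",
    "RearrangementTruth",
    "simulate_tree",
    "simulate_locus",
    "simulate_loci",
    "write_vcf",
    "generate_coords",
    "write_coords",
    "generate_mito_alignment",
    "write_fasta_alignment",
]


# ---------------------------------------------------------------------------
# demographies

@dataclass(frozen=True)
class Constant:
    """Constant population size (the null demography)."""


@dataclass(frozen=True)
class ExponentialGrowth:
    """Exponential growth at `rate` per coalescent time unit.

    Backwards in time the population shrinks, so the pairwise coalescence
    rate at time t is ``C(k,2) * exp(rate * t)``; forward in time this is an
    expanding population, which produces an excess of low-frequency variants.
    """

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("growth rate must be positive")


@dataclass(frozen=True)
class TwoDeme:
    """Two demes of equal size merging `split_depth` time units in the past.

    No migration: a clean split, the minimal structure needed to test
    PCA / clustering recovery of two sample groups.
    """

    split_depth: float
    migration: float = 0.0

    def __post_init__(self) -> None:
        if self.split_depth <= 0:
            raise ValueError("split_depth must be positive")
        if self.migration != 0.0:
            raise ValueError("migration is not modeled; only a clean split")


Demography = Constant | ExponentialGrowth | TwoDeme


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    theta_per_locus is the scaled per-locus mutation rate (dimensionless);
    with time in units of 2N generations it equals the expected per-locus
    pairwise difference.
    """

    n_diploids: int
    theta_per_locus: float
    n_loci: int
    demography: Demography = Constant()
    seed: int = 0
    locus_length: int = 10_000

    def __post_init__(self) -> None:
        if self.n_diploids < 2:
            raise ValueError("need at least 2 diploid samples")
        if self.theta_per_locus < 0:
            raise ValueError("theta_per_locus must be non-negative")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.locus_length < 1:
            raise ValueError("locus_length must be positive")

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_diploids


@dataclass(frozen=True)
class DepthModel:
    """Per-variant read depth: negative-binomial base + Pareto-tailed outliers.

    The outlier mixture guarantees a wide gap between the median and the
    90th percentile, as seen in real resequencing depth distributions where
    repeated sequences inflate coverage.
    """

    mean_depth: float = 22.7
    dispersion: float = 8.0
    outlier_fraction: float = 0.02
    outlier_scale: float = 6.0
    pareto_shape: float = 1.5

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer depths."""
        r = self.dispersion
        p = r / (r + self.mean_depth)
        dp = rng.negative_binomial(r, p, size=n).astype(np.int64)
        if self.outlier_fraction > 0:
            mask = rng.random(n) < self.outlier_fraction
            k = int(mask.sum())
            if k:
                tail = 1.0 + rng.pareto(self.pareto_shape, size=k)
                dp[mask] = np.round(self.mean_depth * self.outlier_scale * tail)
        return np.maximum(dp, 0)


# ---------------------------------------------------------------------------
# genealogy

def _coalesce_constant(active: list[int], t: float, times: list[float],
                       parents: dict[int, int], rng: np.random.Generator,
                       stop: float = math.inf) -> float:
    """Merge lineages at rate C(k,2) until one remains or `stop` is reached."""
    while len(active) > 1:
        k = len(active)
        dt = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + dt > stop:
            return stop
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = len(times)
        times.append(t)
        parents[a] = new
        parents[b] = new
        active[:] = [x for x in active if x not in (a, b)] + [new]
    return t


def simulate_tree(n_lineages: int, demography: Demography,
                  rng: np.random.Generator,
                  deme_of: Sequence[int] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one genealogy.

    Returns (parent, time): arrays over 2*n_lineages - 1 nodes, leaves first
    (nodes 0..n-1 at time 0), parent[root] == -1.  For a TwoDeme demography
    `deme_of` assigns each leaf to deme 0 or 1 (default: first half / second
    half).
    """
    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    times: list[float] = [0.0] * n_lineages
    parents: dict[int, int] = {}

    if isinstance(demography, Constant):
        active = list(range(n_lineages))
        _coalesce_constant(active, 0.0, times, parents, rng)
    elif isinstance(demography, ExponentialGrowth):
        alpha = demography.rate
        active = list(range(n_lineages))
        t = 0.0
        while len(active) > 1:
            k = len(active)
            rate = k * (k - 1) / 2.0
            e = rng.exponential(1.0)
            # invert the cumulative hazard of rate*exp(alpha*t)
            t += math.log1p(alpha * e * math.exp(-alpha * t) / rate) / alpha
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            new = len(times)
            times.append(t)
            parents[a] = new
            parents[b] = new
            active = [x for x in active if x not in (a, b)] + [new]
    elif isinstance(demography, TwoDeme):
        if deme_of is None:
            half = n_lineages // 2
            deme_of = [0] * half + [1] * (n_lineages - half)
        pools = [[i for i in range(n_lineages) if deme_of[i] == d] for d in (0, 1)]
        for pool in pools:
            if pool:
                _coalesce_constant(pool, 0.0, times, parents, rng,
                                   stop=demography.split_depth)
        merged = pools[0] + pools[1]
        if len(merged) > 1:
            _coalesce_constant(merged, demography.split_depth, times, parents, rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown demography {demography!r}")

    n_nodes = len(times)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for child, par in parents.items():
        parent[child] = par
    return parent, np.asarray(times)


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    """Boolean leaf-membership vector below each node (nodes are time-ordered)."""
    n_nodes = parent.size
    below = np.zeros((n_nodes, n_leaves), dtype=bool)
    below[np.arange(n_leaves), np.arange(n_leaves)] = True
    for node in range(n_nodes):  # children always precede parents
        par = parent[node]
        if par >= 0:
            below[par] |= below[node]
    return list(below)


def simulate_locus(spec: SimulationSpec, locus_index: int) -> np.ndarray:
    """Simulate one locus; returns a (2*n_diploids, S) binary haplotype matrix.

    Columns are derived-allele indicators, one per mutation (infinite sites).
    The locus stream is seeded as (spec.seed, locus_index) so loci are
    independent and individually reproducible.
    """
    rng = np.random.default_rng((spec.seed, locus_index))
    return _simulate_locus_with_rng(spec, rng)


def _simulate_locus_with_rng(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    k = spec.n_haplotypes
    parent, times = simulate_tree(k, spec.demography, rng)
    blen = np.where(parent >= 0, times[parent.clip(min=0)] - times, 0.0)
    total = float(blen.sum())
    n_mut = rng.poisson(spec.theta_per_locus / 2.0 * total) if total > 0 else 0
    if n_mut == 0:
        return np.zeros((k, 0), dtype=np.int8)
    probs = blen / total
    branches = rng.choice(parent.size, size=n_mut, p=probs)
    below = _leaf_sets(parent, k)
    cols = np.stack([below[b][:k] for b in branches], axis=1)
    return cols.astype(np.int8)


def simulate_loci(spec: SimulationSpec) -> list[np.ndarray]:
    """All loci of a spec, in order."""
    return [simulate_locus(spec, i) for i in range(spec.n_loci)]


# ---------------------------------------------------------------------------
# VCF output

def write_vcf(haplotypes: Sequence[np.ndarray], path: str, *,
              depth: DepthModel | None = None,
              chrom_labels: dict[str, Sequence[int]] | None = None,
              locus_length: int = 10_000,
              seed: int = 0,
              sample_ids: Sequence[str] | None = None) -> int:
    """Write per-locus haplotype matrices as a diploid VCF v4.2.

    Consecutive haplotypes are paired into phased genotypes (haplotypes 2j and
    2j+1 form sample j).  `chrom_labels` maps chromosome name -> locus
    indices (a partition map, e.g. autosome/Z labels); loci on a chromosome
    occupy consecutive `locus_length` windows, so positions are strictly
    increasing within each chromosome.  Per-variant depth from `depth` is
    written as INFO/DP.  Returns the number of records written.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise ValueError("no loci given")
    n_hap = haplotypes[0].shape[0]
    if n_hap % 2 != 0:
        raise ValueError("odd number of haplotypes cannot be paired into diploids")
    n_samples = n_hap // 2
    if sample_ids is None:
        sample_ids = [f"sample{j}" for j in range(n_samples)]
    if chrom_labels is None:
        chrom_labels = {"chr1": list(range(len(haplotypes)))}
    seen = [i for idx in chrom_labels.values() for i in idx]
    if sorted(seen) != list(range(len(haplotypes))):
        raise ValueError("chrom_labels must partition the locus indices exactly")

    rng = np.random.default_rng((seed, 0xD0))
    dpm = depth if depth is not None else DepthModel()

    lines: list[str] = ["##fileformat=VCFv4.2"]
    for chrom, idx in chrom_labels.items():
        lines.append(f"##contig=<ID={chrom},length={len(idx) * locus_length}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))

    n_records = 0
    for chrom, idx in chrom_labels.items():
        for slot, locus in enumerate(idx):
            h = haplotypes[locus]
            s = h.shape[1]
            if s == 0:
                continue
            # distinct integer positions inside the locus window
            positions: set[int] = set()
            while len(positions) < s:
                need = s - len(positions)
                positions.update(rng.integers(1, locus_length + 1, size=need).tolist())
            pos_sorted = sorted(positions)
            order = np.arange(s)  # columns in mutation order, positions sorted
            dp = dpm.sample(s, rng)
            offset = slot * locus_length
            for col, pos in zip(order, pos_sorted):
                # per-sample depths: even multinomial split of the variant DP
                sample_dp = rng.multinomial(dp[col],
                                            np.full(n_samples, 1.0 / n_samples))
                gts = "\t".join(
                    f"{h[2 * j, col]}|{h[2 * j + 1, col]}:{sample_dp[j]}"
                    for j in range(n_samples)
                )
                lines.append(f"{chrom}\t{offset + pos}\t.\tA\tT\t.\tPASS\t"
                             f"DP={dp[col]}\tGT:DP\t{gts}")
                n_records += 1

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return n_records


# ---------------------------------------------------------------------------
# synteny fixtures

@dataclass
class RearrangementTruth:
    """Known query->reference segment map for synteny recovery tests.

    segments: query_chrom -> ordered list of (ref_chrom, ref_start, ref_end,
    orientation) with orientation in {'+', '-'}; segments must not overlap on
    the query.
    """

    segments: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    def validate(self) -> None:
        for q, segs in self.segments.items():
            by_ref: dict[str, list[tuple[int, int]]] = {}
            for (rc, s, e, o) in segs:
                if s > e or s < 1:
                    raise ValueError(f"bad segment {q}->{rc}:{s}-{e}")
                if o not in ("+", "-"):
                    raise ValueError(f"bad orientation {o!r}")
                by_ref.setdefault(rc, []).append((s, e))
            for rc, ivals in by_ref.items():
                ivals.sort()
                for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                    if s2 <= e1:
                        raise ValueError(
                            f"overlapping truth segments on {q}->{rc}: "
                            f"{s1}-{e1} and {s2}-..."
                        )

    def expected_assignment(self) -> dict[str, str]:
        """query chrom -> reference chrom with the greatest total span."""
        out = {}
        for q, segs in self.segments.items():
            spans: dict[str, int] = {}
            for (rc, s, e, _o) in segs:
                spans[rc] = spans.get(rc, 0) + (e - s + 1)
            out[q] = max(spans, key=lambda r: (spans[r], r))
        return out


COORDS_COLUMNS = ["ref_start", "ref_end", "query_start", "query_end",
                  "ref_alen", "query_alen", "identity", "ref_chrom", "query_chrom"]


def generate_coords(truth: RearrangementTruth, *,
                    identity_noise: float = 2.0,
                    min_block: int = 500,
                    spurious_rate: float = 0.0,
                    blocks_per_segment: int = 20,
                    seed: int = 0):
    """Emit a show-coords-style alignment table realising `truth`.

    Each truth segment is tiled by `blocks_per_segment` contiguous blocks with
    high identity (true alignments); spurious blocks (fraction `spurious_rate`
    of the true count) are short (< min_block) and low-identity (< 70%), so
    the standard distant-genome filters remove them.  Deterministic for a
    fixed seed.  Returns a pandas DataFrame in the coords dialect.
    """
    import pandas as pd

    truth.validate()
    rng = np.random.default_rng((seed, 0xC0))
    rows = []
    for q in sorted(truth.segments):
        q_cursor = 1
        for (rc, rs, re_, orient) in truth.segments[q]:
            seg_len = re_ - rs + 1
            nb = min(blocks_per_segment, max(1, seg_len // (2 * min_block)))
            # contiguous tiling with jittered breakpoints, each block > min_block
            edges = np.linspace(0, seg_len, nb + 1).astype(np.int64)
            jitter = rng.integers(-min_block // 4, min_block // 4 + 1, size=nb - 1) if nb > 1 else []
            for i, j in enumerate(jitter, start=1):
                edges[i] = np.clip(edges[i] + j, edges[i - 1] + min_block + 1,
                                   edges[i + 1] - 1 if i + 1 < nb else seg_len)
            for b in range(nb):
                b_rs = rs + int(edges[b])
                b_re = rs + int(edges[b + 1]) - 1
                blen = b_re - b_rs + 1
                if blen <= min_block:
                    continue
                ident = float(np.clip(rng.normal(94.0, identity_noise), 75.0, 99.9))
                q_s = q_cursor
                q_e = q_cursor + blen - 1
                if orient == "-":
                    q_s, q_e = q_e, q_s
                rows.append((b_rs, b_re, q_s, q_e, blen, blen, round(ident, 2), rc, q))
                q_cursor += blen
    n_true = len(rows)
    n_spur = int(round(spurious_rate * n_true))
    if n_spur:
        all_q = sorted(truth.segments)
        all_r = sorted({rc for segs in truth.segments.values() for (rc, *_x) in segs})
        for _ in range(n_spur):
            q = all_q[rng.integers(len(all_q))]
            rc = all_r[rng.integers(len(all_r))]
            blen = int(rng.integers(50, min_block))
            rs = int(rng.integers(1, 10_000_000))
            qs = int(rng.integers(1, 10_000_000))
            ident = round(float(rng.uniform(40.0, 69.9)), 2)
            rows.append((rs, rs + blen - 1, qs, qs + blen - 1, blen, blen, ident, rc, q))
    return pd.DataFrame(rows, columns=COORDS_COLUMNS)


def write_coords(df, path: str) -> None:
    """Serialize a coords DataFrame as the tab dialect (with header)."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mitogenome fixtures

_BASES = np.array(list("ACGT"))


def generate_mito_alignment(n_seqs: int, theta: float, length: int, seed: int = 0,
                            homopolymer_ranges: Sequence[tuple[int, int]] = ()
                            ) -> list[tuple[str, str]]:
    """Simulate an aligned set of mitogenome sequences.

    Sequences evolve on a constant-size coalescent tree under infinite sites:
    each mutation hits a distinct column and flips the carriers to a different
    base.  `homopolymer_ranges` (1-based inclusive) are overwritten with a
    monomorphic C run in every sequence, emulating the repeat / monomeric
    regions one masks before computing diversity.  Returns (name, sequence)
    pairs, equal length, uppercase A/C/G/T.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng((seed, 0xA1))
    ancestral = rng.integers(0, 4, size=length)
    blocked = np.zeros(length, dtype=bool)
    for (s, e) in homopolymer_ranges:
        if s < 1 or e > length or s > e:
            raise ValueError(f"range {s}-{e} out of bounds for length {length}")
        ancestral[s - 1:e] = 1  # 'C'
        blocked[s - 1:e] = True

    parent, times = simulate_tree(n_seqs, Constant(), rng)
    blen = np.where(parent >= 0, times[parent.clip(min=0)] - times, 0.0)
    total = float(blen.sum())
    n_mut = rng.poisson(theta / 2.0 * total) if (theta > 0 and total > 0) else 0

    seqs = np.tile(ancestral, (n_seqs, 1))
    if n_mut:
        free = np.flatnonzero(~blocked)
        if n_mut > free.size:
            raise ValueError("more mutations than available columns; raise length")
        cols = rng.choice(free, size=n_mut, replace=False)
        probs = blen / total
        branches = rng.choice(parent.size, size=n_mut, p=probs)
        below = _leaf_sets(parent, n_seqs)
        for col, br in zip(cols, branches):
            carriers = below[br][:n_seqs]
            derived = (ancestral[col] + rng.integers(1, 4)) % 4
            seqs[carriers, col] = derived
    return [(f"seq{i}", "".join(_BASES[seqs[i]])) for i in range(n_seqs)]


def write_fasta_alignment(records: Sequence[tuple[str, str]], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records],
        path, "fasta",
    )
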