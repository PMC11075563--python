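"""Mitogenome alignment statistics: masking, H, Hd, S, pi, theta, p-distance.

Columns listed in the mask (1-based inclusive ranges, union semantics) are
removed from every sequence before analysis — the usual treatment of
homopolymer and variable-repeat regions that the assembler cannot resolve.
Columns containing a gap or IUPAC ambiguity code in any sequence are excluded
from S and pi (complete deletion); the pairwise p-distance instead uses the
columns complete for each pair.  With no gaps or ambiguity, pi and the mean
p-distance coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .diversity import harmonic_number

__all__ = ["MaskedAlignment", "MitoSummary", "read_alignment", "read_mask",
           "apply_mask", "haplotype_stats", "mito_diversity"]

_VALID = frozenset("ACGT")


@dataclass
class MaskedAlignment:
    """Equal-length uppercase nucleotide sequences after column masking."""

    names: list[str]
    sequences: list[str]
    effective_length: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        if self.sequences and self.effective_length != len(self.sequences[0]):
            raise ValueError("effective_length inconsistent with sequences")

    @property
    def n(self) -> int:
        return len(self.sequences)

    def as_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


@dataclass(frozen=True)
class MitoSummary:
    H: int
    Hd: float
    S: int
    pi: float
    theta: float
    mean_p_distance: float
    n: int
    effective_length: int


def read_alignment(path: str) -> MaskedAlignment:
    """Read an aligned FASTA; sequences uppercased, equal length required."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    aln = MaskedAlignment(names, seqs, len(seqs[0]))
    return aln


def read_mask(path: str) -> list[tuple[int, int]]:
    """Mask ranges from a TSV of (name, start, end), 1-based inclusive."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["name", "start", "end"], comment="#")
    return [(int(r.start), int(r.end)) for r in df.itertuples()]


def apply_mask(aln: MaskedAlignment,
               ranges: list[tuple[int, int]]) -> MaskedAlignment:
    """Remove masked columns (1-based inclusive ranges, overlaps unioned)."""
    length = len(aln.sequences[0]) if aln.sequences else 0
    drop = np.zeros(length, dtype=bool)
    for (s, e) in ranges:
        if s < 1 or e > length or s > e:
            raise ValueError(f"mask range {s}-{e} out of bounds (1..{length})")
        drop[s - 1:e] = True
    keep = ~drop
    seqs = ["".join(np.array(list(s))[keep]) for s in aln.sequences]
    return MaskedAlignment(list(aln.names), seqs, int(keep.sum()))


def haplotype_stats(aln: MaskedAlignment) -> tuple[int, float]:
    """Haplotype count H and diversity Hd = n (1 - sum p_k^2) / (n - 1)."""
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    _, counts = np.unique(aln.sequences, return_counts=True)
    p = counts / n
    hd = n * (1.0 - float(np.sum(p ** 2))) / (n - 1)
    return int(counts.size), hd


def mito_diversity(aln: MaskedAlignment) -> MitoSummary:
    """All summary statistics of the (masked) alignment.

    S and pi use columns where every sequence has an unambiguous base
    (complete deletion); theta = S / (a_{n-1} * L) with n the number of
    sequences and L the post-masking alignment length; the p-distance for a
    pair uses the columns unambiguous in that pair.
    """
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    L = aln.effective_length
    if L == 0:
        raise ValueError("alignment has length 0")
    arr = aln.as_array()
    valid = np.isin(arr, list(_VALID))
    complete = valid.all(axis=0)

    sub = arr[:, complete]
    n_states = np.array([len(set(col)) for col in sub.T]) if sub.size else np.array([])
    S = int(np.sum(n_states >= 2))

    # pi: mean pairwise differences over complete columns, per masked-length site
    diffs = []
    pdists = []
    for a, b in combinations(range(n), 2):
        d_complete = int(np.sum(sub[a] != sub[b]))
        diffs.append(d_complete)
        pair_ok = valid[a] & valid[b]
        n_comp = int(pair_ok.sum())
        d_pair = int(np.sum((arr[a] != arr[b]) & pair_ok))
        pdists.append(d_pair / n_comp if n_comp else 0.0)
    pi = float(np.mean(diffs)) / L if diffs else 0.0

    H, Hd = haplotype_stats(aln)
    return MitoSummary(
        H=H, Hd=Hd, S=S, pi=pi,
        theta=S / (harmonic_number(n - 1) * L),
        mean_p_distance=float(np.mean(pdists)) if pdists else 0.0,
        n=n, effective_length=L,
    )
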