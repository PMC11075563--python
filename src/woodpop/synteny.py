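"""Synteny-based chromosome assignment from whole-genome alignment blocks.

The procedure mirrors the standard comparative workflow for a fragmented
avian assembly aligned to a model reference (e.g. chicken): filter alignment
blocks on identity and length, assign each query chromosome to the reference
chromosome with the greatest total aligned overlap and rename it accordingly,
keep chromosome pairs supported by enough unique links for plotting, and
order query chromosomes along each reference chromosome by the median
position of their hits.

Filter strictness follows the usual phrasing: identity and length thresholds
are strict (>), the link-count floor is inclusive (>=).  Two presets are
provided: "distant" (70% / 500 bp, for a diverged reference) and "close"
(80% / 10 kb, for a close relative where repeat-driven noise dominates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import COORDS_COLUMNS

__all__ = ["SyntenyConfig", "parse_coords", "filter_blocks",
           "assign_chromosomes", "retain_by_links", "order_segments"]


@dataclass(frozen=True)
class SyntenyConfig:
    min_identity: float = 70.0   # percent, strict >
    min_length: int = 500        # bp on the reference, strict >
    min_links: int = 500         # unique blocks per chromosome pair, inclusive >=

    def __post_init__(self) -> None:
        if self.min_identity <= 0 or self.min_length <= 0 or self.min_links <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def preset(cls, name: str, min_links: int = 500) -> "SyntenyConfig":
        if name == "distant":
            return cls(70.0, 500, min_links)
        if name == "close":
            return cls(80.0, 10_000, min_links)
        raise ValueError(f"unknown preset {name!r}")


def parse_coords(path: str) -> pd.DataFrame:
    """Parse a show-coords-style tab table into an AlignmentBlock frame.

    Header lines are tolerated; malformed rows are rejected with their line
    numbers.  Columns: ref_start, ref_end, query_start, query_end, ref_alen,
    query_alen, identity, ref_chrom, query_chrom.  Reversed query coordinates
    (start > end) mark minus-strand alignments and are preserved.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == COORDS_COLUMNS[0] or line.startswith(("#", "=", "/")):
                continue  # header / banner lines
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected >=9 tab fields, "
                                 f"got {len(parts)}")
            try:
                rec = {
                    "ref_start": int(parts[0]), "ref_end": int(parts[1]),
                    "query_start": int(parts[2]), "query_end": int(parts[3]),
                    "ref_alen": int(parts[4]), "query_alen": int(parts[5]),
                    "identity": float(parts[6]),
                    "ref_chrom": parts[7], "query_chrom": parts[8],
                }
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable field "
                                 f"({exc})") from exc
            if not (0.0 <= rec["identity"] <= 100.0):
                raise ValueError(f"{path}:{lineno}: identity "
                                 f"{rec['identity']} outside [0, 100]")
            if rec["ref_alen"] <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive block length")
            rows.append(rec)
    return pd.DataFrame(rows, columns=COORDS_COLUMNS)


def filter_blocks(blocks: pd.DataFrame, cfg: SyntenyConfig) -> pd.DataFrame:
    """Keep blocks with identity > min_identity and length > min_length."""
    keep = (blocks["identity"] > cfg.min_identity) & \
           (blocks["ref_alen"] > cfg.min_length)
    return blocks.loc[keep].reset_index(drop=True)


def _unique_links(blocks: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate links by their exact (ref interval, query interval)."""
    return blocks.drop_duplicates(
        subset=["ref_chrom", "ref_start", "ref_end",
                "query_chrom", "query_start", "query_end"])


def assign_chromosomes(blocks_filtered: pd.DataFrame) -> pd.DataFrame:
    """Assign each query chromosome to its greatest-overlap reference chromosome.

    Overlap is the total alignment length on the reference.  Ties break by
    larger unique-link count, then lexicographically smaller reference label.
    Query chromosomes sharing a reference assignment (fission, the norm in a
    more fragmented karyotype) are renamed with 'a', 'b', ... suffixes in
    decreasing overlap order.  Returns a frame indexed by query_chrom with
    columns ref_chrom, total_overlap_bp, n_links, new_name.
    """
    if blocks_filtered.empty:
        return pd.DataFrame(
            columns=["query_chrom", "ref_chrom", "total_overlap_bp",
                     "n_links", "new_name"]).set_index("query_chrom")
    uniq = _unique_links(blocks_filtered)
    per_pair = uniq.groupby(["query_chrom", "ref_chrom"]).agg(
        total_overlap_bp=("ref_alen", "sum"),
        n_links=("ref_alen", "size"),
    ).reset_index()

    chosen = []
    for q, grp in per_pair.groupby("query_chrom"):
        grp = grp.sort_values(
            by=["total_overlap_bp", "n_links", "ref_chrom"],
            ascending=[False, False, True], kind="mergesort")
        chosen.append(grp.iloc[0])
    table = pd.DataFrame(chosen).reset_index(drop=True)

    # rename: suffix collisions by descending overlap
    names = {}
    for ref, grp in table.groupby("ref_chrom"):
        grp = grp.sort_values(["total_overlap_bp", "query_chrom"],
                              ascending=[False, True], kind="mergesort")
        if len(grp) == 1:
            names[grp.iloc[0]["query_chrom"]] = str(ref)
        else:
            for i, (_, row) in enumerate(grp.iterrows()):
                names[row["query_chrom"]] = f"{ref}{chr(ord('a') + i)}"
    table["new_name"] = table["query_chrom"].map(names)
    return table.sort_values("query_chrom").set_index("query_chrom")


def retain_by_links(table: pd.DataFrame, blocks_filtered: pd.DataFrame,
                    cfg: SyntenyConfig) -> pd.DataFrame:
    """Unique links of assigned pairs with at least min_links support.

    Returns the deduplicated link rows (circos-ready) restricted to
    (query, assigned ref) pairs whose unique-link count >= min_links.
    """
    if table.empty or blocks_filtered.empty:
        return blocks_filtered.iloc[0:0]
    uniq = _unique_links(blocks_filtered)
    assigned = table["ref_chrom"].to_dict()
    on_pair = uniq[
        uniq.apply(lambda r: assigned.get(r["query_chrom"]) == r["ref_chrom"],
                   axis=1)
    ]
    counts = on_pair.groupby("query_chrom").size()
    keep_q = counts[counts >= cfg.min_links].index
    return on_pair[on_pair["query_chrom"].isin(keep_q)].reset_index(drop=True)


def _natural_key(label: str):
    import re
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label)]


def order_segments(blocks_filtered: pd.DataFrame,
                   table: pd.DataFrame) -> pd.DataFrame:
    """Order query chromosomes by median reference hit position.

    For each assigned query chromosome the median of the reference-side block
    midpoints (on its assigned reference chromosome) is computed; query
    chromosomes are then sorted by (reference chromosome, median position).
    Deterministic regardless of input row order.
    """
    if table.empty:
        return pd.DataFrame(columns=["query_chrom", "ref_chrom",
                                     "median_ref_pos", "rank"])
    rows = []
    for q, row in table.iterrows():
        ref = row["ref_chrom"]
        hits = blocks_filtered[
            (blocks_filtered["query_chrom"] == q)
            & (blocks_filtered["ref_chrom"] == ref)]
        mid = (hits["ref_start"] + hits["ref_end"]) / 2.0
        rows.append({"query_chrom": q, "ref_chrom": ref,
                     "median_ref_pos": float(np.median(mid))})
    out = pd.DataFrame(rows)
    ref_order = {c: i for i, c in
                 enumerate(sorted(out["ref_chrom"].unique(), key=_natural_key))}
    out["_ref_rank"] = out["ref_chrom"].map(ref_order)
    out = (out.sort_values(["_ref_rank", "median_ref_pos", "query_chrom"],
                           kind="mergesort")
           .drop(columns="_ref_rank").reset_index(drop=True))
    out["rank"] = np.arange(len(out))
    return out
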