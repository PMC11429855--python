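"""Small genomic-interval helpers shared across modules.

Intervals are rows of DataFrames with columns (chrom, start, end), 0-based
half-open. These are deliberately simple sorted-array routines; brute-force
quadratic equivalents live in the test suite as oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals that overlap, or lie within ``gap`` bp of each other."""
    if df.empty:
        return df.copy().reset_index(drop=True)
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_length(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame, pad: int = 0) -> np.ndarray:
    """Boolean per query row: does it intersect any target interval (padded)?"""
    hits = np.zeros(len(query), dtype=bool)
    by_chrom = {c: g for c, g in targets.groupby("chrom")}
    for pos, row in enumerate(query.itertuples()):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        s = grp["start"].to_numpy() - pad
        e = grp["end"].to_numpy() + pad
        hits[pos] = bool(np.any((s < row.end) & (e > row.start)))
    return hits


def count_overlaps(query: pd.DataFrame, targets: pd.DataFrame, pad: int = 0) -> np.ndarray:
    """Number of target intervals intersecting each query interval (padded)."""
    counts = np.zeros(len(query), dtype=int)
    by_chrom = {c: g for c, g in targets.groupby("chrom")}
    for pos, row in enumerate(query.itertuples()):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        s = grp["start"].to_numpy() - pad
        e = grp["end"].to_numpy() + pad
        counts[pos] = int(np.sum((s < row.end) & (e > row.start)))
    return counts


def reciprocal_overlap_match(
    a: pd.DataFrame, b: pd.DataFrame, min_frac: float = 0.5
) -> np.ndarray:
    """Per row of ``a``: index into ``b`` of a reciprocal-overlap match, or -1.

    A match requires the overlap to cover at least ``min_frac`` of *both*
    intervals; among candidates the largest overlap wins.
    """
    match = np.full(len(a), -1, dtype=int)
    by_chrom = {c: g for c, g in b.groupby("chrom")}
    for pos, row in enumerate(a.itertuples()):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        ov = np.minimum(e, row.end) - np.maximum(s, row.start)
        len_a = row.end - row.start
        ok = (ov >= min_frac * len_a) & (ov >= min_frac * (e - s))
        if ok.any():
            best = np.flatnonzero(ok)[np.argmax(ov[ok])]
            match[pos] = int(grp.index[best])
    return match


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names) + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or list(df.columns)
    df[cols].to_csv(path, sep="\t", header=False, index=False)
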