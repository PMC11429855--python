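"""Pairwise MCD projection, O/E pile-ups and focal-enrichment profiles.

All unordered MCD pairs are projected in cis and trans; O/E snippets centred
on the summit pair are stacked into mean pile-up maps, and each pair gets a
focal score: mean O/E over a small central zone divided by the mean over a
surrounding square ring. Cis snippets use the distance expectation, trans
snippets the per-chromosome-pair expectation, so 1 means background in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import OEMatrix


def project_pairs(
    mcds: pd.DataFrame,
    min_sep: int = 0,
    include_trans: bool = True,
) -> pd.DataFrame:
    """All unordered MCD pairs (a < b by table order) with separation bookkeeping.

    Cis pairs closer than ``min_sep`` (summit to summit, bp) are dropped.
    The attrs dict on the result records cis/trans/dropped counts; their sum
    is C(N, 2).
    """
    if len(mcds) < 2:
        raise ValueError("need at least 2 MCDs to project pairs")
    mcds = mcds.reset_index(drop=True)
    summits = mcds["summit"].to_numpy() if "summit" in mcds else (
        (mcds["start"].to_numpy() + mcds["end"].to_numpy()) // 2
    )
    chroms = mcds["chrom"].to_numpy()
    a, b = np.triu_indices(len(mcds), k=1)
    cis = chroms[a] == chroms[b]
    sep = np.where(cis, np.abs(summits[a] - summits[b]), -1)
    keep = (~cis & include_trans) | (cis & (sep >= min_sep))
    df = pd.DataFrame(
        {
            "mcd_a": a[keep],
            "mcd_b": b[keep],
            "cis": cis[keep],
            "separation": sep[keep],
        }
    )
    n_total = len(a)
    df.attrs["n_cis"] = int((cis & keep).sum())
    df.attrs["n_trans"] = int((~cis & keep).sum())
    df.attrs["n_dropped"] = int(n_total - keep.sum())
    df.attrs["n_total"] = n_total
    return df


@dataclass
class Pileup:
    """Stacked mean O/E map around projected pairs."""

    half_width: int
    mean_map: np.ndarray  # (2h+1, 2h+1)
    n_snippets: int
    n_dropped: int

    @property
    def central_value(self) -> float:
        h = self.half_width
        return float(self.mean_map[h, h])


def _snippet(
    oe: OEMatrix, mcds: pd.DataFrame, pair, half_width: int
) -> np.ndarray | None:
    bs = oe.bins.bin_size
    ra = mcds.iloc[int(pair.mcd_a)]
    rb = mcds.iloc[int(pair.mcd_b)]
    sa = int(ra["summit"] if "summit" in mcds else (ra["start"] + ra["end"]) // 2)
    sb = int(rb["summit"] if "summit" in mcds else (rb["start"] + rb["end"]) // 2)
    ia, ib = sa // bs, sb // bs
    c1, c2 = ra["chrom"], rb["chrom"]
    if not oe.has_block(c1, c2):
        return None
    block = oe.block(c1, c2)
    h = half_width
    if c1 == c2 and ia > ib:
        ia, ib = ib, ia
    if ia - h < 0 or ib - h < 0 or ia + h >= block.shape[0] or ib + h >= block.shape[1]:
        return None
    if c1 == c2 and (ib - h) - (ia + h) <= 0:  # window crosses the diagonal
        return None
    return block[ia - h : ia + h + 1, ib - h : ib + h + 1]


def stack_pileup(
    oe: OEMatrix,
    mcds: pd.DataFrame,
    pairs: pd.DataFrame,
    half_width: int = 10,
    max_invalid_frac: float = 0.5,
) -> Pileup:
    """Elementwise-mean O/E map over snippets centred on pair summits.

    Snippets falling off the matrix, crossing the cis diagonal, or with more
    than ``max_invalid_frac`` undefined pixels are dropped. Raises if no
    snippet survives, naming the responsible filter.
    """
    size = 2 * half_width + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = n_bounds = n_invalid = 0
    mcds = mcds.reset_index(drop=True)
    for pair in pairs.itertuples():
        snip = _snippet(oe, mcds, pair, half_width)
        if snip is None:
            n_bounds += 1
            continue
        finite = np.isfinite(snip)
        if finite.mean() < 1 - max_invalid_frac:
            n_invalid += 1
            continue
        acc[finite] += snip[finite]
        cnt += finite
        n_used += 1
    if n_used == 0:
        reason = "window bounds / diagonal" if n_bounds >= n_invalid else "invalid-pixel fraction"
        raise ValueError(f"no usable snippets: all dropped by {reason} filter")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return Pileup(half_width, mean, n_used, n_bounds + n_invalid)


def focal_enrichment_map(
    snippet: np.ndarray,
    peak_halfwidth: int = 1,
    ring_inner: int = 3,
    ring_outer: int = 5,
) -> float:
    """Central-zone mean over square-ring mean of one snippet (NaN-aware).

    Returns NaN when either zone is empty after masking.
    """
    if not ring_outer > ring_inner or ring_inner < peak_halfwidth:
        raise ValueError("require ring_outer > ring_inner >= peak_halfwidth")
    h = snippet.shape[0] // 2
    di, dj = np.meshgrid(
        np.arange(snippet.shape[0]) - h, np.arange(snippet.shape[1]) - h, indexing="ij"
    )
    cheb = np.maximum(np.abs(di), np.abs(dj))
    centre = cheb <= peak_halfwidth
    ring = (cheb > ring_inner) & (cheb <= ring_outer)
    c = snippet[centre]
    r = snippet[ring]
    c = c[np.isfinite(c)]
    r = r[np.isfinite(r)]
    if c.size == 0 or r.size == 0 or r.mean() <= 0:
        return np.nan
    return float(c.mean() / r.mean())


def score_pairs(
    oe: OEMatrix,
    mcds: pd.DataFrame,
    pairs: pd.DataFrame,
    peak_halfwidth: int = 1,
    ring_inner: int = 3,
    ring_outer: int = 5,
    half_width: int | None = None,
    score_col: str = "focal_score",
) -> pd.DataFrame:
    """Attach a focal-enrichment score to every pair (NaN where undefined)."""
    if half_width is None:
        half_width = ring_outer
    scores = np.full(len(pairs), np.nan)
    mcds = mcds.reset_index(drop=True)
    for k, pair in enumerate(pairs.itertuples()):
        snip = _snippet(oe, mcds, pair, half_width)
        if snip is not None:
            scores[k] = focal_enrichment_map(snip, peak_halfwidth, ring_inner, ring_outer)
    out = pairs.copy()
    out[score_col] = scores
    return out


def _bootstrap_ci(values: np.ndarray, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


def distance_profile(
    pairs: pd.DataFrame,
    strata: list[int],
    score_cols: list[str],
    group_keys: list[str] | None = None,
    ratio_of: tuple[str, str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean focal score per distance stratum (x optional group keys).

    ``strata`` are bp edges for cis separations; trans pairs fall in a "trans"
    stratum. Reports count, mean and a bootstrap 95% CI per score column, and
    a per-stratum ratio ``ratio_of[0]/ratio_of[1]`` when requested. Empty
    strata are reported with count 0 and NaN means.
    """
    df = pairs.copy()
    edges = list(strata)
    labels = [f"{edges[k]}-{edges[k+1]}" for k in range(len(edges) - 1)]
    stratum = pd.Series(pd.NA, index=df.index, dtype="object")
    cis = df["cis"].astype(bool)
    cut = pd.cut(df.loc[cis, "separation"], bins=edges, labels=labels, right=False)
    stratum.loc[cis] = cut.astype("object")
    stratum.loc[~cis] = "trans"
    df["stratum"] = stratum
    keys = ["stratum"] + (group_keys or [])
    all_strata = labels + ["trans"]
    rows = []
    group_values = (
        [tuple()] if not group_keys
        else list(df.groupby(group_keys, sort=True).groups.keys())
    )
    group_values = [g if isinstance(g, tuple) else (g,) for g in group_values]
    for s in all_strata:
        for gvals in group_values:
            sel = df["stratum"] == s
            for key, val in zip(group_keys or [], gvals):
                sel &= df[key] == val
            sub = df[sel]
            row = {"stratum": s}
            row.update(dict(zip(group_keys or [], gvals)))
            row["n"] = int(len(sub))
            for col in score_cols:
                vals = sub[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[f"mean_{col}"] = float(vals.mean()) if vals.size else np.nan
                if vals.size > 1:
                    lo, hi = _bootstrap_ci(vals, n_boot, seed)
                else:
                    lo = hi = np.nan
                row[f"ci_lo_{col}"], row[f"ci_hi_{col}"] = lo, hi
            if ratio_of is not None:
                a, b = row.get(f"mean_{ratio_of[0]}"), row.get(f"mean_{ratio_of[1]}")
                row["ratio"] = a / b if (a is not None and b and np.isfinite(b)) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
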