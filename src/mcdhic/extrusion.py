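"""Convergent-CTCF loops, nested-loop extrusion domains (TADs), and pruning classes.

A loop is an anchor pair on one chromosome with convergent CTCF motif
orientations (+ then -). An extrusion domain is the interval spanned by the
outermost loop of a group of loops nested by containment; non-nested
overlapping loops deliberately yield separate domains. Each cis MCD pair is
classified by (i) whether a single loop's two anchors hit the two MCDs
("loop-exact"), (ii) whether at least one MCD overlaps any loop anchor, and
(iii) whether both MCD summits fall inside one common extrusion domain
(intra-TAD) or not (inter-TAD). Trans pairs short-circuit to "trans".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import OEMatrix
from .pairs import distance_profile

PRUNING_CLASSES = (
    "loop-exact",
    "anchor>=1 & intra-TAD",
    "anchor>=1 & inter-TAD",
    "anchor=0 & intra-TAD",
    "anchor=0 & inter-TAD",
    "trans",
)


def read_loops_bedpe(path) -> pd.DataFrame:
    """BEDPE with strand columns: chrom1 start1 end1 chrom2 start2 end2 [name score] strand1 strand2."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if ncol >= 10:
        names += ["name", "score", "strand1", "strand2"]
    elif ncol >= 8:
        names += ["strand1", "strand2"]
    df.columns = names + [f"col{k}" for k in range(len(names), ncol)]
    out = pd.DataFrame(
        {
            "chrom": df["chrom1"],
            "start1": df["start1"],
            "end1": df["end1"],
            "start2": df["start2"],
            "end2": df["end2"],
            "strand1": df.get("strand1", "+"),
            "strand2": df.get("strand2", "-"),
        }
    )
    bad = (df["chrom1"] != df["chrom2"]).to_numpy()
    if bad.any():
        raise ValueError("trans anchor pairs in loop BEDPE")
    return out


def is_convergent(loops: pd.DataFrame) -> np.ndarray:
    return ((loops["strand1"] == "+") & (loops["strand2"] == "-")).to_numpy()


def loop_strength(
    oe: OEMatrix, loops: pd.DataFrame, window: int = 200_000, resolution: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean O/E over the 3x3 central zone of the motif-centred window, per loop.

    Returns the loop table with a ``strength`` column (NaN where an anchor
    falls in a masked bin) and the stacked mean snippet over scored loops.
    """
    bs = resolution or oe.bins.bin_size
    h = window // (2 * bs)
    size = 2 * h + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    strengths = np.full(len(loops), np.nan)
    out = loops.copy().reset_index(drop=True)
    for k, row in enumerate(out.itertuples()):
        block = oe.block(row.chrom, row.chrom)
        n = block.shape[0]
        i = (row.start1 + row.end1) // 2 // bs
        j = (row.start2 + row.end2) // 2 // bs
        if i - h < 0 or j + h >= n:
            continue
        snip = block[i - h : i + h + 1, j - h : j + h + 1]
        centre = snip[h - 1 : h + 2, h - 1 : h + 2]
        finite_c = np.isfinite(centre)
        if finite_c.any():
            strengths[k] = float(centre[finite_c].mean())
        finite = np.isfinite(snip)
        acc[finite] += snip[finite]
        cnt += finite
    out["strength"] = strengths
    with np.errstate(invalid="ignore", divide="ignore"):
        stack = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return out, stack


def nest_to_domains(loops: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Group loops by span containment; outermost loops define the domains.

    Loop a contains loop b iff b's span [start1, end2) lies within a's span.
    Maximal loops (contained in no other) are domain roots; every other loop
    joins the containing root with the smallest span (leftmost on ties).
    Returns (domain table with member counts, root assignment per loop).
    Output is invariant to input order: loops are sort-canonicalised first.
    """
    if loops.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_loops"]), np.array([], int)
    canon = loops.reset_index(drop=True).sort_values(
        ["chrom", "start1", "end2"], kind="stable"
    )
    order = canon.index.to_numpy()
    canon = canon.reset_index(drop=True)
    assign = np.full(len(canon), -1, dtype=int)
    for chrom, grp in canon.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        lo = grp["start1"].to_numpy()
        hi = grp["end2"].to_numpy()
        span = hi - lo
        # strict containment; on identical spans the canonically-first loop wins
        def contains(x: int, y: int) -> bool:
            if lo[x] > lo[y] or hi[x] < hi[y]:
                return False
            if span[x] > span[y]:
                return True
            return lo[x] == lo[y] and hi[x] == hi[y] and x < y
        for a_pos, a in enumerate(idx):
            if not any(contains(x, a_pos) for x in range(len(idx)) if x != a_pos):
                assign[a] = a  # root
        for a_pos, a in enumerate(idx):
            if assign[a] == a:
                continue
            cand = [x for x in range(len(idx))
                    if assign[idx[x]] == idx[x] and lo[x] <= lo[a_pos] and hi[x] >= hi[a_pos]]
            best = min(cand, key=lambda x: (span[x], lo[x]))
            assign[a] = idx[best]
    rows = []
    root_ids = np.unique(assign)
    root_of = np.empty(len(canon), dtype=int)
    for r_out, r in enumerate(root_ids):
        members = np.flatnonzero(assign == r)
        rows.append(
            {
                "chrom": canon.loc[r, "chrom"],
                "start": int(canon.loc[r, "start1"]),
                "end": int(canon.loc[r, "end2"]),
                "n_loops": int(len(members)),
            }
        )
        root_of[members] = r_out
    domains = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    remap = {old: new for new, old in enumerate(domains.index)}
    domains = domains.reset_index(drop=True)
    root_of = np.array([remap[r] for r in root_of])
    # undo the canonical sort so assignment matches the input row order
    assignment = np.empty(len(loops), dtype=int)
    assignment[order] = root_of
    return domains, assignment


def anchor_overlap_count(mcd_row, loops: pd.DataFrame, pad: int = 0) -> int:
    """Number of distinct loop anchors whose (padded) interval hits the MCD."""
    count = 0
    sub = loops[loops["chrom"] == mcd_row["chrom"]]
    for _, loop in sub.iterrows():
        for s_col, e_col in (("start1", "end1"), ("start2", "end2")):
            if loop[s_col] - pad < mcd_row["end"] and loop[e_col] + pad > mcd_row["start"]:
                count += 1
    return count


def _anchors_frame(loops: pd.DataFrame) -> pd.DataFrame:
    a1 = loops[["chrom", "start1", "end1"]].rename(columns={"start1": "start", "end1": "end"})
    a2 = loops[["chrom", "start2", "end2"]].rename(columns={"start2": "start", "end2": "end"})
    a1 = a1.assign(loop_id=np.arange(len(loops)), side=1)
    a2 = a2.assign(loop_id=np.arange(len(loops)), side=2)
    return pd.concat([a1, a2], ignore_index=True)


def classify_pairs(
    pairs: pd.DataFrame,
    mcds: pd.DataFrame,
    loops: pd.DataFrame,
    domains: pd.DataFrame,
    pad: int = 0,
) -> pd.DataFrame:
    """Assign one of the six pruning classes to every pair (exhaustive partition).

    Loop-exact: some loop's two anchors respectively intersect MCD a and MCD b.
    Otherwise the anchor axis (>=1 anchor hit over the two MCDs, or 0) crosses
    the TAD axis: intra-TAD iff both summits fall inside one common extrusion
    domain. Straddling summits are inter-TAD by this rule.
    """
    mcds = mcds.reset_index(drop=True)
    anchors = _anchors_frame(loops)
    n_mcd = len(mcds)
    # per-MCD: set of loop ids hit per side, and anchor-hit count
    side_hits: list[dict[int, set]] = []
    any_anchor = np.zeros(n_mcd, dtype=bool)
    for _, m in mcds.iterrows():
        sub = anchors[anchors["chrom"] == m["chrom"]]
        hit = (sub["start"] - pad < m["end"]) & (sub["end"] + pad > m["start"])
        hits = sub[hit]
        side_hits.append(
            {1: set(hits.loc[hits["side"] == 1, "loop_id"]),
             2: set(hits.loc[hits["side"] == 2, "loop_id"])}
        )
        any_anchor[len(side_hits) - 1] = bool(len(hits))
    # per-MCD summit domain membership
    dom_of = np.full(n_mcd, -1, dtype=int)
    for k, m in mcds.iterrows():
        summit = int(m["summit"]) if "summit" in mcds else (m["start"] + m["end"]) // 2
        sub = domains[(domains["chrom"] == m["chrom"])
                      & (domains["start"] <= summit) & (domains["end"] > summit)]
        if len(sub):
            # innermost containing domain for determinism (smallest span)
            spans = sub["end"] - sub["start"]
            dom_of[k] = int(sub.index[np.argmin(spans.to_numpy())])
    out = pairs.copy()
    classes = []
    for pair in out.itertuples():
        if not pair.cis:
            classes.append("trans")
            continue
        a, b = int(pair.mcd_a), int(pair.mcd_b)
        exact = (side_hits[a][1] & side_hits[b][2]) | (side_hits[a][2] & side_hits[b][1])
        if exact:
            classes.append("loop-exact")
            continue
        anchored = "anchor>=1" if (any_anchor[a] or any_anchor[b]) else "anchor=0"
        intra = dom_of[a] >= 0 and dom_of[a] == dom_of[b]
        classes.append(f"{anchored} & {'intra' if intra else 'inter'}-TAD")
    out["pruning_class"] = classes
    return out


def pruning_summary(
    classified_pairs: pd.DataFrame,
    strata: list[int],
    condition_cols: dict[str, str],
    ratio_of: tuple[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per class x stratum table of mean focal scores across conditions.

    ``condition_cols`` maps condition name -> score column of
    ``classified_pairs``. Reports counts, means, bootstrap CIs, and the
    condition ratio ``ratio_of[0]/ratio_of[1]`` per cell. Empty cells are
    reported with count 0, never fatal.
    """
    score_cols = list(condition_cols.values())
    ratio_cols = tuple(condition_cols[c] for c in ratio_of) if ratio_of else None
    return distance_profile(
        classified_pairs,
        strata,
        score_cols,
        group_keys=["pruning_class"],
        ratio_of=ratio_cols,
        seed=seed,
    )
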