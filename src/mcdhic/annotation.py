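"""cCRE and ATAC-peak set logic.

Three condition-tagged peak sets (prometaphase, G1-control, G1-depleted) are
merged into union peaks whose membership vector defines seven categories;
"bookmarked" = present in all three. Element classes (promoter/enhancer/CTCF)
come from input annotations, never from sequence. Fold enrichment compares
element densities (per Mb) in target vs background interval sets; valency
counts the significant pairwise interactions each MCD engages in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import count_overlaps, merge_intervals, overlaps_any

CONDITIONS = ("prometaphase", "G1-control", "G1-depleted")

CATEGORY_NAMES = {
    (True, True, True): "bookmarked",
    (False, True, False): "G1-control-only",
    (True, False, False): "prometaphase-only",
    (False, False, True): "G1-depleted-only",
    (False, True, True): "control+depleted",
    (True, True, False): "prometaphase+control",
    (True, False, True): "prometaphase+depleted",
}


def intersect_peak_sets(
    peak_sets: dict[str, pd.DataFrame],
    merge_gap: int = 0,
    restrict_to: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union peaks with membership categories, plus a category-fraction table.

    Union peaks are built by merging overlapping (or gap <= ``merge_gap``)
    intervals across all three sets; each union peak records which condition
    sets contribute to it. With ``restrict_to`` (e.g. MCD intervals) the
    fraction table is additionally computed over union peaks overlapping those
    intervals. Fractions sum to 1 in every table column.
    """
    missing = [c for c in CONDITIONS if c not in peak_sets]
    if missing:
        raise ValueError(f"missing condition sets: {missing}")
    pooled = pd.concat(
        [peak_sets[c][["chrom", "start", "end"]] for c in CONDITIONS], ignore_index=True
    )
    if pooled.empty:
        raise ValueError("empty union: no peaks in any set")
    union = merge_intervals(pooled, gap=merge_gap)
    member = {c: overlaps_any(union, peak_sets[c], pad=merge_gap) for c in CONDITIONS}
    cats = [
        CATEGORY_NAMES[(bool(member["prometaphase"][k]),
                        bool(member["G1-control"][k]),
                        bool(member["G1-depleted"][k]))]
        for k in range(len(union))
    ]
    union = union.assign(category=cats)
    tables = {"genome-wide": union["category"].value_counts(normalize=True)}
    if restrict_to is not None:
        at_target = union[overlaps_any(union, restrict_to)]
        if len(at_target):
            tables["restricted"] = at_target["category"].value_counts(normalize=True)
    fractions = (
        pd.DataFrame(tables).reindex(sorted(CATEGORY_NAMES.values())).fillna(0.0)
    )
    return union, fractions


def _total_length_mb(intervals: pd.DataFrame) -> float:
    merged = merge_intervals(intervals)
    return float((merged["end"] - merged["start"]).sum()) / 1e6


def fold_enrichment(
    elements: pd.DataFrame,
    targets: pd.DataFrame,
    background: pd.DataFrame,
    class_col: str = "cre_class",
) -> pd.DataFrame:
    """Per-class density (elements/Mb) in targets over density in background.

    Element membership is interval intersection. Classes with zero background
    density get a NaN fold (flagged by the ``defined`` column).
    """
    if background.empty:
        raise ValueError("empty background")
    t_mb = _total_length_mb(targets)
    b_mb = _total_length_mb(background)
    in_t = overlaps_any(elements, targets)
    in_b = overlaps_any(elements, background)
    rows = []
    for cls, grp in elements.groupby(class_col, sort=True):
        idx = grp.index.to_numpy()
        d_t = in_t[elements.index.get_indexer(idx)].sum() / t_mb if t_mb > 0 else np.nan
        d_b = in_b[elements.index.get_indexer(idx)].sum() / b_mb if b_mb > 0 else np.nan
        defined = bool(d_b and np.isfinite(d_b))
        rows.append(
            {
                "cre_class": cls,
                "density_target": d_t,
                "density_background": d_b,
                "fold": d_t / d_b if defined else np.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def mcd_bookmark_coverage(
    mcds: pd.DataFrame, elements: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Fraction of MCDs overlapping >= 1 bookmarked promoter/enhancer element.

    ``elements`` should already be filtered to the qualifying set (bookmarked
    promoters and enhancers). Also returns per-MCD element counts.
    """
    if mcds.empty:
        return 0.0, pd.Series(dtype=int)
    counts = count_overlaps(mcds.reset_index(drop=True), elements)
    return float((counts > 0).mean()), pd.Series(counts)


def valency(
    mcds: pd.DataFrame,
    scored_pairs: pd.DataFrame,
    score_col: str = "focal_score",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Number of qualifying pairwise interactions each MCD engages in.

    A pair qualifies when its focal score is finite and >= ``threshold``.
    The sum of valencies equals exactly twice the number of qualifying pairs.
    """
    mcds = mcds.reset_index(drop=True)
    v = np.zeros(len(mcds), dtype=int)
    scores = scored_pairs[score_col].to_numpy(dtype=float)
    ok = np.isfinite(scores) & (scores >= threshold)
    for pair in scored_pairs[ok].itertuples():
        v[int(pair.mcd_a)] += 1
        v[int(pair.mcd_b)] += 1
    out = mcds.copy()
    out["valency"] = v
    return out
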