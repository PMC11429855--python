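"""Compartment eigenvector, saddle strength, subcompartment aggregation, P(s).

EV1 is the leading eigenvector (by eigenvalue magnitude) of the centred cis
O/E block of each chromosome, scaled by sqrt(|eigenvalue|) and sign-phased so
its correlation with a gene-density track is positive (A > 0). Saddle analysis
ranks bins by EV1 into equal-count quantiles and averages cis O/E per quantile
pair; corner means quantify A-A and B-B strength. P(s) is the mean balanced
contact per log-spaced separation bin; the local peak of its smoothed log-log
derivative estimates the average extruded-loop size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bins import BinTable
from .matrix import ContactMatrix, OEMatrix

MIN_EV_BINS = 50
PS_LOG_RATIO = 2 ** (1 / 8)


@dataclass
class EigenTrack:
    """Per-bin EV1 values (NaN on masked bins) with per-chromosome eigenvalues."""

    bins: BinTable
    values: np.ndarray
    eigenvalues: dict[str, float] = field(default_factory=dict)

    def of(self, chrom: str) -> np.ndarray:
        return self.values[self.bins.chrom_slice(chrom)]


def compute_ev1(oe: OEMatrix, gene_density: np.ndarray, min_bins: int = MIN_EV_BINS) -> EigenTrack:
    """Leading eigenvector of the centred cis O/E per chromosome, phased A > 0.

    Chromosomes with fewer than ``min_bins`` unmasked bins are left undefined.
    A rank-0 (all-zero after centring) block yields an all-zero EV1 with a
    warning-free pass-through.
    """
    values = np.full(oe.bins.n_bins, np.nan)
    eigenvalues: dict[str, float] = {}
    for chrom in oe.bins.chromosomes:
        if not oe.has_block(chrom, chrom):
            continue
        block = oe.block(chrom, chrom)
        sl = oe.bins.chrom_slice(chrom)
        gd = np.asarray(gene_density)[sl]
        finite_rows = np.isfinite(block).any(axis=1)
        keep = np.flatnonzero(finite_rows)
        if keep.size < min_bins:
            continue
        sub = block[np.ix_(keep, keep)]
        sub = np.where(np.isfinite(sub), sub, 1.0) - 1.0  # centre; fill masked with background
        sub = (sub + sub.T) / 2
        evals, evecs = np.linalg.eigh(sub)
        lead = int(np.argmax(np.abs(evals)))
        lam = float(evals[lead])
        vec = evecs[:, lead] * np.sqrt(abs(lam))
        if lam == 0 or not np.any(vec):
            ev = np.zeros(keep.size)
        else:
            ev = vec
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(ev, gd[keep])[0, 1]
            if np.isfinite(corr) and corr < 0:
                ev = -ev
        chrom_vals = np.full(block.shape[0], np.nan)
        chrom_vals[keep] = ev
        values[sl] = chrom_vals
        eigenvalues[chrom] = lam
    return EigenTrack(bins=oe.bins, values=values, eigenvalues=eigenvalues)


@dataclass
class SaddleResult:
    grid: np.ndarray  # Q x Q mean O/E
    aa_strength: float
    bb_strength: float
    quantiles: int
    corner_fraction: float
    reference_used: bool


def saddle(
    ev: EigenTrack,
    oe: OEMatrix,
    quantiles: int = 50,
    corner_fraction: float = 0.2,
    reference_ev: EigenTrack | None = None,
) -> SaddleResult:
    """Quantile-by-quantile mean cis O/E grid over EV1-ranked bins.

    Bins are ranked by ``reference_ev`` when given (borrowed-ranking design),
    else by ``ev``; quantile 0 holds the most negative (B-most) values. AA/BB
    strengths are means over the extreme ``corner_fraction`` x
    ``corner_fraction`` corner blocks of the grid.
    """
    if quantiles < 5:
        raise ValueError("need at least 5 quantiles")
    ranking = (reference_ev or ev).values
    valid = np.isfinite(ranking)
    if valid.sum() < quantiles:
        raise ValueError("fewer unmasked bins than quantiles")
    ranks = np.full(ranking.size, -1, dtype=int)
    order = np.argsort(ranking[valid], kind="stable")
    qa = np.floor(np.arange(order.size) * quantiles / order.size).astype(int)
    tmp = np.empty(order.size, dtype=int)
    tmp[order] = qa
    ranks[valid] = tmp
    if np.bincount(ranks[valid], minlength=quantiles).min() == 0:
        raise ValueError("empty quantile")
    sums = np.zeros((quantiles, quantiles))
    counts = np.zeros((quantiles, quantiles))
    for chrom in oe.bins.chromosomes:
        if not oe.has_block(chrom, chrom):
            continue
        block = oe.block(chrom, chrom)
        r = ranks[oe.bins.chrom_slice(chrom)]
        ok = r >= 0
        sub = block[np.ix_(ok, ok)]
        rr = r[ok]
        finite = np.isfinite(sub)
        vals = np.where(finite, sub, 0.0)
        q1 = np.repeat(rr, rr.size)
        q2 = np.tile(rr, rr.size)
        np.add.at(sums, (q1, q2), vals.ravel())
        np.add.at(counts, (q1, q2), finite.ravel().astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    k = max(1, int(round(corner_fraction * quantiles)))
    bb = float(np.nanmean(grid[:k, :k]))
    aa = float(np.nanmean(grid[-k:, -k:]))
    return SaddleResult(grid, aa, bb, quantiles, corner_fraction, reference_ev is not None)


def subcompartment_aggregate(
    labels: np.ndarray,
    oe: OEMatrix,
    mcd_mask: np.ndarray | None = None,
    trans: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean O/E per ordered class pair; optionally split classes by MCD status.

    ``labels`` is a per-bin array of class names (NaN/None bins excluded).
    With ``mcd_mask`` each class is split into "<class>|MCD" and
    "<class>|non-MCD" groups; the second return value then reports the MCD
    composition per class (fraction of class bins inside MCDs), else None.
    """
    labels = np.asarray(labels, dtype=object)
    if mcd_mask is not None:
        status = np.where(np.asarray(mcd_mask, bool), "MCD", "non-MCD")
        groups = np.array(
            [f"{l}|{s}" if l is not None else None for l, s in zip(labels, status)],
            dtype=object,
        )
    else:
        groups = labels
    names = sorted({g for g in groups if g is not None and g == g})
    if len(names) < 1:
        raise ValueError("no classes defined")
    index = {n: k for k, n in enumerate(names)}
    gid = np.array([index.get(g, -1) for g in groups])
    unknown = (gid < 0) & np.array([g is not None and g == g for g in groups])
    if unknown.any():
        raise ValueError("unknown label encountered")
    n = len(names)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))

    def accumulate(block, g1, g2):
        ok1, ok2 = g1 >= 0, g2 >= 0
        sub = block[np.ix_(ok1, ok2)]
        a, b = g1[ok1], g2[ok2]
        finite = np.isfinite(sub)
        q1 = np.repeat(a, b.size)
        q2 = np.tile(b, a.size)
        np.add.at(sums, (q1, q2), np.where(finite, sub, 0.0).ravel())
        np.add.at(counts, (q1, q2), finite.ravel().astype(float))

    chroms = oe.bins.chromosomes
    for ci, c1 in enumerate(chroms):
        for c2 in chroms[ci:]:
            if (c1 == c2) == trans or not oe.has_block(c1, c2):
                continue
            block = oe.block(c1, c2)
            g1 = gid[oe.bins.chrom_slice(c1)]
            g2 = gid[oe.bins.chrom_slice(c2)]
            accumulate(block, g1, g2)
            if c1 != c2:
                accumulate(block.T, g2, g1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(grid, index=names, columns=names)
    composition = None
    if mcd_mask is not None:
        comp_rows = []
        for cls in sorted({l for l in labels if l is not None and l == l}):
            in_cls = labels == cls
            frac = float(np.asarray(mcd_mask, bool)[in_cls].mean()) if in_cls.any() else np.nan
            comp_rows.append({"class": cls, "n_bins": int(in_cls.sum()), "mcd_fraction": frac})
        composition = pd.DataFrame(comp_rows)
    return table, composition


@dataclass
class PsCurve:
    """Contact probability vs separation with its log-log derivative."""

    separations: np.ndarray  # bp, geometric bin centres (mean separation per bin)
    probabilities: np.ndarray  # normalised to sum 1 over the measured range
    derivative: np.ndarray  # d log P / d log s, central differences
    smoothed_derivative: np.ndarray


def ps_curve(
    matrix: ContactMatrix,
    weights: np.ndarray | None = None,
    log_bin_ratio: float = PS_LOG_RATIO,
    smooth_window: int = 3,
    min_sep_bins: int = 2,
) -> PsCurve:
    """Mean balanced contact per log-spaced separation bin, over all chromosomes.

    The derivative is computed by central differences on log P vs log s and
    smoothed with a ``smooth_window``-bin moving average before peak picking.
    """
    if weights is None:
        if matrix.weights is None:
            raise ValueError("matrix not balanced and no weights given")
        weights = matrix.weights
    bs = matrix.bins.bin_size
    max_bins = max(matrix.bins.n_bins_of(c) for c in matrix.bins.chromosomes)
    sums = np.zeros(max_bins)
    counts = np.zeros(max_bins)
    for chrom in matrix.bins.chromosomes:
        if not matrix.has_block(chrom, chrom):
            continue
        w = weights[matrix.bins.chrom_slice(chrom)]
        bal = matrix.block(chrom, chrom) * np.outer(w, w)
        n = bal.shape[0]
        for d in range(min_sep_bins, n):
            diag = np.diagonal(bal, d)
            finite = np.isfinite(diag)
            sums[d] += diag[finite].sum()
            counts[d] += finite.sum()
    dists = np.flatnonzero(counts > 0)
    if dists.size == 0:
        raise ValueError("no valid separations")
    # geometric binning of integer distances
    edges = [dists[0]]
    while edges[-1] < dists[-1] + 1:
        edges.append(max(edges[-1] + 1, int(np.ceil(edges[-1] * log_bin_ratio))))
    edges = np.array(edges)
    sep_list, p_list = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi = min(hi, len(counts))
        c = counts[lo:hi].sum()
        if c == 0:
            continue
        mean_p = sums[lo:hi].sum() / c
        d_range = np.arange(lo, hi)
        mean_d = (d_range * counts[lo:hi]).sum() / c
        sep_list.append(mean_d * bs)
        p_list.append(mean_p)
    sep = np.array(sep_list)
    p = np.array(p_list)
    if sep.size < 10:
        raise ValueError("fewer than 10 log-spaced separation bins")
    p = p / p.sum()
    logs, logp = np.log(sep), np.log(p)
    deriv = np.full(sep.size, np.nan)
    deriv[1:-1] = (logp[2:] - logp[:-2]) / (logs[2:] - logs[:-2])
    sm = deriv.copy()
    inner = deriv[1:-1]
    if smooth_window > 1 and inner.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(inner, pad, mode="edge")
        sm[1:-1] = np.convolve(padded, kernel, mode="valid")
    return PsCurve(sep, p, deriv, sm)


def loop_size_estimate(curve: PsCurve, min_prominence: float = 0.1) -> float | None:
    """Location (bp) of the most prominent local max of the smoothed derivative, or None."""
    d = curve.smoothed_derivative
    ok = np.isfinite(d)
    vals = d[ok]
    seps = curve.separations[ok]
    peaks, props = signal.find_peaks(vals, prominence=min_prominence)
    if peaks.size == 0:
        return None
    best = peaks[int(np.argmax(props["prominences"]))]
    return float(seps[best])
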