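"""Synthetic Hi-C generator with planted ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* cis distance decay ``P(s) ~ s^-alpha`` with an extrusion "bump" whose
  log-log derivative peaks, by construction, at the configured mean loop size;
* A/B (optionally subcompartment) checkerboard with multiplicative strength
  ``kappa``;
* a planted grid of small mutually interacting microcompartment domains
  (MCDs) with focal factor ``mu``, acting between any two distinct MCDs in
  cis and in trans;
* convergent-CTCF loop pixels with factor ``loop_factor`` at anchor pairs;
* multiplicative log-normal per-bin biases and Poisson counting noise.

Every random draw flows through one :func:`numpy.random.default_rng` stream
(PCG64) seeded from the config, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .bins import BinTable, make_bins
from .matrix import ContactMatrix


@dataclass
class SimulationConfig:
    """Generator parameters. All enrichment factors are >= 1; 1 switches a feature off."""

    chromsizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    bin_size: int = 10_000
    cis_reads: int = 5_000_000
    trans_reads: int = 2_500_000
    alpha: float = 1.0  # cis decay exponent
    # compartments
    compartment_mean_block: int = 1_500_000  # bp, mean alternating-block length
    kappa: float = 1.6  # homotypic/heterotypic multiplicative strength
    subcompartments: bool = False  # label A blocks A1/A2/V-VI instead of plain A
    # microcompartment domains
    n_mcds: int = 40
    mcd_size_range: tuple[int, int] = (30_000, 100_000)
    mu: float = 4.0  # focal MCD-MCD enrichment factor
    mcd_min_gap: int = 50_000  # bp kept clear between planted MCDs
    # loops
    n_loops: int = 60
    loop_mean_size: int = 100_000  # bp; also sets the P(s) bump location
    loop_min_size: int = 30_000
    loop_factor: float = 5.0
    mcd_anchor_fraction: float = 0.75  # fraction of MCDs that contain a loop anchor
    # P(s) bump: log-log slope gets + bump_weight * gaussian(ln s; ln Lbar, bump_sigma)
    bump_weight: float = 0.6
    bump_sigma: float = 0.35
    # noise
    bias_sigma: float = 0.25  # log-SD of per-bin multiplicative biases
    overdispersion: float = 0.0  # gamma-mixing variance; 0 = pure Poisson
    # two-condition pruning knob: attenuate MCD-pair enrichment beyond a distance
    prune_distance: int | None = None  # bp; None = off
    prune_factor: float = 1.0  # multiplies (mu) for attenuated pairs
    prune_requires_anchor: bool = True  # attenuate only pairs with >=1 anchored MCD
    # annotations
    n_atac_peaks: int = 1_000
    frac_bookmarked: float = 0.30
    frac_g1_only: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kappa", "mu", "loop_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (1 = off)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.mcd_size_range
        if lo < self.bin_size or hi < lo:
            raise ValueError("invalid mcd_size_range")

    def bins(self) -> BinTable:
        return make_bins(self.chromsizes, self.bin_size)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Planted features: the recovery target for downstream modules."""

    bins: BinTable
    labels: np.ndarray  # per-bin subcompartment-style label (A/B or A1/A2/V-VI/B)
    ab_labels: np.ndarray  # per-bin 'A' or 'B'
    mcds: pd.DataFrame  # chrom, start, end, has_anchor
    loops: pd.DataFrame  # chrom, start1, end1, start2, end2, strand1, strand2
    biases: np.ndarray  # per-bin multiplicative bias

    def mcd_bin_ids(self) -> list[np.ndarray]:
        """Global bin indices of each planted MCD, in table order."""
        out = []
        for row in self.mcds.itertuples():
            lo = self.bins.bin_index(row.chrom, row.start)
            hi = self.bins.bin_index(row.chrom, row.end - 1)
            out.append(np.arange(lo, hi + 1))
        return out


def _plant_labels(bins: BinTable, config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    mean_blocks = max(2.0, config.compartment_mean_block / config.bin_size)
    sub_cycle = ["A1", "A2", "V/VI"]
    labels = np.empty(bins.n_bins, dtype=object)
    ab = np.empty(bins.n_bins, dtype=object)
    for chrom in bins.chromosomes:
        n = bins.n_bins_of(chrom)
        off = bins.offset(chrom)
        pos = 0
        state = rng.integers(0, 2)  # 0 = A-type, 1 = B
        k = 0
        while pos < n:
            width = max(2, int(round(rng.exponential(mean_blocks))))
            width = min(width, n - pos)
            if state == 0:
                lab = sub_cycle[k % 3] if config.subcompartments else "A"
                k += 1
                labels[off + pos : off + pos + width] = lab
                ab[off + pos : off + pos + width] = "A"
            else:
                labels[off + pos : off + pos + width] = "B"
                ab[off + pos : off + pos + width] = "B"
            pos += width
            state = 1 - state
    return labels, ab


def _plant_mcds(bins: BinTable, ab: np.ndarray, config: SimulationConfig, rng) -> pd.DataFrame:
    """Place non-overlapping MCDs uniformly at random inside A-labelled runs."""
    lo_bins = max(1, config.mcd_size_range[0] // config.bin_size)
    hi_bins = max(lo_bins, config.mcd_size_range[1] // config.bin_size)
    gap = -(-config.mcd_min_gap // config.bin_size)
    taken = np.zeros(bins.n_bins, dtype=bool)
    rows = []
    attempts = 0
    max_attempts = 20_000 * max(1, config.n_mcds)
    while len(rows) < config.n_mcds:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_mcds} non-overlapping MCDs "
                f"(placed {len(rows)}); genome too small or too few A bins"
            )
        size = int(rng.integers(lo_bins, hi_bins + 1))
        g = int(rng.integers(0, bins.n_bins))
        chrom, start, _ = bins.bin_coords(g)
        local = g - bins.offset(chrom)
        if local + size > bins.n_bins_of(chrom):
            continue
        span = slice(g, g + size)
        if not np.all(ab[span] == "A"):
            continue
        pad = slice(max(0, g - gap), min(bins.n_bins, g + size + gap))
        if taken[pad].any():
            continue
        taken[span] = True
        rows.append({"chrom": chrom, "start": start, "end": start + size * config.bin_size})
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    df["has_anchor"] = False
    return df


def _plant_loops(
    bins: BinTable, mcds: pd.DataFrame, config: SimulationConfig, rng
) -> pd.DataFrame:
    """Convergent loops; a configured fraction anchored inside planted MCDs."""
    if config.n_loops == 0:
        return pd.DataFrame(
            columns=["chrom", "start1", "end1", "start2", "end2", "strand1", "strand2"]
        )
    bs = config.bin_size
    n_anchored = min(int(round(config.mcd_anchor_fraction * len(mcds))), config.n_loops)
    anchored_mcds = rng.choice(len(mcds), size=n_anchored, replace=False) if n_anchored else []
    rows = []

    def draw_span() -> int:
        span = config.loop_min_size + rng.exponential(
            max(bs, config.loop_mean_size - config.loop_min_size)
        )
        return max(bs, int(round(span / bs)) * bs)

    for m in anchored_mcds:
        row = mcds.iloc[m]
        clen = bins.chromsizes[row.chrom]
        a1 = (int(rng.integers(row.start, row.end)) // bs) * bs
        for _ in range(100):
            span = draw_span()
            if a1 + span + bs <= clen:
                break
        else:
            span = ((clen - a1 - bs) // bs) * bs
            if span < bs:
                continue
        rows.append((row.chrom, a1, a1 + bs, a1 + span, a1 + span + bs))
        mcds.loc[m, "has_anchor"] = True
    chroms = bins.chromosomes
    while len(rows) < config.n_loops:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = bins.chromsizes[chrom]
        span = draw_span()
        if span + bs >= clen:
            continue
        a1 = int(rng.integers(0, (clen - span - bs) // bs)) * bs
        rows.append((chrom, a1, a1 + bs, a1 + span, a1 + span + bs))
    df = pd.DataFrame(rows, columns=["chrom", "start1", "end1", "start2", "end2"])
    df["strand1"] = "+"
    df["strand2"] = "-"
    # loops whose second anchor happens to fall inside an MCD also mark it anchored
    for m, row in mcds.iterrows():
        if not mcds.loc[m, "has_anchor"]:
            hit = (
                (df["chrom"] == row.chrom)
                & (
                    ((df["start1"] < row.end) & (df["end1"] > row.start))
                    | ((df["start2"] < row.end) & (df["end2"] > row.start))
                )
            )
            if hit.any():
                mcds.loc[m, "has_anchor"] = True
    return df.sort_values(["chrom", "start1", "start2"]).reset_index(drop=True)


def plant_features(config: SimulationConfig, rng=None) -> TruthSet:
    """Draw compartment labels, MCDs, loops and per-bin biases."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bins = config.bins()
    labels, ab = _plant_labels(bins, config, rng)
    if config.n_mcds > 0:
        mcds = _plant_mcds(bins, ab, config, rng)
    else:
        mcds = pd.DataFrame(columns=["chrom", "start", "end", "has_anchor"])
    loops = _plant_loops(bins, mcds, config, rng)
    if config.bias_sigma > 0:
        biases = np.exp(rng.normal(0.0, config.bias_sigma, bins.n_bins))
    else:
        biases = np.ones(bins.n_bins)
    return TruthSet(bins=bins, labels=labels, ab_labels=ab, mcds=mcds, loops=loops, biases=biases)


def decay_profile(s_bins: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Unnormalised cis intensity B(s) as a function of separation in bins.

    ``ln B(s) = -alpha ln s + w * sigma * sqrt(pi/2) * (1 + erf((ln s - ln L)/(sqrt(2) sigma)))``
    so that ``d ln B / d ln s = -alpha + w * exp(-(ln s - ln L)^2 / (2 sigma^2))``:
    the log-log slope carries a Gaussian bump of height ``w`` centred exactly at
    the mean loop size ``L`` (in bins). ``w = 0`` gives a pure power law.
    """
    s = np.maximum(np.asarray(s_bins, dtype=float), 1.0)
    logs = np.log(s)
    out = -config.alpha * logs
    if config.bump_weight > 0:
        L = max(1.0, config.loop_mean_size / config.bin_size)
        sig = config.bump_sigma
        out = out + config.bump_weight * sig * np.sqrt(np.pi / 2) * (
            1.0 + erf((logs - np.log(L)) / (np.sqrt(2) * sig))
        )
    return np.exp(out)


def _mcd_factor_blocks(
    truth: TruthSet, config: SimulationConfig
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (mcd id per bin or -1, anchored flag per bin)."""
    out = {}
    for chrom in truth.bins.chromosomes:
        n = truth.bins.n_bins_of(chrom)
        ids = np.full(n, -1, dtype=int)
        anchored = np.zeros(n, dtype=bool)
        sub = truth.mcds[truth.mcds["chrom"] == chrom]
        for idx, row in sub.iterrows():
            lo = row.start // config.bin_size
            hi = -(-row.end // config.bin_size)
            ids[lo:hi] = idx
            anchored[lo:hi] = bool(row.has_anchor)
        out[chrom] = (ids, anchored)
    return out


def _pair_factor(
    ids1: np.ndarray,
    ids2: np.ndarray,
    anch1: np.ndarray,
    anch2: np.ndarray,
    sep_bp: np.ndarray | None,
    config: SimulationConfig,
) -> np.ndarray:
    """MCD-pair enrichment matrix M_ij, with optional distance-dependent pruning."""
    in1 = ids1[:, None] >= 0
    in2 = ids2[None, :] >= 0
    distinct = ids1[:, None] != ids2[None, :]
    m = np.where(in1 & in2 & distinct, config.mu, 1.0)
    # pruning is distance-gated and tied to extrusion, hence cis-only
    if config.prune_distance is not None and config.prune_factor != 1.0 and sep_bp is not None:
        attn = in1 & in2 & distinct & (sep_bp > config.prune_distance)
        if config.prune_requires_anchor:
            attn &= anch1[:, None] | anch2[None, :]
        m = np.where(attn, np.maximum(1.0, config.mu * config.prune_factor), m)
    return m


def simulate_counts(truth: TruthSet, config: SimulationConfig, rng=None) -> ContactMatrix:
    """Poisson-sample a contact matrix around the planted intensity model.

    Cis pixel intensity: ``N_c * b_i * b_j * B(s) * C_ij * M_ij * L_ij`` with
    B the decay profile, C the compartment checkerboard (kappa / 1/kappa),
    M the MCD grid factor (mu between distinct MCDs) and L the loop-anchor
    factor (peak-weighted over the anchor 3x3 neighbourhood). Trans intensity:
    ``N_t * b_i * b_j * C_ij * M_ij``. The constants ``N_c``/``N_t`` are set so
    expected totals match the configured read budgets.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bins = truth.bins
    bs = config.bin_size
    mcd_info = _mcd_factor_blocks(truth, config)
    chroms = bins.chromosomes

    cis_intensity: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n = bins.n_bins_of(chrom)
        sl = bins.chrom_slice(chrom)
        b = truth.biases[sl]
        lab = truth.ab_labels[sl]
        idx = np.arange(n)
        s = np.abs(idx[:, None] - idx[None, :])
        inten = decay_profile(s, config) * np.outer(b, b)
        same = lab[:, None] == lab[None, :]
        inten *= np.where(same, config.kappa, 1.0 / config.kappa)
        ids, anch = mcd_info[chrom]
        inten *= _pair_factor(ids, ids, anch, anch, s * bs, config)
        if config.loop_factor > 1:
            lmat = np.ones((n, n))
            sub = truth.loops[truth.loops["chrom"] == chrom]
            lam = config.loop_factor
            edge = 1 + (lam - 1) * 0.5
            for row in sub.itertuples():
                i = row.start1 // bs
                j = row.start2 // bs
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < n and 0 <= jj < n:
                            f = lam if (di == 0 and dj == 0) else edge
                            lmat[ii, jj] = max(lmat[ii, jj], f)
                            lmat[jj, ii] = lmat[ii, jj]
            inten *= lmat
        cis_intensity[chrom] = inten

    total_cis = sum(np.triu(v).sum() for v in cis_intensity.values())
    n_c = config.cis_reads / total_cis if total_cis > 0 else 0.0

    blocks: dict[tuple[str, str], np.ndarray] = {}
    for chrom in chroms:
        inten = cis_intensity[chrom] * n_c
        upper = np.triu(rng.poisson(np.triu(inten)))
        blocks[(chrom, chrom)] = upper + np.triu(upper, 1).T

    if len(chroms) > 1 and config.trans_reads > 0:
        trans_intensity: dict[tuple[str, str], np.ndarray] = {}
        for a, c1 in enumerate(chroms):
            for c2 in chroms[a + 1 :]:
                s1, s2 = bins.chrom_slice(c1), bins.chrom_slice(c2)
                b1, b2 = truth.biases[s1], truth.biases[s2]
                l1, l2 = truth.ab_labels[s1], truth.ab_labels[s2]
                inten = np.outer(b1, b2)
                same = l1[:, None] == l2[None, :]
                inten *= np.where(same, config.kappa, 1.0 / config.kappa)
                ids1, anch1 = mcd_info[c1]
                ids2, anch2 = mcd_info[c2]
                inten *= _pair_factor(ids1, ids2, anch1, anch2, None, config)
                trans_intensity[(c1, c2)] = inten
        total_trans = sum(v.sum() for v in trans_intensity.values())
        n_t = config.trans_reads / total_trans
        for key, inten in trans_intensity.items():
            blocks[key] = rng.poisson(inten * n_t).astype(float)
    else:
        for a, c1 in enumerate(chroms):
            for c2 in chroms[a + 1 :]:
                blocks[(c1, c2)] = np.zeros((bins.n_bins_of(c1), bins.n_bins_of(c2)))

    return ContactMatrix(
        bins,
        {k: v.astype(float) for k, v in blocks.items()},
        metadata={"source": "mcdhic-simulation", "seed": config.seed},
    )


def simulate_annotations(truth: TruthSet, config: SimulationConfig, rng=None) -> dict:
    """Emit cCRE elements, three condition-tagged ATAC peak sets, and gene density.

    cCREs are dense inside planted MCDs (every MCD gets a bookmarked promoter
    and enhancer) and sparse elsewhere; CTCF-site elements sit at every planted
    loop anchor with the planted orientation. ATAC peaks carry one of seven
    membership categories over {prometaphase, G1-control, G1-depleted} with
    configured bookmarked / G1-control-only fractions. Gene density is a
    per-bin track positively correlated with the A label (for EV1 phasing).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    bins = truth.bins
    width = 600  # element width, bp

    elements = []
    peak_rows = []

    def add_peak(chrom, start, category):
        peak_rows.append({"chrom": chrom, "start": start, "end": start + width, "category": category})

    # every MCD: one bookmarked promoter + one bookmarked enhancer inside it
    for row in truth.mcds.itertuples():
        mid = (row.start + row.end) // 2
        for cls, pos in (("promoter", row.start + width), ("enhancer", mid)):
            elements.append(
                {"chrom": row.chrom, "start": pos, "end": pos + width, "cre_class": cls,
                 "category": "bookmarked"}
            )
            add_peak(row.chrom, pos, "bookmarked")
    for row in truth.loops.itertuples():
        for start, strand in ((row.start1, "+"), (row.start2, "-")):
            elements.append(
                {"chrom": row.chrom, "start": start, "end": start + width,
                 "cre_class": "CTCF", "category": "bookmarked", "strand": strand}
            )

    # background ATAC peaks with configured intersection structure
    n_bg = max(0, config.n_atac_peaks - len(peak_rows))
    cats = ["bookmarked", "G1-control-only", "prometaphase-only", "G1-depleted-only",
            "control+depleted", "prometaphase+control", "prometaphase+depleted"]
    p_rest = max(0.0, 1.0 - config.frac_bookmarked - config.frac_g1_only) / 5
    probs = np.array([config.frac_bookmarked, config.frac_g1_only] + [p_rest] * 5)
    probs = probs / probs.sum()
    chroms = bins.chromosomes
    bg_classes = ["promoter", "enhancer", "other"]
    for _ in range(n_bg):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, bins.chromsizes[chrom] - width))
        cat = cats[int(rng.choice(len(cats), p=probs))]
        add_peak(chrom, start, cat)
        elements.append(
            {"chrom": chrom, "start": start, "end": start + width,
             "cre_class": bg_classes[int(rng.integers(0, 3))], "category": cat}
        )

    peaks = pd.DataFrame(peak_rows)
    membership = {
        "bookmarked": ("prometaphase", "G1-control", "G1-depleted"),
        "G1-control-only": ("G1-control",),
        "prometaphase-only": ("prometaphase",),
        "G1-depleted-only": ("G1-depleted",),
        "control+depleted": ("G1-control", "G1-depleted"),
        "prometaphase+control": ("prometaphase", "G1-control"),
        "prometaphase+depleted": ("prometaphase", "G1-depleted"),
    }
    peak_sets = {}
    for cond in ("prometaphase", "G1-control", "G1-depleted"):
        keep = peaks["category"].map(lambda c: cond in membership[c])
        peak_sets[cond] = (
            peaks.loc[keep, ["chrom", "start", "end"]]
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )

    gene_density = 0.2 + 0.05 * rng.random(bins.n_bins)
    gene_density[truth.ab_labels == "A"] += 1.0

    elements_df = (
        pd.DataFrame(elements).sort_values(["chrom", "start"]).reset_index(drop=True)
    )
    return {"elements": elements_df, "peak_sets": peak_sets, "gene_density": gene_density}
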