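"""Binned contact matrices: container, balancing, expected models, O/E transform, I/O.

The container holds one dense block per chromosome pair (cis blocks symmetric).
Balancing is matrix scaling by iterative correction: it finds one positive
weight per bin such that the weighted marginals of all unmasked bins are equal
(normalised here to 1), removing multiplicative per-bin biases. Cis expected is
the per-diagonal mean of balanced values (optionally pooled in log-spaced
distance windows); trans expected is a single scalar per chromosome pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .bins import BinTable


class BalanceError(RuntimeError):
    """Iterative correction failed to converge; carries the last marginal CV."""

    def __init__(self, cv: float, max_iter: int):
        super().__init__(
            f"balancing did not converge in {max_iter} iterations (marginal CV={cv:.3g})"
        )
        self.cv = cv


def _block_key(bins: BinTable, c1: str, c2: str) -> tuple[str, str, bool]:
    order = {c: i for i, c in enumerate(bins.chromosomes)}
    if order[c1] <= order[c2]:
        return c1, c2, False
    return c2, c1, True


@dataclass
class ContactMatrix:
    """Raw (count) Hi-C matrix over a :class:`BinTable`.

    ``blocks`` maps ordered chromosome pairs (c1 before c2 in bin-table order)
    to dense count arrays; cis blocks are symmetric. ``weights`` holds the
    per-bin balancing weight (NaN = masked), or None before balancing.
    """

    bins: BinTable
    blocks: dict[tuple[str, str], np.ndarray]
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (c1, c2), arr in self.blocks.items():
            n1, n2 = self.bins.n_bins_of(c1), self.bins.n_bins_of(c2)
            if arr.shape != (n1, n2):
                raise ValueError(f"block {(c1, c2)} has shape {arr.shape}, want {(n1, n2)}")
            if np.any(arr < 0):
                raise ValueError(f"block {(c1, c2)} has negative counts")
            if c1 == c2 and not np.allclose(arr, arr.T):
                raise ValueError(f"cis block {c1} is not symmetric")

    def block(self, c1: str, c2: str) -> np.ndarray:
        """Count block for (c1, c2), transposed on the fly if stored as (c2, c1)."""
        a, b, flipped = _block_key(self.bins, c1, c2)
        arr = self.blocks[(a, b)]
        return arr.T if flipped else arr

    def has_block(self, c1: str, c2: str) -> bool:
        a, b, _ = _block_key(self.bins, c1, c2)
        return (a, b) in self.blocks

    def weights_of(self, chrom: str) -> np.ndarray:
        if self.weights is None:
            raise ValueError("matrix is not balanced (weights is None)")
        return self.weights[self.bins.chrom_slice(chrom)]

    def balanced_block(self, c1: str, c2: str) -> np.ndarray:
        """Balanced values w_i * K_ij * w_j; NaN over masked rows/columns."""
        w1 = self.weights_of(c1)
        w2 = self.weights_of(c2)
        return self.block(c1, c2) * np.outer(w1, w2)

    def raw_marginals(self, cis_only: bool = False) -> np.ndarray:
        """Genome-wide row sums of the full symmetric matrix."""
        m = np.zeros(self.bins.n_bins)
        for (c1, c2), arr in self.blocks.items():
            s1, s2 = self.bins.chrom_slice(c1), self.bins.chrom_slice(c2)
            if c1 == c2:
                m[s1] += arr.sum(axis=1)
            elif not cis_only:
                m[s1] += arr.sum(axis=1)
                m[s2] += arr.sum(axis=0)
        return m

    def total_counts(self, cis: bool | None = None) -> float:
        """Sum of counts over unique pixels (upper triangle for cis blocks)."""
        total = 0.0
        for (c1, c2), arr in self.blocks.items():
            if c1 == c2:
                if cis is False:
                    continue
                total += np.triu(arr).sum()
            else:
                if cis is True:
                    continue
                total += arr.sum()
        return total


def balance(
    matrix: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 500,
    marginal_filter: float = 0.02,
    cis_only: bool = False,
) -> np.ndarray:
    """Iterative correction of a contact matrix; returns per-bin weights.

    Bins with zero raw marginal, or raw marginal below the ``marginal_filter``
    quantile of the nonzero marginals, are masked (weight NaN). Balancing is
    genome-wide over cis and trans blocks unless ``cis_only``. Weights are
    scaled so that the weighted marginal of every unmasked bin equals 1.

    Raises :class:`BalanceError` if the marginal coefficient of variation does
    not drop to ``tol`` within ``max_iter`` sweeps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    m0 = matrix.raw_marginals(cis_only=cis_only)
    masked = m0 == 0
    nonzero = m0[~masked]
    if nonzero.size == 0:
        raise ValueError("matrix has no counts")
    if marginal_filter > 0:
        cutoff = np.quantile(nonzero, marginal_filter)
        masked |= m0 < cutoff
    if (~masked).sum() == 0:
        raise ValueError("all bins masked by the marginal filter")

    n = matrix.bins.n_bins
    b = np.ones(n)
    b[masked] = 0.0
    cv = np.inf
    for _ in range(max_iter):
        # marginals of K_ij * b_i * b_j
        m = np.zeros(n)
        for (c1, c2), arr in matrix.blocks.items():
            if cis_only and c1 != c2:
                continue
            s1, s2 = matrix.bins.chrom_slice(c1), matrix.bins.chrom_slice(c2)
            if c1 == c2:
                m[s1] += b[s1] * (arr @ b[s1])
            else:
                m[s1] += b[s1] * (arr @ b[s2])
                m[s2] += b[s2] * (arr.T @ b[s1])
        live = m[~masked]
        mean = live.mean()
        cv = live.std() / mean if mean > 0 else np.inf
        if cv <= tol:
            b[~masked] /= np.sqrt(mean)  # normalise marginals to 1
            weights = np.full(n, np.nan)
            weights[~masked] = b[~masked]
            return weights
        scale = np.ones(n)
        scale[~masked] = np.sqrt(live / mean)
        b /= np.where(scale > 0, scale, 1.0)
    raise BalanceError(cv, max_iter)


LOG_WINDOW_RATIO = 2 ** (1 / 8)
SMOOTH_START_BINS = 40


@dataclass
class ExpectedModel:
    """Distance-decay expectation (cis) and per-pair scalar expectation (trans).

    ``cis[chrom][d]`` is the expected balanced value at bin distance ``d``
    (NaN where no unmasked pixel exists); ``cis_counts`` the number of
    unmasked pixels that entered each distance. ``trans[(c1, c2)]`` is the mean
    balanced value over all unmasked pixels of the pair.
    """

    bins: BinTable
    cis: dict[str, np.ndarray] = field(default_factory=dict)
    cis_counts: dict[str, np.ndarray] = field(default_factory=dict)
    trans: dict[tuple[str, str], float] = field(default_factory=dict)
    smoothing: str = "none"

    def trans_value(self, c1: str, c2: str) -> float:
        a, b, _ = _block_key(self.bins, c1, c2)
        return self.trans[(a, b)]


def _diagonal_stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-diagonal (sum of finite values, count of finite values)."""
    n = block.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for d in range(n):
        diag = np.diagonal(block, d)
        finite = np.isfinite(diag)
        counts[d] = int(finite.sum())
        sums[d] = diag[finite].sum()
    return sums, counts


def _log_windows(start: int, stop: int, ratio: float) -> list[tuple[int, int]]:
    """Half-open integer windows covering [start, stop) with ~geometric widths."""
    windows = []
    lo = start
    edge = float(start)
    while lo < stop:
        edge = max(edge * ratio, lo + 1)
        hi = min(int(np.ceil(edge)), stop)
        windows.append((lo, hi))
        lo = hi
    return windows


def cis_expected(
    matrix: ContactMatrix,
    weights: np.ndarray | None = None,
    smoothing: str = "log-window",
    smooth_start_bins: int = SMOOTH_START_BINS,
    log_ratio: float = LOG_WINDOW_RATIO,
) -> ExpectedModel:
    """Per-chromosome expected balanced value as a function of bin distance.

    With ``smoothing='log-window'`` distances beyond ``smooth_start_bins`` are
    pooled in multiplicatively spaced windows (ratio ``log_ratio``) to control
    variance where per-diagonal pixel counts get sparse; short distances are
    always exact per-diagonal means.
    """
    if smoothing not in ("none", "log-window"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    if weights is None:
        if matrix.weights is None:
            raise ValueError("matrix not balanced and no weights given")
        weights = matrix.weights
    model = ExpectedModel(bins=matrix.bins, smoothing=smoothing)
    for chrom in matrix.bins.chromosomes:
        if not matrix.has_block(chrom, chrom):
            continue
        w = weights[matrix.bins.chrom_slice(chrom)]
        if np.isfinite(w).sum() < 2:
            warnings.warn(f"chromosome {chrom} has <2 unmasked bins; expected undefined")
            continue
        bal = matrix.block(chrom, chrom) * np.outer(w, w)
        sums, counts = _diagonal_stats(bal)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if smoothing == "log-window":
            for lo, hi in _log_windows(smooth_start_bins, len(exp), log_ratio):
                c = counts[lo:hi].sum()
                if c > 0:
                    pooled = sums[lo:hi].sum() / c
                    exp[lo:hi] = np.where(counts[lo:hi] > 0, pooled, np.nan)
        model.cis[chrom] = exp
        model.cis_counts[chrom] = counts
    return model


def trans_expected(matrix: ContactMatrix, weights: np.ndarray | None = None) -> ExpectedModel:
    """Scalar mean balanced value per trans chromosome pair."""
    if weights is None:
        if matrix.weights is None:
            raise ValueError("matrix not balanced and no weights given")
        weights = matrix.weights
    model = ExpectedModel(bins=matrix.bins)
    for (c1, c2), arr in matrix.blocks.items():
        if c1 == c2:
            continue
        w1 = weights[matrix.bins.chrom_slice(c1)]
        w2 = weights[matrix.bins.chrom_slice(c2)]
        bal = arr * np.outer(w1, w2)
        finite = np.isfinite(bal)
        if not finite.any():
            warnings.warn(f"trans pair {(c1, c2)} has no unmasked pixels")
            continue
        model.trans[(c1, c2)] = float(bal[finite].mean())
    return model


@dataclass
class OEMatrix:
    """Observed/expected matrix with the block structure of its source.

    Values are balanced observed divided by expected; NaN wherever a bin is
    masked or the expected value is zero/undefined.
    """

    bins: BinTable
    blocks: dict[tuple[str, str], np.ndarray]
    weights: np.ndarray

    def block(self, c1: str, c2: str) -> np.ndarray:
        a, b, flipped = _block_key(self.bins, c1, c2)
        arr = self.blocks[(a, b)]
        return arr.T if flipped else arr

    def has_block(self, c1: str, c2: str) -> bool:
        a, b, _ = _block_key(self.bins, c1, c2)
        return (a, b) in self.blocks


def observed_over_expected(
    matrix: ContactMatrix,
    expected: ExpectedModel,
    trans_exp: ExpectedModel | None = None,
    weights: np.ndarray | None = None,
) -> OEMatrix:
    """Elementwise balanced-observed / expected.

    Cis blocks are divided by the distance expectation of their chromosome;
    trans blocks by the scalar pair expectation (from ``trans_exp`` if given,
    else from ``expected``).
    """
    if expected.bins is not matrix.bins and expected.bins.chromsizes != matrix.bins.chromsizes:
        raise ValueError("expected model and matrix use different bin tables")
    if weights is None:
        if matrix.weights is None:
            raise ValueError("matrix not balanced and no weights given")
        weights = matrix.weights
    trans_model = trans_exp if trans_exp is not None else expected
    out: dict[tuple[str, str], np.ndarray] = {}
    for (c1, c2), arr in matrix.blocks.items():
        w1 = weights[matrix.bins.chrom_slice(c1)]
        w2 = weights[matrix.bins.chrom_slice(c2)]
        bal = arr * np.outer(w1, w2)
        if c1 == c2:
            if c1 not in expected.cis:
                out[(c1, c2)] = np.full_like(bal, np.nan)
                continue
            n = arr.shape[0]
            dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
            denom = expected.cis[c1][dist]
        else:
            denom = np.full_like(bal, trans_model.trans.get((c1, c2), np.nan))
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(denom > 0, bal / denom, np.nan)
        out[(c1, c2)] = oe
    return OEMatrix(bins=matrix.bins, blocks=out, weights=weights)


# ---------------------------------------------------------------------------
# I/O: plain-text exchange format and a minimal HDF5 container
# ---------------------------------------------------------------------------

def write_text(matrix: ContactMatrix, bins_path, pixels_path) -> None:
    """Write bin table TSV (chrom, start, end[, weight]) and upper-triangle COO TSV."""
    bins_df = matrix.bins.to_frame()
    if matrix.weights is not None:
        bins_df["weight"] = matrix.weights
    bins_df.to_csv(bins_path, sep="\t", index=False, float_format="%.10g")
    rows = []
    for (c1, c2), arr in sorted(matrix.blocks.items()):
        o1 = matrix.bins.offset(c1)
        o2 = matrix.bins.offset(c2)
        view = np.triu(arr) if c1 == c2 else arr
        i, j = np.nonzero(view)
        rows.append(
            pd.DataFrame({"bin1": i + o1, "bin2": j + o2, "count": view[i, j].astype(np.int64)})
        )
    coo = (
        pd.concat(rows, ignore_index=True).sort_values(["bin1", "bin2"])
        if rows
        else pd.DataFrame(columns=["bin1", "bin2", "count"])
    )
    coo.to_csv(pixels_path, sep="\t", index=False)


def read_text(bins_path, pixels_path, metadata: dict | None = None) -> ContactMatrix:
    """Read the plain-text exchange format written by :func:`write_text`."""
    bins_df = pd.read_csv(bins_path, sep="\t")
    sizes: dict[str, int] = {}
    for chrom, grp in bins_df.groupby("chrom", sort=False):
        sizes[str(chrom)] = int(grp["end"].max())
    widths = bins_df["end"] - bins_df["start"]
    bin_size = int(widths.max())
    bins = BinTable(sizes, bin_size)
    coo = pd.read_csv(pixels_path, sep="\t")
    blocks: dict[tuple[str, str], np.ndarray] = {}
    chroms = bins.chromosomes
    for a_i, c1 in enumerate(chroms):
        for c2 in chroms[a_i:]:
            blocks[(c1, c2)] = np.zeros((bins.n_bins_of(c1), bins.n_bins_of(c2)))
    edges = np.array([bins.offset(c) for c in chroms] + [bins.n_bins])
    which = np.searchsorted(edges, coo["bin1"].to_numpy(), side="right") - 1
    which2 = np.searchsorted(edges, coo["bin2"].to_numpy(), side="right") - 1
    for (a, b), grp in coo.groupby([which, which2]):
        c1, c2 = chroms[a], chroms[b]
        i = grp["bin1"].to_numpy() - bins.offset(c1)
        j = grp["bin2"].to_numpy() - bins.offset(c2)
        blocks[(c1, c2)][i, j] += grp["count"].to_numpy()
        if c1 == c2:
            off_diag = i != j
            blocks[(c1, c2)][j[off_diag], i[off_diag]] += grp["count"].to_numpy()[off_diag]
    weights = bins_df["weight"].to_numpy() if "weight" in bins_df else None
    return ContactMatrix(bins, blocks, weights=weights, metadata=metadata or {})


def write_hdf5(matrix: ContactMatrix, path) -> None:
    """Write a minimal cool-style HDF5 container (chroms, bins, pixels groups)."""
    bins_df = matrix.bins.to_frame()
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = matrix.bins.bin_size
        for key, value in matrix.metadata.items():
            f.attrs[f"meta/{key}"] = value
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(matrix.bins.chromosomes, dtype="S"))
        g.create_dataset("length", data=np.array(list(matrix.bins.chromsizes.values())))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=bins_df["chrom"].to_numpy(dtype="S"))
        g.create_dataset("start", data=bins_df["start"].to_numpy())
        g.create_dataset("end", data=bins_df["end"].to_numpy())
        if matrix.weights is not None:
            g.create_dataset("weight", data=matrix.weights)
        rows_i, rows_j, rows_v = [], [], []
        for (c1, c2), arr in sorted(matrix.blocks.items()):
            view = np.triu(arr) if c1 == c2 else arr
            i, j = np.nonzero(view)
            rows_i.append(i + matrix.bins.offset(c1))
            rows_j.append(j + matrix.bins.offset(c2))
            rows_v.append(view[i, j])
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=np.concatenate(rows_i) if rows_i else np.array([], int))
        g.create_dataset("bin2_id", data=np.concatenate(rows_j) if rows_j else np.array([], int))
        g.create_dataset("count", data=np.concatenate(rows_v) if rows_v else np.array([]))


def read_hdf5(path) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["chroms/name"][:]]
        lengths = f["chroms/length"][:]
        bins = BinTable(dict(zip(names, map(int, lengths))), int(f.attrs["bin-size"]))
        weights = f["bins/weight"][:] if "weight" in f["bins"] else None
        i = f["pixels/bin1_id"][:]
        j = f["pixels/bin2_id"][:]
        v = f["pixels/count"][:]
        metadata = {
            k[len("meta/"):]: f.attrs[k] for k in f.attrs if str(k).startswith("meta/")
        }
    blocks: dict[tuple[str, str], np.ndarray] = {}
    chroms = bins.chromosomes
    for a_i, c1 in enumerate(chroms):
        for c2 in chroms[a_i:]:
            blocks[(c1, c2)] = np.zeros((bins.n_bins_of(c1), bins.n_bins_of(c2)))
    edges = np.array([bins.offset(c) for c in chroms] + [bins.n_bins])
    wi = np.searchsorted(edges, i, side="right") - 1
    wj = np.searchsorted(edges, j, side="right") - 1
    for a, b, ii, jj, vv in zip(wi, wj, i, j, v):
        c1, c2 = chroms[a], chroms[b]
        li, lj = ii - bins.offset(c1), jj - bins.offset(c2)
        blocks[(c1, c2)][li, lj] += vv
        if c1 == c2 and li != lj:
            blocks[(c1, c2)][lj, li] += vv
    return ContactMatrix(bins, blocks, weights=weights, metadata=metadata)
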