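"""Shared fixtures: small deterministic simulations and toy matrices."""

import numpy as np
import pytest

from mcdhic import matrix as mx
from mcdhic.bins import make_bins
from mcdhic.matrix import ContactMatrix
from mcdhic.simulate import SimulationConfig, plant_features, simulate_annotations, simulate_counts


def toy_matrix(values: np.ndarray, chrom: str = "chrA", bin_size: int = 10_000,
               weights=None) -> ContactMatrix:
    """Single-chromosome ContactMatrix from a square array."""
    n = values.shape[0]
    bins = make_bins({chrom: n * bin_size}, bin_size)
    m = ContactMatrix(bins, {(chrom, chrom): np.asarray(values, dtype=float)})
    if weights is not None:
        m.weights = np.asarray(weights, dtype=float)
    return m


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        chromsizes={"chr1": 8_000_000, "chr2": 8_000_000},
        cis_reads=2_000_000,
        trans_reads=1_000_000,
        n_mcds=14,
        mcd_size_range=(30_000, 60_000),
        loop_factor=1.0,
        bump_weight=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One balanced small simulation shared across tests (read-only)."""
    truth = plant_features(small_config)
    m = simulate_counts(truth, small_config)
    m.weights = mx.balance(m)
    exp_raw = mx.cis_expected(m, smoothing="none")
    exp_smooth = mx.cis_expected(m, smoothing="log-window")
    exp_trans = mx.trans_expected(m)
    oe = mx.observed_over_expected(m, exp_raw, trans_exp=exp_trans)
    ann = simulate_annotations(truth, small_config)
    return {
        "config": small_config,
        "truth": truth,
        "matrix": m,
        "expected_raw": exp_raw,
        "expected_smooth": exp_smooth,
        "expected_trans": exp_trans,
        "oe": oe,
        "annotations": ann,
    }
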