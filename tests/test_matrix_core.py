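"""Bin tables, balancing, expected models and O/E transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mcdhic import matrix as mx
from mcdhic.bins import make_bins
from mcdhic.matrix import ContactMatrix

from conftest import toy_matrix


class TestMakeBins:
    @pytest.mark.parametrize(
        "sizes,bin_size,expect",
        [
            ({"chrA": 25_000}, 10_000, [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]),
            ({"chrA": 20_000}, 10_000, [(0, 10_000), (10_000, 20_000)]),
        ],
    )
    def test_bin_edges(self, sizes, bin_size, expect):
        bins = make_bins(sizes, bin_size)
        df = bins.to_frame()
        assert list(zip(df["start"], df["end"])) == expect

    def test_total_count_two_chromosomes(self):
        bins = make_bins({"chrA": 30_000_000, "chrB": 20_000_000}, 10_000)
        assert bins.n_bins == 5_000

    def test_index_monotone_in_chrom_order_and_start(self):
        bins = make_bins({"c2": 35_000, "c1": 20_000}, 10_000)
        coords = [bins.bin_coords(k) for k in range(bins.n_bins)]
        assert coords[0][0] == "c2" and coords[-1][0] == "c1"
        assert bins.bin_index("c1", 0) == bins.offset("c1") == 4

    @pytest.mark.parametrize(
        "sizes,bin_size",
        [({}, 10_000), ({"chrA": 10_000}, 0), ({"chrA": -5}, 10)],
    )
    def test_invalid_inputs_raise(self, sizes, bin_size):
        with pytest.raises(ValueError):
            make_bins(sizes, bin_size)


class TestBalance:
    def test_constant_matrix_gives_equal_weights(self):
        m = toy_matrix(np.full((5, 5), 5.0))
        w = mx.balance(m, marginal_filter=0.0)
        assert np.allclose(w, w[0])
        marg = (m.block("chrA", "chrA") * np.outer(w, w)).sum(axis=1)
        assert np.std(marg) / np.mean(marg) < 1e-5

    def test_recovers_planted_biases(self):
        rng = np.random.default_rng(0)
        n = 120
        b = np.exp(rng.normal(0, 0.4, n))
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        d = np.minimum(d, n - d)  # circulant decay: constant marginals, so only b remains
        base = 100.0 / (1.0 + d)
        m = toy_matrix(np.outer(b, b) * base)
        w = mx.balance(m, tol=1e-8, marginal_filter=0.0)
        rho = spearmanr(np.log(w), -np.log(b)).statistic
        assert rho > 0.99
        # and pearson on logs, since the relation should be linear
        assert np.corrcoef(np.log(w), -np.log(b))[0, 1] > 0.99

    def test_zero_row_masked_others_converge(self):
        vals = np.full((6, 6), 4.0)
        vals[2, :] = 0
        vals[:, 2] = 0
        m = toy_matrix(vals)
        w = mx.balance(m, marginal_filter=0.0)
        assert np.isnan(w[2]) and np.isfinite(np.delete(w, 2)).all()

    def test_rebalancing_is_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(8.0, (30, 30)).astype(float)
        vals = (vals + vals.T) / 2
        m = toy_matrix(vals)
        w = mx.balance(m, tol=1e-8, marginal_filter=0.0)
        m2 = toy_matrix(vals * np.outer(w, w))
        w2 = mx.balance(m2, tol=1e-8, marginal_filter=0.0)
        assert np.nanstd(w2) / np.nanmean(w2) < 1e-6

    def test_nonconvergence_raises_with_cv(self):
        m = toy_matrix(np.full((8, 8), 3.0) + np.diag(np.arange(8.0)))
        with pytest.raises(mx.BalanceError) as err:
            mx.balance(m, tol=1e-16, max_iter=2, marginal_filter=0.0)
        assert err.value.cv > 0


class TestExpected:
    def test_exact_decay_recovered(self):
        n = 30
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        m = toy_matrix(1.0 / (1.0 + d), weights=np.ones(n))
        exp = mx.cis_expected(m, smoothing="none")
        assert np.allclose(exp.cis["chrA"], 1.0 / (1.0 + np.arange(n)))

    def test_matches_per_diagonal_brute_force(self):
        rng = np.random.default_rng(2)
        n = 40
        vals = rng.poisson(5.0, (n, n)).astype(float)
        vals = np.triu(vals) + np.triu(vals, 1).T
        w = np.ones(n)
        w[[3, 17]] = np.nan
        m = toy_matrix(vals, weights=w)
        exp = mx.cis_expected(m, smoothing="none")
        bal = vals * np.outer(w, w)
        for dist in range(n):
            pix = [bal[i, i + dist] for i in range(n - dist) if np.isfinite(bal[i, i + dist])]
            if pix:
                assert exp.cis["chrA"][dist] == np.sum(pix) / len(pix)
            else:
                assert np.isnan(exp.cis["chrA"][dist])

    def test_oe_self_normalisation_per_diagonal(self, small_sim):
        oe = small_sim["oe"]
        block = oe.block("chr1", "chr1")
        for dist in (2, 5, 20, 100):
            diag = np.diagonal(block, dist)
            vals = diag[np.isfinite(diag)]
            assert abs(vals.mean() - 1.0) < 1e-12

    def test_log_window_smoothing_pools_far_distances(self):
        rng = np.random.default_rng(3)
        n = 200
        vals = rng.poisson(3.0, (n, n)).astype(float)
        vals = np.triu(vals) + np.triu(vals, 1).T
        m = toy_matrix(vals, weights=np.ones(n))
        sm = mx.cis_expected(m, smoothing="log-window")
        raw = mx.cis_expected(m, smoothing="none")
        assert np.allclose(sm.cis["chrA"][:40], raw.cis["chrA"][:40], equal_nan=True)
        assert np.nanstd(sm.cis["chrA"][40:]) < np.nanstd(raw.cis["chrA"][40:])


class TestTransExpected:
    def _two_chrom(self, block_vals):
        bins = make_bins({"c1": 40_000, "c2": 40_000}, 10_000)
        cis = np.full((4, 4), 2.0)
        m = ContactMatrix(
            bins,
            {("c1", "c1"): cis.copy(), ("c2", "c2"): cis.copy(), ("c1", "c2"): block_vals},
            weights=np.ones(8),
        )
        return m

    def test_constant_block_gives_oe_one(self):
        m = self._two_chrom(np.full((4, 4), 3.0))
        exp_t = mx.trans_expected(m)
        assert exp_t.trans[("c1", "c2")] == 3.0
        oe = mx.observed_over_expected(m, mx.cis_expected(m, smoothing="none"), trans_exp=exp_t)
        assert np.allclose(oe.block("c1", "c2"), 1.0)

    def test_random_block_equals_grand_mean(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(6.0, (4, 4)).astype(float)
        m = self._two_chrom(vals)
        exp_t = mx.trans_expected(m)
        assert exp_t.trans[("c1", "c2")] == pytest.approx(vals.mean(), rel=1e-12)

    def test_each_pair_normalised_by_its_own_mean(self, small_sim):
        oe = small_sim["oe"]
        block = oe.block("chr1", "chr2")
        vals = block[np.isfinite(block)]
        assert vals.mean() == pytest.approx(1.0, abs=1e-9)


class TestObservedOverExpected:
    def test_matrix_equal_to_expected_gives_ones(self):
        n = 20
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        m = toy_matrix(2.0 / (1.0 + d), weights=np.ones(n))
        oe = mx.observed_over_expected(m, mx.cis_expected(m, smoothing="none"))
        block = oe.block("chrA", "chrA")
        assert np.allclose(block, 1.0)

    def test_single_scaled_pixel(self):
        n = 30
        vals = np.ones((n, n))
        vals[5, 20] = vals[20, 5] = 4.0
        m = toy_matrix(vals, weights=np.ones(n))
        exp = mx.ExpectedModel(bins=m.bins, cis={"chrA": np.ones(n)})
        oe = mx.observed_over_expected(m, exp)
        assert oe.block("chrA", "chrA")[5, 20] == 4.0

    def test_masked_bin_row_undefined(self):
        n = 10
        w = np.ones(n)
        w[4] = np.nan
        m = toy_matrix(np.ones((n, n)), weights=w)
        oe = mx.observed_over_expected(m, mx.cis_expected(m, smoothing="none"))
        assert np.isnan(oe.block("chrA", "chrA")[4]).all()

    def test_mismatched_bin_tables_raise(self):
        m = toy_matrix(np.ones((5, 5)), weights=np.ones(5))
        other = toy_matrix(np.ones((6, 6)), weights=np.ones(6))
        exp = mx.cis_expected(other, smoothing="none")
        with pytest.raises(ValueError):
            mx.observed_over_expected(m, exp)

    def test_cis_oe_blocks_stay_symmetric(self, small_sim):
        block = small_sim["oe"].block("chr1", "chr1")
        finite = np.isfinite(block)
        assert (finite == finite.T).all()
        assert np.allclose(block[finite], block.T[finite])


class TestIO:
    def test_text_roundtrip(self, tmp_path, small_sim):
        m = small_sim["matrix"]
        mx.write_text(m, tmp_path / "bins.tsv", tmp_path / "pixels.tsv")
        back = mx.read_text(tmp_path / "bins.tsv", tmp_path / "pixels.tsv")
        assert back.bins.chromsizes == m.bins.chromsizes
        for key in m.blocks:
            assert np.allclose(back.blocks[key], m.blocks[key])
        assert np.allclose(back.weights, m.weights, equal_nan=True)

    def test_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        vals = rng.poisson(4.0, (12, 12)).astype(float)
        vals = np.triu(vals) + np.triu(vals, 1).T
        m = toy_matrix(vals)
        mx.write_hdf5(m, tmp_path / "m.h5")
        back = mx.read_hdf5(tmp_path / "m.h5")
        assert np.allclose(back.block("chrA", "chrA"), vals)
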