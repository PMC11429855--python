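"""Kernel scoring, Poisson significance, clustering, and stage classification."""

import numpy as np
import pandas as pd
import pytest

from mcdhic import matrix as mx
from mcdhic.calling import (
    KernelSet,
    bh_adjust,
    call_mcds,
    classify_stage,
    cluster_to_domains,
    score_pixels,
)

from conftest import toy_matrix


def bh_oracle(pvals):
    """Hand-rolled BH step-up: q_(i) = min over j>=i of p_(j)*m/j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return np.minimum(q, 1.0)


def poisson_tail_oracle(k, lam, terms=400):
    """P(X >= k) by direct pmf summation."""
    total = 0.0
    for x in range(int(k), int(k) + terms):
        logp = -lam + x * np.log(lam) - sum(np.log(t) for t in range(1, x + 1))
        total += np.exp(logp)
    return total


class TestKernels:
    def test_footprints_nonempty_disjoint_from_peak(self):
        ks = KernelSet(p=1, w=5)
        p, w = ks.p, ks.w
        di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
        peak = (np.abs(di) <= p) & (np.abs(dj) <= p)
        for name, fp in ks.footprints.items():
            assert fp.any(), name
            assert not (fp & peak).any(), name
            assert fp.shape == (2 * w + 1, 2 * w + 1)

    def test_lowerleft_is_one_quadrant(self):
        ks = KernelSet(p=1, w=4)
        fp = ks.footprints["lowerleft"]
        di, dj = np.meshgrid(np.arange(-4, 5), np.arange(-4, 5), indexing="ij")
        assert (di[fp] >= 1).all() and (dj[fp] <= -1).all()

    def test_w_not_greater_than_p_raises(self):
        with pytest.raises(ValueError):
            KernelSet(p=3, w=3)


class TestBH:
    def test_worked_step_up_example(self):
        q = bh_adjust(np.array([0.001, 0.01, 0.02, 0.9]))
        assert np.allclose(q, [0.004, 0.02, 4 * 0.02 / 3, 0.9], rtol=1e-12)

    def test_matches_oracle_on_random_pvalues(self):
        rng = np.random.default_rng(6)
        p = rng.random(500) ** 2
        assert np.allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)


def _flat_scored(n=120, value=6.0, w=5):
    m = toy_matrix(np.full((n, n), value), weights=np.ones(n))
    exp = mx.cis_expected(m, smoothing="none")
    return score_pixels(m, exp, KernelSet(p=1, w=w), min_sep=5, max_sep=60)


class TestScorePixels:
    def test_flat_matrix_has_no_significant_pixels(self):
        calls = _flat_scored()
        assert len(calls) > 0
        assert calls["significant"].sum() == 0

    def test_poisson_tail_matches_term_summation(self):
        n = 80
        vals = np.full((n, n), 2.0)
        vals[30, 50] = vals[50, 30] = 12.0
        m = toy_matrix(vals, weights=np.ones(n))
        exp = mx.ExpectedModel(bins=m.bins, cis={"chrA": np.full(n, 2.0)})
        calls = score_pixels(m, exp, KernelSet(p=1, w=5), min_sep=5, max_sep=40)
        row = calls[(calls["bin1"] == 30) & (calls["bin2"] == 50)].iloc[0]
        for kernel in ("donut", "lowerleft", "horizontal", "vertical"):
            lam = row[f"lambda_{kernel}"] / row["weight_prod"]
            expect = poisson_tail_oracle(12, lam)
            assert row[f"p_{kernel}"] == pytest.approx(expect, rel=1e-12)

    def test_min_sep_respects_peak_zone(self):
        m = toy_matrix(np.ones((40, 40)), weights=np.ones(40))
        exp = mx.cis_expected(m, smoothing="none")
        with pytest.raises(ValueError):
            score_pixels(m, exp, KernelSet(p=2, w=6), min_sep=3)

    def test_heavily_clipped_edge_windows_are_skipped(self):
        calls = _flat_scored(n=60, w=10)
        # diagonal-corner pixels lose most of their footprint and are skipped,
        # but pixels with a merely clipped window are still evaluated
        assert not ((calls["bin1"] == 0) & (calls["bin2"] == 5)).any()
        assert (calls["bin1"] < 10).any()

    def test_matches_brute_force_on_small_matrix(self, small_sim):
        """Full oracle equivalence: kernel lambdas by explicit loops."""
        m = small_sim["matrix"]
        exp = small_sim["expected_smooth"]
        ks = KernelSet(p=1, w=5)
        calls = score_pixels(m, exp, ks, min_sep=5, max_sep=30)
        chrom = "chr1"
        sub = calls[calls["chrom"] == chrom]
        w_bins = m.weights_of(chrom)
        bal = m.block(chrom, chrom) * np.outer(w_bins, w_bins)
        n = bal.shape[0]
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(exp.cis[chrom][dist] > 0, bal / exp.cis[chrom][dist], np.nan)
        rng = np.random.default_rng(7)
        take = rng.choice(len(sub), size=60, replace=False)
        offsets = {
            name: np.argwhere(fp) - ks.w for name, fp in ks.footprints.items()
        }
        for k in take:
            row = sub.iloc[k]
            i, j = int(row["bin1"]), int(row["bin2"])
            for name, offs in offsets.items():
                vals = []
                for di, dj in offs:
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n and np.isfinite(oe[ii, jj]):
                        vals.append(oe[ii, jj])
                lam = exp.cis[chrom][dist[i, j]] * np.mean(vals)
                assert row[f"lambda_{name}"] == pytest.approx(lam, rel=1e-8)


class TestClusterToDomains:
    def _calls(self, pixels, bin_size=10_000, n=1_000):
        df = pd.DataFrame(pixels, columns=["bin1", "bin2"])
        df["chrom"] = "chrA"
        df["significant"] = True
        df["enrichment"] = 3.0
        return df

    def _bins(self, n=1_000):
        from mcdhic.bins import make_bins

        return make_bins({"chrA": n * 10_000}, 10_000)

    def test_single_pixel_footprint_too_small(self):
        domains = cluster_to_domains(self._calls([(100, 300)]), self._bins())
        assert domains.empty  # 10 kb anchors are below the 25 kb size floor

    def test_three_adjacent_anchors_make_one_30kb_domain(self):
        calls = self._calls([(100, 300), (101, 300), (102, 300)])
        domains = cluster_to_domains(calls, self._bins())
        spans = set(zip(domains["start"], domains["end"]))
        assert (100 * 10_000, 103 * 10_000) in spans

    def test_oversized_anchor_run_discarded(self):
        calls = self._calls([(100 + k, 400) for k in range(13)])  # 130 kb run
        domains = cluster_to_domains(calls, self._bins())
        assert not ((domains["start"] == 100 * 10_000).any())

    def test_summit_tie_breaks_to_lowest_coordinate(self):
        calls = self._calls([(100, 300), (101, 300), (102, 300)])
        domains = cluster_to_domains(calls, self._bins())
        row = domains[domains["start"] == 100 * 10_000].iloc[0]
        assert row["summit"] == 100 * 10_000

    def test_merge_radius_links_nearby_pixels(self):
        near = self._calls([(100, 300), (102, 302), (104, 300)])
        domains = cluster_to_domains(near, self._bins(), merge_radius=2)
        assert (domains["end"] - domains["start"]).max() >= 50_000

    def test_empty_input_gives_empty_output(self):
        empty = self._calls([]).iloc[0:0]
        assert cluster_to_domains(empty, self._bins()).empty


class TestCallMcds:
    def test_deterministic_output(self, small_sim):
        m, exp = small_sim["matrix"], small_sim["expected_smooth"]
        d1, r1 = call_mcds(m, exp, max_sep=100)
        d2, r2 = call_mcds(m, exp, max_sep=100)
        assert d1.equals(d2) and r1 == r2

    def test_all_domains_satisfy_size_invariant(self, small_sim):
        d, _ = call_mcds(small_sim["matrix"], small_sim["expected_smooth"], max_sep=100)
        sizes = d["end"] - d["start"]
        assert ((sizes >= 25_000) & (sizes <= 125_000)).all()
        assert ((d["summit"] >= d["start"]) & (d["summit"] < d["end"])).all()

    def test_recovers_most_planted_domains_small_genome(self, small_sim):
        from mcdhic.intervals import reciprocal_overlap_match

        truth = small_sim["truth"]
        d, _ = call_mcds(small_sim["matrix"], small_sim["expected_smooth"])
        rec = (reciprocal_overlap_match(truth.mcds, d, 0.5) >= 0).mean()
        assert rec >= 0.7


class TestClassifyStage:
    def _bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_identical_sets_all_cytokinesis(self):
        a = self._bed([("c", 0, 50_000), ("c", 100_000, 150_000)])
        out = classify_stage(a, a.copy())
        assert (out["stage"] == "cytokinesis-detected").all()

    def test_disjoint_sets_all_g1_specific(self):
        a = self._bed([("c", 0, 50_000)])
        b = self._bed([("c", 200_000, 260_000)])
        out = classify_stage(a, b)
        assert (out["stage"] == "G1-specific").all()

    def test_partial_overlap_meets_threshold(self):
        # 50 kb G1 domain overlapping a 60 kb early domain by 30 kb: 0.6 / 0.5 reciprocal
        early = self._bed([("c", 0, 60_000)])
        late = self._bed([("c", 30_000, 80_000)])
        out = classify_stage(early, late, min_overlap=0.5)
        assert out.iloc[0]["stage"] == "cytokinesis-detected"
        out2 = classify_stage(early, late, min_overlap=0.7)
        assert out2.iloc[0]["stage"] == "G1-specific"

    def test_output_partitions_late_set(self):
        rng = np.random.default_rng(8)
        early = self._bed([("c", int(s), int(s) + 40_000) for s in rng.integers(0, 5_000_000, 20)])
        late = self._bed([("c", int(s), int(s) + 40_000) for s in rng.integers(0, 5_000_000, 30)])
        out = classify_stage(early, late)
        n_cyt = (out["stage"] == "cytokinesis-detected").sum()
        n_g1 = (out["stage"] == "G1-specific").sum()
        assert n_cyt + n_g1 == len(late)
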