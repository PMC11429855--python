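"""Loop strength, nested extrusion domains, anchor overlap, pruning classes."""

import numpy as np
import pandas as pd
import pytest

from mcdhic.bins import make_bins
from mcdhic.extrusion import (
    anchor_overlap_count,
    classify_pairs,
    is_convergent,
    loop_strength,
    nest_to_domains,
    pruning_summary,
)
from mcdhic.matrix import OEMatrix


def _loops(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start1", "end1", "start2", "end2"])
    df["strand1"] = "+"
    df["strand2"] = "-"
    return df


def _flat_oe(n=300, value=1.0):
    bins = make_bins({"c1": n * 10_000}, 10_000)
    return OEMatrix(bins=bins, blocks={("c1", "c1"): np.full((n, n), value)},
                    weights=np.ones(n))


def nest_oracle(loops):
    """O(n^2) containment grouping with the same published tie-break."""
    lo = loops["start1"].to_numpy()
    hi = loops["end2"].to_numpy()
    chrom = loops["chrom"].to_numpy()
    order = sorted(range(len(loops)), key=lambda k: (chrom[k], lo[k], hi[k]))
    pos = {k: r for r, k in enumerate(order)}
    span = hi - lo

    def contains(x, y):
        if chrom[x] != chrom[y] or lo[x] > lo[y] or hi[x] < hi[y]:
            return False
        if span[x] > span[y]:
            return True
        return lo[x] == lo[y] and hi[x] == hi[y] and pos[x] < pos[y]

    roots = [k for k in range(len(loops))
             if not any(contains(x, k) for x in range(len(loops)) if x != k)]
    assign = {}
    for k in range(len(loops)):
        if k in roots:
            assign[k] = k
            continue
        cands = [r for r in roots if chrom[r] == chrom[k] and lo[r] <= lo[k] and hi[r] >= hi[k]]
        assign[k] = min(cands, key=lambda r: (span[r], lo[r]))
    groups = {}
    for k, r in assign.items():
        groups.setdefault(r, set()).add(k)
    return {frozenset(v) for v in groups.values()}


class TestLoopStrength:
    def test_flat_oe_unit_strength(self):
        oe = _flat_oe()
        loops = _loops([("c1", 500_000, 510_000, 700_000, 710_000)])
        scored, stack = loop_strength(oe, loops)
        assert scored["strength"].iloc[0] == pytest.approx(1.0)
        assert np.allclose(stack[np.isfinite(stack)], 1.0)

    def test_central_zone_equals_nine_pixel_mean(self):
        rng = np.random.default_rng(13)
        oe = _flat_oe()
        oe.blocks[("c1", "c1")] += rng.random((300, 300))
        loops = _loops([("c1", 500_000, 510_000, 700_000, 710_000)])
        scored, _ = loop_strength(oe, loops)
        block = oe.block("c1", "c1")
        i, j = 50, 70  # anchor midpoints in bins
        oracle = block[i - 1 : i + 2, j - 1 : j + 2].mean()
        assert scored["strength"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_grand_mean_invariant_to_global_rescale(self):
        rng = np.random.default_rng(14)
        base = rng.random((300, 300)) + 0.5
        loops = _loops([("c1", 500_000, 510_000, 700_000, 710_000),
                        ("c1", 1_000_000, 1_010_000, 1_400_000, 1_410_000)])
        oe1 = _flat_oe(); oe1.blocks[("c1", "c1")] = base
        oe2 = _flat_oe(); oe2.blocks[("c1", "c1")] = base * 11.0
        s1, _ = loop_strength(oe1, loops)
        s2, _ = loop_strength(oe2, loops)
        assert np.allclose(s2["strength"], s1["strength"] * 11.0)

    def test_masked_anchor_gives_nan_strength(self):
        oe = _flat_oe()
        oe.blocks[("c1", "c1")][49:52, 69:72] = np.nan
        loops = _loops([("c1", 500_000, 510_000, 700_000, 710_000)])
        scored, _ = loop_strength(oe, loops)
        assert np.isnan(scored["strength"].iloc[0])


class TestNestToDomains:
    def test_nested_pair_one_domain(self):
        loops = _loops([("c1", 100_000, 110_000, 490_000, 500_000),
                        ("c1", 200_000, 210_000, 390_000, 400_000)])
        domains, assign = nest_to_domains(loops)
        assert len(domains) == 1
        assert domains.iloc[0]["start"] == 100_000 and domains.iloc[0]["end"] == 500_000
        assert domains.iloc[0]["n_loops"] == 2
        assert assign[0] == assign[1]

    def test_overlap_without_containment_two_domains(self):
        loops = _loops([("c1", 100_000, 110_000, 290_000, 300_000),
                        ("c1", 200_000, 210_000, 390_000, 400_000)])
        domains, assign = nest_to_domains(loops)
        assert len(domains) == 2
        assert assign[0] != assign[1]

    def test_singleton_loops_give_singleton_domains(self):
        loops = _loops([("c1", 100_000, 110_000, 200_000, 210_000),
                        ("c1", 800_000, 810_000, 900_000, 910_000)])
        domains, _ = nest_to_domains(loops)
        assert len(domains) == 2 and (domains["n_loops"] == 1).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(15)
        rows = []
        for _ in range(30):
            s = int(rng.integers(0, 5_000_000))
            e = s + int(rng.integers(100_000, 2_000_000))
            rows.append(("c1", s, s + 10_000, e, e + 10_000))
        loops = _loops(rows)
        d1, _ = nest_to_domains(loops)
        d2, _ = nest_to_domains(loops.sample(frac=1, random_state=1))
        assert d1.equals(d2)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_quadratic_oracle_random_sets(self, trial):
        rng = np.random.default_rng(100 + trial)
        rows = []
        for _ in range(int(rng.integers(2, 50))):
            chrom = "c1" if rng.random() < 0.7 else "c2"
            s = int(rng.integers(0, 3_000_000))
            e = s + int(rng.integers(50_000, 2_000_000))
            rows.append((chrom, s, s + 10_000, e, e + 10_000))
        loops = _loops(rows)
        _, assign = nest_to_domains(loops)
        groups = {}
        for k, r in enumerate(assign):
            groups.setdefault(r, set()).add(k)
        assert {frozenset(v) for v in groups.values()} == nest_oracle(loops)


class TestAnchorOverlap:
    def test_single_hit(self):
        mcd = {"chrom": "c1", "start": 100_000, "end": 150_000}
        loops = _loops([("c1", 120_000, 130_000, 700_000, 710_000)])
        assert anchor_overlap_count(mcd, loops) == 1

    def test_no_anchors_on_chromosome(self):
        mcd = {"chrom": "c9", "start": 100_000, "end": 150_000}
        loops = _loops([("c1", 120_000, 130_000, 700_000, 710_000)])
        assert anchor_overlap_count(mcd, loops) == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(16)
        loops = _loops([
            ("c1", int(s), int(s) + 10_000, int(s) + 200_000, int(s) + 210_000)
            for s in rng.integers(0, 4_000_000, 40)
        ])
        for _ in range(25):
            start = int(rng.integers(0, 4_000_000))
            mcd = {"chrom": "c1", "start": start, "end": start + 60_000}
            oracle = 0
            for row in loops.itertuples():
                for s, e in ((row.start1, row.end1), (row.start2, row.end2)):
                    if s < mcd["end"] and e > mcd["start"]:
                        oracle += 1
            assert anchor_overlap_count(mcd, loops) == oracle


class TestClassifyPairs:
    def _setup(self):
        mcds = pd.DataFrame(
            {
                "chrom": ["c1"] * 4 + ["c2"],
                "start": [100_000, 500_000, 1_200_000, 3_000_000, 100_000],
                "end": [150_000, 550_000, 1_250_000, 3_050_000, 150_000],
            }
        )
        mcds["summit"] = (mcds["start"] + mcds["end"]) // 2
        # loop joining MCD0 and MCD1; a big domain containing MCD0..MCD2
        loops = _loops([
            ("c1", 110_000, 120_000, 510_000, 520_000),
            ("c1", 50_000, 60_000, 1_400_000, 1_410_000),
        ])
        domains, _ = nest_to_domains(loops)
        return mcds, loops, domains

    def _pairs(self, a, b, cis=True, sep=1_000_000):
        return pd.DataFrame({"mcd_a": [a], "mcd_b": [b], "cis": [cis],
                             "separation": [sep if cis else -1]})

    def test_loop_exact(self):
        mcds, loops, domains = self._setup()
        out = classify_pairs(self._pairs(0, 1), mcds, loops, domains)
        assert out["pruning_class"].iloc[0] == "loop-exact"

    def test_anchor_and_intra_tad(self):
        mcds, loops, domains = self._setup()
        out = classify_pairs(self._pairs(1, 2), mcds, loops, domains)
        assert out["pruning_class"].iloc[0] == "anchor>=1 & intra-TAD"

    def test_no_anchor_inter_tad(self):
        mcds, loops, domains = self._setup()
        # MCD2 and MCD3 overlap no anchor and live in different domains
        out = classify_pairs(self._pairs(2, 3), mcds, loops, domains)
        assert out["pruning_class"].iloc[0] == "anchor=0 & inter-TAD"

    def test_anchor_inter_tad_and_trans(self):
        mcds, loops, domains = self._setup()
        # MCD1 sits on a loop anchor; MCD3 is outside every domain
        out = classify_pairs(self._pairs(1, 3), mcds, loops, domains)
        assert out["pruning_class"].iloc[0] == "anchor>=1 & inter-TAD"
        lonely = pd.DataFrame({"mcd_a": [3], "mcd_b": [4], "cis": [False], "separation": [-1]})
        out3 = classify_pairs(lonely, mcds, loops, domains)
        assert out3["pruning_class"].iloc[0] == "trans"

    def test_partition_is_exhaustive(self, small_sim):
        from mcdhic.pairs import project_pairs

        truth = small_sim["truth"]
        mcds = truth.mcds.assign(summit=(truth.mcds["start"] + truth.mcds["end"]) // 2)
        pairs = project_pairs(mcds, min_sep=100_000)
        domains, _ = nest_to_domains(truth.loops)
        out = classify_pairs(pairs, mcds, truth.loops, domains)
        counts = out["pruning_class"].value_counts()
        assert counts.sum() == len(pairs)
        from mcdhic.extrusion import PRUNING_CLASSES

        assert set(counts.index) <= set(PRUNING_CLASSES)


class TestPruningSummary:
    def test_identical_conditions_unit_ratios(self):
        rng = np.random.default_rng(17)
        n = 60
        pairs = pd.DataFrame(
            {
                "cis": True,
                "separation": rng.integers(100_000, 3_000_000, n),
                "pruning_class": rng.choice(["anchor>=1 & inter-TAD", "anchor=0 & inter-TAD"], n),
                "s1": rng.random(n) + 1,
            }
        )
        pairs["s2"] = pairs["s1"]
        out = pruning_summary(pairs, [0, 500_000, 5_000_000],
                              {"a": "s1", "b": "s2"}, ratio_of=("a", "b"))
        assert np.allclose(out["ratio"].dropna(), 1.0)

    def test_cell_means_match_groupby_oracle(self):
        rng = np.random.default_rng(18)
        n = 200
        pairs = pd.DataFrame(
            {
                "cis": True,
                "separation": rng.integers(0, 4_999_999, n),
                "pruning_class": rng.choice(["x", "y"], n),
                "s1": rng.random(n),
                "s2": rng.random(n),
            }
        )
        out = pruning_summary(pairs, [0, 2_000_000, 5_000_000], {"a": "s1", "b": "s2"})
        for _, row in out.iterrows():
            if row["stratum"] == "trans":
                continue
            lo, hi = map(int, row["stratum"].split("-"))
            sel = (pairs["separation"] >= lo) & (pairs["separation"] < hi) & (
                pairs["pruning_class"] == row["pruning_class"]
            )
            if sel.sum():
                assert row["mean_s1"] == pytest.approx(pairs.loc[sel, "s1"].mean(), rel=1e-12)
            else:
                assert row["n"] == 0
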