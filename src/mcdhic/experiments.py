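"""Frozen benchmark experiments on synthetic data.

Each experiment builds its study conditions from a fixed configuration plus a
caller-supplied seed, runs the relevant pipeline stages from scratch, and
returns the measured quantities. They are used by the acceptance script, the
acceptance test suite, and the numbered analysis drivers, so the same
definitions produce every reported number.

Experiment design notes (see docs/methods.md for rationale):

* Recovery and pruning runs use the transport-depleted G1 condition the
  domains are called in: no cohesin loop enrichment, no extrusion bump.
* The focal-recovery (mu sweep) run uses a sparse-MCD, single-factor
  configuration: 20 domains of 30-60 kb (~2% of the genome) with
  compartments off, so iterative correction leaves the planted focal factor
  approximately unbiased.
* The pruning run gives both conditions identical physics except the planted
  long-range attenuation, and uses a 50% anchor fraction so both anchor
  classes are populated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import matrix as mx
from .calling import call_mcds
from .compartments import compute_ev1, loop_size_estimate, ps_curve, saddle
from .extrusion import classify_pairs, nest_to_domains, pruning_summary
from .intervals import reciprocal_overlap_match
from .pairs import project_pairs, score_pairs, stack_pileup
from .pipeline import run_pipeline
from .simulate import SimulationConfig, plant_features, simulate_annotations, simulate_counts

GENOME_2X20 = {"chr1": 20_000_000, "chr2": 20_000_000}


def _prepare(cfg: SimulationConfig, rng=None):
    truth = plant_features(cfg)
    m = simulate_counts(truth, cfg, rng=rng)
    m.weights = mx.balance(m)
    exp_raw = mx.cis_expected(m, smoothing="none")
    exp_trans = mx.trans_expected(m)
    oe = mx.observed_over_expected(m, exp_raw, trans_exp=exp_trans)
    return truth, m, oe


def _summits(mcds: pd.DataFrame) -> pd.DataFrame:
    out = mcds.copy()
    if "summit" not in out:
        out["summit"] = (out["start"] + out["end"]) // 2
    return out


# ---------------------------------------------------------------------------
# 1. MCD recovery and null control
# ---------------------------------------------------------------------------

def mcd_recovery_experiment(seed: int, replicates: int = 3) -> dict:
    """Call MCDs on 2x20 Mb / 10 kb / ~5e6 cis reads with 40 planted domains.

    Runs ``replicates`` independent simulations (derived seeds) and reports
    the mean fraction of planted domains recovered at >= 50% reciprocal
    overlap, the mean fraction of calls without a planted match, and the
    number of calls in a matched null simulation (mu = 1, nothing planted).
    Averaging over replicate genomes removes placement luck (how many planted
    domains happen to have no partner within the calling scan) from the
    benchmark.
    """
    recoveries, unmatched_fracs, n_called = [], [], []
    for rep in range(replicates):
        cfg = SimulationConfig(
            chromsizes=dict(GENOME_2X20), cis_reads=5_000_000, trans_reads=2_500_000,
            n_mcds=40, mcd_size_range=(30_000, 100_000), mu=4.0,
            loop_factor=1.0, bump_weight=0.0, seed=seed + 1009 * rep,
        )
        truth, m, _ = _prepare(cfg)
        exp_smooth = mx.cis_expected(m, smoothing="log-window")
        calls, _report = call_mcds(m, exp_smooth)
        recoveries.append(float((reciprocal_overlap_match(truth.mcds, calls, 0.5) >= 0).mean()))
        unmatched_fracs.append(
            float((reciprocal_overlap_match(calls, truth.mcds, 0.5) < 0).mean())
            if len(calls) else 0.0
        )
        n_called.append(len(calls))
    null_cfg = SimulationConfig(
        chromsizes=dict(GENOME_2X20), cis_reads=5_000_000, trans_reads=2_500_000,
        n_mcds=0, mu=1.0, loop_factor=1.0, bump_weight=0.0, seed=seed,
    )
    _, m0, _ = _prepare(null_cfg)
    null_calls, _ = call_mcds(m0, mx.cis_expected(m0, smoothing="log-window"))
    return {
        "n_planted": 40,
        "n_called": int(np.mean(n_called)),
        "recovery": float(np.mean(recoveries)),
        "unmatched": float(np.mean(unmatched_fracs)),
        "null_calls": len(null_calls),
        "replicates": replicates,
    }


# ---------------------------------------------------------------------------
# 2. Focal-enrichment (pile-up) recovery
# ---------------------------------------------------------------------------

def focal_recovery_experiment(seed: int, mu: float) -> dict:
    """Mean pile-up central O/E over planted pairs, cis and trans, at one mu.

    Weights come from the generator's planted biases (the TruthSet), so this
    benchmark measures the projection/pile-up machinery in isolation; the
    balancing estimator has its own recovery criteria, and at desk scale it
    would otherwise absorb part of the planted marginal enrichment.
    """
    cfg = SimulationConfig(
        chromsizes=dict(GENOME_2X20), cis_reads=5_000_000, trans_reads=2_500_000,
        n_mcds=20, mcd_size_range=(30_000, 60_000), mu=mu, kappa=1.0,
        loop_factor=1.0, bump_weight=0.0, seed=seed,
    )
    truth = plant_features(cfg)
    m = simulate_counts(truth, cfg)
    m.weights = 1.0 / truth.biases
    exp_raw = mx.cis_expected(m, smoothing="none")
    oe = mx.observed_over_expected(m, exp_raw, trans_exp=mx.trans_expected(m))
    mcds = _summits(truth.mcds)
    pairs = project_pairs(mcds, min_sep=100_000)
    cis = stack_pileup(oe, mcds, pairs[pairs["cis"]], half_width=10)
    trans = stack_pileup(oe, mcds, pairs[~pairs["cis"]], half_width=10)
    return {
        "mu": mu,
        "cis_central": cis.central_value,
        "trans_central": trans.central_value,
        "n_cis": cis.n_snippets,
        "n_trans": trans.n_snippets,
    }


def flat_pileup_experiment(seed: int) -> float:
    """Pile-up central value when O/E is identically 1 (background contract).

    Uses the planted MCD positions of a truth draw over an exactly flat O/E
    container: the mean map must be 1 everywhere.
    """
    from .matrix import OEMatrix

    cfg = SimulationConfig(
        chromsizes=dict(GENOME_2X20), n_mcds=20, mcd_size_range=(30_000, 60_000),
        loop_factor=1.0, bump_weight=0.0, seed=seed,
    )
    truth = plant_features(cfg)
    bins = truth.bins
    blocks = {}
    chroms = bins.chromosomes
    for a, c1 in enumerate(chroms):
        for c2 in chroms[a:]:
            blocks[(c1, c2)] = np.ones((bins.n_bins_of(c1), bins.n_bins_of(c2)))
    oe = OEMatrix(bins=bins, blocks=blocks, weights=np.ones(bins.n_bins))
    mcds = _summits(truth.mcds)
    pairs = project_pairs(mcds, min_sep=100_000)
    pile = stack_pileup(oe, mcds, pairs, half_width=10)
    return float(pile.central_value)


# ---------------------------------------------------------------------------
# 3. Loop-size recovery from the P(s) derivative
# ---------------------------------------------------------------------------

def loop_size_experiment(seed: int, loop_size: int | None) -> float | None:
    """Estimate the average loop size; ``loop_size=None`` runs the no-bump control."""
    cfg = SimulationConfig(
        chromsizes={"chr1": 20_000_000}, cis_reads=5_000_000, trans_reads=0,
        n_mcds=0, mu=1.0, kappa=1.0, bias_sigma=0.0, n_loops=0, loop_factor=1.0,
        bump_weight=0.0 if loop_size is None else 0.6,
        loop_mean_size=loop_size or 100_000, seed=seed,
    )
    truth = plant_features(cfg)
    m = simulate_counts(truth, cfg)
    m.weights = mx.balance(m)
    return loop_size_estimate(ps_curve(m))


# ---------------------------------------------------------------------------
# 4. Pruning logic across two conditions
# ---------------------------------------------------------------------------

def pruning_experiment(seed: int) -> pd.DataFrame:
    """Two-condition pruning report over one shared truth.

    The "control" condition halves the planted enrichment of cis pairs
    separated by > 500 kb with at least one anchor-overlapping MCD; the
    "depleted" condition plants the full grid. Both share every other factor.
    Returns the class x stratum table with the control/depleted ratio.
    """
    base = dict(
        chromsizes=dict(GENOME_2X20), cis_reads=5_000_000, trans_reads=2_500_000,
        n_mcds=40, mcd_size_range=(30_000, 100_000), mu=4.0, kappa=1.0,
        loop_factor=1.0, bump_weight=0.0, mcd_anchor_fraction=0.5, n_loops=30,
        seed=seed,
    )
    cfg_dep = SimulationConfig(**base)
    cfg_ctl = SimulationConfig(**base, prune_distance=500_000, prune_factor=0.5)
    truth = plant_features(cfg_dep)

    def oe_for(cfg, shift):
        m = simulate_counts(truth, cfg, rng=np.random.default_rng(seed + shift))
        m.weights = mx.balance(m)
        return mx.observed_over_expected(
            m, mx.cis_expected(m, smoothing="none"), trans_exp=mx.trans_expected(m)
        )

    oe_dep = oe_for(cfg_dep, 1)
    oe_ctl = oe_for(cfg_ctl, 101)
    mcds = _summits(truth.mcds)
    pairs = project_pairs(mcds, min_sep=100_000)
    scored = score_pairs(oe_dep, mcds, pairs, score_col="score_depleted")
    scored = score_pairs(oe_ctl, mcds, scored, score_col="score_control")
    domains, _ = nest_to_domains(truth.loops)
    classified = classify_pairs(scored, mcds, truth.loops, domains)
    report = pruning_summary(
        classified,
        [100_000, 500_000, 20_000_000],
        {"control": "score_control", "depleted": "score_depleted"},
        ratio_of=("control", "depleted"),
        seed=seed,
    )
    report.attrs["n_pairs"] = len(classified)
    report.attrs["class_counts"] = classified["pruning_class"].value_counts().to_dict()
    return report


# ---------------------------------------------------------------------------
# 6. Compartment monotonicity
# ---------------------------------------------------------------------------

def compartment_experiment(seed: int) -> pd.DataFrame:
    """Saddle AA/BB strength and EV1-truth agreement across planted kappa."""
    rows = []
    for kappa in (1.2, 1.5, 2.0):
        cfg = SimulationConfig(
            chromsizes=dict(GENOME_2X20), cis_reads=5_000_000, trans_reads=2_500_000,
            n_mcds=0, mu=1.0, kappa=kappa, loop_factor=1.0, bump_weight=0.0,
            seed=seed,
        )
        truth, _, oe = _prepare(cfg)
        ann = simulate_annotations(truth, cfg)
        ev = compute_ev1(oe, ann["gene_density"])
        ok = np.isfinite(ev.values)
        agreement = float(((ev.values > 0) == (truth.ab_labels == "A"))[ok].mean())
        res = saddle(ev, oe, quantiles=50, corner_fraction=0.2)
        rows.append(
            {"kappa": kappa, "aa": res.aa_strength, "bb": res.bb_strength,
             "ev1_agreement": agreement}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 7. End-to-end determinism
# ---------------------------------------------------------------------------

DETERMINISM_RUN = {
    "simulation": {
        "chromsizes": {"chr1": 10_000_000, "chr2": 10_000_000},
        "cis_reads": 2_500_000,
        "trans_reads": 1_000_000,
        "n_mcds": 16,
        "mcd_size_range": [30_000, 60_000],
        "n_loops": 20,
        "loop_factor": 1.0,
        "bump_weight": 0.0,
    },
}


def determinism_experiment(seed: int, workdir) -> dict:
    """Run the full pipeline twice from one seed; compare outputs byte-for-byte."""
    workdir = Path(workdir)
    config = dict(DETERMINISM_RUN, seed=seed)
    out1, out2 = workdir / "run1", workdir / "run2"
    run_pipeline(config, out1)
    run_pipeline(config, out2)
    names = sorted(p.name for p in out1.iterdir())
    identical = names == sorted(p.name for p in out2.iterdir()) and all(
        (out1 / n).read_bytes() == (out2 / n).read_bytes() for n in names
    )
    return {"identical": identical, "n_files": len(names)}
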