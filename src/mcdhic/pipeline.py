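"""End-to-end orchestration: one configured run from simulation to reports.

A run executes simulate -> balance -> expected -> call-mcds -> (stage) ->
pairs -> pile-ups -> loops/TADs -> pruning classification/report -> EV1 /
saddle / P(s) -> cCRE tables, writing every stage output as deterministic
text into the output directory together with a manifest of sha256 hashes and
the fully resolved configuration. All randomness flows from one seed through
named substreams per module.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, calling, compartments, extrusion, matrix as mx, pairs as pr
from .simulate import SimulationConfig, plant_features, simulate_annotations, simulate_counts

FLOAT_FMT = "%.6g"

DEFAULTS: dict[str, dict] = {
    "simulation": {f.name: f.default if f.default is not dataclasses.MISSING else None
                   for f in dataclasses.fields(SimulationConfig)},
    "balance": {"tol": 1e-5, "max_iter": 500, "marginal_filter": 0.02, "cis_only": False},
    "expected": {"smoothing": "log-window"},
    "calling": {"p": 1, "w": 12, "min_sep": 5, "max_sep": 200, "q_max": 0.1,
                "enrichment_min": 2.0, "merge_radius": 2,
                "size_min": 25_000, "size_max": 125_000},
    "pairs": {"min_sep": 100_000, "half_width": 10, "peak_halfwidth": 1,
              "ring_inner": 3, "ring_outer": 5, "score_threshold": 2.0},
    "pruning": {"enabled": False, "strata": [0, 500_000, 20_000_000],
                "prune_distance": 500_000, "prune_factor": 0.5},
    "compartments": {"quantiles": 50, "corner_fraction": 0.2, "min_prominence": 0.1},
    "seed": 0,
}
# simulation defaults that dataclasses.MISSING left as None are filled at build time


def resolve_config(user: dict | None) -> dict:
    """Fill defaults and reject unknown keys at both levels."""
    user = user or {}
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    resolved: dict = {}
    for section, defaults in DEFAULTS.items():
        if not isinstance(defaults, dict):
            resolved[section] = user.get(section, defaults)
            continue
        block = dict(user.get(section, {}) or {})
        bad = set(block) - set(defaults)
        if bad:
            raise ValueError(f"unknown key(s) in [{section}]: {sorted(bad)}")
        merged = {**defaults, **block}
        resolved[section] = merged
    return resolved


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _sim_config(resolved: dict, seed_shift: int = 0, **overrides) -> SimulationConfig:
    block = {k: v for k, v in resolved["simulation"].items() if v is not None}
    block.update(overrides)
    block["seed"] = int(resolved["seed"]) + seed_shift
    if "chromsizes" in block:
        block["chromsizes"] = dict(block["chromsizes"])
    if "mcd_size_range" in block:
        block["mcd_size_range"] = tuple(block["mcd_size_range"])
    return SimulationConfig(**block)


def _write_tsv(df: pd.DataFrame, path: Path, header: bool = True) -> None:
    df.to_csv(path, sep="\t", index=False, header=header, float_format=FLOAT_FMT)


def _write_matrix_tsv(arr: np.ndarray, path: Path) -> None:
    pd.DataFrame(arr).to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def prepare_condition(config: SimulationConfig, balance_cfg: dict, expected_cfg: dict):
    """Simulate one condition and derive weights, expected models and O/E."""
    truth = plant_features(config)
    m = simulate_counts(truth, config)
    m.weights = mx.balance(
        m, tol=balance_cfg["tol"], max_iter=balance_cfg["max_iter"],
        marginal_filter=balance_cfg["marginal_filter"], cis_only=balance_cfg["cis_only"],
    )
    exp_smooth = mx.cis_expected(m, smoothing=expected_cfg["smoothing"])
    exp_raw = mx.cis_expected(m, smoothing="none")
    exp_trans = mx.trans_expected(m)
    oe = mx.observed_over_expected(m, exp_raw, trans_exp=exp_trans)
    return truth, m, exp_smooth, exp_raw, exp_trans, oe


def run_pipeline(config: dict | None, outdir) -> dict:
    """Execute the full pipeline; returns the manifest mapping."""
    resolved = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df, name, header=True):
        path = outdir / name
        _write_tsv(df, path, header=header)
        written.append(path)
        return path

    sim = _sim_config(resolved)
    bal_cfg, exp_cfg = resolved["balance"], resolved["expected"]
    truth, m, exp_smooth, exp_raw, exp_trans, oe = prepare_condition(sim, bal_cfg, exp_cfg)

    mx.write_text(m, outdir / "matrix.bins.tsv", outdir / "matrix.pixels.tsv")
    written += [outdir / "matrix.bins.tsv", outdir / "matrix.pixels.tsv"]
    save(truth.mcds, "truth.mcds.bed", header=False)
    save(truth.loops, "truth.loops.bedpe", header=False)

    # --- MCD calling -----------------------------------------------------
    cal = resolved["calling"]
    kernels = calling.KernelSet(p=cal["p"], w=cal["w"])
    mcds, report = calling.call_mcds(
        m, exp_smooth, kernels, min_sep=cal["min_sep"], max_sep=cal["max_sep"],
        q_max=cal["q_max"], enrichment_min=cal["enrichment_min"],
        merge_radius=cal["merge_radius"], size_range=(cal["size_min"], cal["size_max"]),
    )
    save(mcds, "mcds.bed")
    save(pd.DataFrame([report]), "call_report.tsv")

    # --- pairwise projection and pile-ups --------------------------------
    pcfg = resolved["pairs"]
    results: dict = {"n_mcds": len(mcds)}
    if len(mcds) >= 2:
        pairs = pr.project_pairs(mcds, min_sep=pcfg["min_sep"])
        scored = pr.score_pairs(
            oe, mcds, pairs, peak_halfwidth=pcfg["peak_halfwidth"],
            ring_inner=pcfg["ring_inner"], ring_outer=pcfg["ring_outer"],
        )
        for name, sel in (("cis", scored["cis"]), ("trans", ~scored["cis"])):
            subset = scored[sel]
            if len(subset):
                try:
                    pile = pr.stack_pileup(oe, mcds, subset, half_width=pcfg["half_width"])
                    _write_matrix_tsv(pile.mean_map, outdir / f"pileup_{name}.tsv")
                    written.append(outdir / f"pileup_{name}.tsv")
                    results[f"pileup_{name}_central"] = pile.central_value
                except ValueError:
                    pass
        # pruning classification against the planted loop list
        domains, _ = extrusion.nest_to_domains(truth.loops)
        classified = extrusion.classify_pairs(scored, mcds, truth.loops, domains)
        save(classified, "classified_pairs.bedpe")
        save(domains, "tads.bed")
        loops_scored, _ = extrusion.loop_strength(oe, truth.loops)
        save(loops_scored, "loops.bedpe")
        prcfg = resolved["pruning"]
        profile = pr.distance_profile(
            classified, prcfg["strata"], ["focal_score"],
            group_keys=["pruning_class"], seed=int(resolved["seed"]),
        )
        save(profile, "prune_report.tsv")
        val = annotation.valency(mcds, classified, threshold=pcfg["score_threshold"])
        save(val, "valency.tsv")
        results["n_pairs_cis"] = pairs.attrs["n_cis"]
        results["n_pairs_trans"] = pairs.attrs["n_trans"]

    # --- compartments ----------------------------------------------------
    ann = simulate_annotations(truth, sim)
    ccfg = resolved["compartments"]
    ev = compartments.compute_ev1(oe, ann["gene_density"])
    ev_df = truth.bins.to_frame().assign(ev1=ev.values)
    save(ev_df, "ev1.bedgraph", header=False)
    try:
        sad = compartments.saddle(ev, oe, quantiles=ccfg["quantiles"],
                                  corner_fraction=ccfg["corner_fraction"])
        _write_matrix_tsv(sad.grid, outdir / "saddle.tsv")
        written.append(outdir / "saddle.tsv")
        results["saddle_aa"] = sad.aa_strength
        results["saddle_bb"] = sad.bb_strength
    except ValueError:
        pass
    curve = compartments.ps_curve(m)
    ps_df = pd.DataFrame(
        {"separation": curve.separations, "probability": curve.probabilities,
         "derivative": curve.derivative, "smoothed": curve.smoothed_derivative}
    )
    save(ps_df, "ps_curve.tsv")
    est = compartments.loop_size_estimate(curve, ccfg["min_prominence"])
    results["loop_size_estimate"] = est

    # --- cCRE / ATAC tables ----------------------------------------------
    union, fractions = annotation.intersect_peak_sets(ann["peak_sets"], restrict_to=mcds)
    save(union, "peak_categories.tsv")
    save(fractions.reset_index(names="category"), "peak_fractions.tsv")
    bookmarked = ann["elements"][
        (ann["elements"]["category"] == "bookmarked")
        & (ann["elements"]["cre_class"].isin(["promoter", "enhancer"]))
    ]
    if len(mcds):
        frac, _counts = annotation.mcd_bookmark_coverage(mcds, bookmarked)
        results["bookmark_coverage"] = frac
    targets = mcds[["chrom", "start", "end"]] if len(mcds) else truth.mcds
    genome = pd.DataFrame(
        [{"chrom": c, "start": 0, "end": l} for c, l in sim.chromsizes.items()]
    )
    folds = annotation.fold_enrichment(ann["elements"], targets, genome)
    save(folds, "cre_enrichment.tsv")

    # --- manifest ---------------------------------------------------------
    manifest_path = outdir / "manifest.txt"
    with open(manifest_path, "w") as fh:
        fh.write("# mcdhic run manifest\n")
        fh.write(f"seed: {resolved['seed']}\n")
        for key, val in sorted(results.items()):
            fh.write(f"result.{key}: {val}\n")
        fh.write("config:\n")
        for line in yaml.safe_dump(resolved, sort_keys=True).splitlines():
            fh.write(f"  {line}\n")
        for path in sorted(written, key=lambda p: p.name):
            fh.write(f"file.{path.name}: sha256={_sha256(path)}\n")
    results["manifest"] = str(manifest_path)
    results["outputs"] = [str(p) for p in written]
    return results
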