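# mcdhic

Analysis of **microcompartment domains (MCDs)** in Hi-C contact maps — the
fine-scale compartmentalization of active cis-regulatory elements that
emerges as cells exit mitosis — together with a synthetic Hi-C generator
that makes every stage testable by parameter recovery on a laptop.

When nuclear import is blocked during mitotic exit, post-mitotic chromosomes
fold a striking grid of focal contacts between small (25–125 kb) active
domains, in cis and in trans; in normal G1 cells cohesin-mediated loop
extrusion "prunes" the long-range part of this network. `mcdhic` implements
the computational side of that analysis:

* **matrix core** — binned contact matrices with iterative-correction
  balancing, distance-decay (cis) and chromosome-pair (trans) expected
  models, and observed/expected (O/E) transforms;
* **mcd caller** — focal-pixel detection with four local-background
  convolution kernels (donut, lower-left quadrant, two stripes), exact
  Poisson upper-tail tests, BH correction within geometric lambda-chunks,
  2D clustering with seed-and-extend anchor footprints, and the 25–125 kb
  domain size filter; staging of calls across time points;
* **pair aggregation** — projection of all C(N,2) domain pairs, O/E pile-ups
  centred on summits, focal scores (centre over square ring), and
  distance-stratified profiles with bootstrap CIs;
* **extrusion features** — convergent-CTCF loop strength, TADs as outermost
  nested loops, and the five-way pruning classification of cis pairs
  (loop-exact / anchor x TAD status) plus trans;
* **compartment profiles** — gene-density-phased EV1, quantile saddle plots
  with corner strengths, subcompartment x MCD aggregation, and average
  loop-size estimation from the peak of the P(s) log-log derivative;
* **cCRE annotation** — ATAC peak-set intersection categories (bookmarked
  vs condition-specific), cCRE fold enrichment, bookmark coverage of
  domains, and interaction valency;
* **synthetic generator** — Poisson contact maps with power-law decay, an
  extrusion bump whose derivative peak sits exactly at the configured mean
  loop size, A/B (or subcompartment) checkerboard, a planted MCD grid,
  convergent loop pixels, and log-normal per-bin biases — plus the planted
  truth for recovery testing.

The statistical core in one line: a pixel is a significant focal contact iff
its observed count exceeds all four kernel backgrounds
`lambda_k = E(s) * mean(O/E over kernel footprint)` with BH-adjusted Poisson
tail `P(X >= obs | lambda_k)` at q <= 0.1 and obs/max(lambda) >= 2; domains
are the 25–125 kb merged anchor footprints of significant-pixel clusters.

## Worked example

```python
from mcdhic import matrix as mx
from mcdhic.calling import call_mcds
from mcdhic.pairs import project_pairs, stack_pileup
from mcdhic.simulate import SimulationConfig, plant_features, simulate_counts

cfg = SimulationConfig(seed=1, loop_factor=1.0, bump_weight=0.0)  # 2x20 Mb, 40 MCDs, mu=4
truth = plant_features(cfg)
m = simulate_counts(truth, cfg)
m.weights = mx.balance(m)

mcds, report = call_mcds(m, mx.cis_expected(m))
print(len(truth.mcds), "planted,", len(mcds), "called;", report["pixels_significant"], "significant pixels")

oe = mx.observed_over_expected(m, mx.cis_expected(m, smoothing="none"),
                               trans_exp=mx.trans_expected(m))
pairs = project_pairs(mcds, min_sep=100_000)
pile = stack_pileup(oe, mcds, pairs[~pairs["cis"]], half_width=10)
print(f"trans pile-up central O/E: {pile.central_value:.2f} over {pile.n_snippets} pairs")
```

Output:

```
40 planted, 39 called; 634 significant pixels
trans pile-up central O/E: 3.77 over 338 pairs
```

Nearly all planted domains are recovered, and the trans pile-up over all
projected domain pairs shows a strong focal enrichment over the
chromosome-pair background (the planted factor is 4; iterative correction
absorbs part of the planted marginal enrichment at this desk-scale genome —
see `docs/methods.md`).

The numbered scripts under `analysis/` run the full study narrative
(simulate, call, project, pile up, estimate loop sizes, prune, profile
compartments, annotate cCREs) and write tables under `results/`. The same
stages are available as a CLI:

```bash
mcdhic run-all --seed 1 --out runs/demo          # full pipeline + manifest
mcdhic call-mcds --bins bins.tsv --pixels pixels.tsv --qmax 0.1 --out mcds.bed
mcdhic ps --bins bins.tsv --pixels pixels.tsv --out ps.tsv
```

Matrices travel as plain-text bin-table + COO TSV (or a minimal HDF5
container); features as BED/BEDPE; reports as TSV. Re-running any command
with the same seed reproduces every output byte-for-byte.

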