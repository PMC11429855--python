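"""Simulate the standard study genome and write its matrix and ground truth.

Generates the transport-depleted-like G1 condition used by the downstream
drivers: 2 x 20 Mb at 10 kb, ~5e6 cis / 2.5e6 trans reads, A/B checkerboard,
40 planted microcompartment domains (mu = 4) and convergent CTCF loop
positions (enrichment off in this condition: no cohesin without import).

Large matrix files go to scratch/standard_genome/ (regenerable); the planted
feature tables go to results/.
"""

from pathlib import Path

from mcdhic import matrix as mx
from mcdhic.simulate import SimulationConfig, plant_features, simulate_annotations, simulate_counts

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "standard_genome"
RESULTS = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(
        chromsizes={"chr1": 20_000_000, "chr2": 20_000_000},
        cis_reads=5_000_000, trans_reads=2_500_000,
        n_mcds=40, mcd_size_range=(30_000, 100_000), mu=4.0,
        loop_factor=1.0, bump_weight=0.0, seed=SEED,
    )
    truth = plant_features(cfg)
    m = simulate_counts(truth, cfg)
    m.weights = mx.balance(m)
    mx.write_text(m, OUT / "matrix.bins.tsv", OUT / "matrix.pixels.tsv")
    truth.mcds.to_csv(RESULTS / "planted_mcds.bed", sep="\t", index=False, header=False)
    truth.loops.to_csv(RESULTS / "planted_loops.bedpe", sep="\t", index=False, header=False)
    ann = simulate_annotations(truth, cfg)
    ann["elements"].to_csv(RESULTS / "planted_elements.bed", sep="\t", index=False, header=False)
    print(f"simulated {m.bins.n_bins} bins; "
          f"{int(m.total_counts(cis=True)):,} cis and {int(m.total_counts(cis=False)):,} trans counts")
    print(f"planted {len(truth.mcds)} MCDs ({truth.mcds.has_anchor.sum()} with a loop anchor) "
          f"and {len(truth.loops)} convergent loops")
    print(f"matrix -> {OUT}, truth tables -> {RESULTS}")


if __name__ == "__main__":
    main()
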