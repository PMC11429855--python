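"""Estimate average extruded-loop sizes from the P(s) log-log derivative.

Simulates contact decay with the extrusion bump centred at 50, 100 and 250 kb
(the cohesin-G1 vs condensin-prometaphase size contrast) plus a no-bump
control, and locates the derivative peak.
"""

from pathlib import Path

import pandas as pd

from mcdhic.experiments import loop_size_experiment

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for planted in (50_000, 100_000, 250_000, None):
        est = loop_size_experiment(SEED, planted)
        rows.append({"planted_bp": planted, "estimate_bp": est})
        label = f"{planted // 1000} kb" if planted else "no bump"
        shown = f"{est / 1000:.1f} kb" if est else "no peak"
        print(f"planted {label}: derivative peak at {shown}")
    pd.DataFrame(rows).to_csv(RESULTS / "loop_sizes.tsv", sep="\t", index=False)
    print(f"table -> {RESULTS / 'loop_sizes.tsv'}")


if __name__ == "__main__":
    main()
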