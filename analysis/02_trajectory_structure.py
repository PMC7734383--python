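#!/usr/bin/env python
"""Correlation structure of cfRNA trajectories in the weekly cohorts.

Computes pairwise Pearson correlations between per-week mean trajectories,
summarises within- and cross-tissue-group medians (placental and immune
transcripts travel together within their groups), and writes the gene-by-
gene matrix plus medians under results/analysis/. Run 01 first.
"""

from pathlib import Path

from cfpreg import report as rpt

RUN_DIR = Path("results/analysis")
SEED = 1


def main() -> None:
    cfg = rpt.load_config({"seed": SEED, "out_dir": str(RUN_DIR)})
    cor = rpt.run_correlate(cfg, RUN_DIR)
    print("median within-group trajectory correlation:")
    for group, r in sorted(cor["group_medians"].items()):
        print(f"  {group:12s} r = {r:.2f}")
    print("median cross-group correlation:")
    for pair, r in sorted(cor["cross_medians"].items()):
        print(f"  {pair:24s} r = {r:.2f}")


if __name__ == "__main__":
    main()
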