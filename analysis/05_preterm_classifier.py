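#!/usr/bin/env python
"""Preterm-delivery classification with the 3-gene combination ensemble.

Reads the screen/ensemble results written by 04 (re-running the stage if
needed): effect-size/FDR screen on the discovery cohort (8 preterm vs 26
term samples), all unique 3-gene combinations of the top seven transcripts,
and evaluation on the independent validation cohort (5 preterm vs 18 term).
"""

import json
from pathlib import Path

from cfpreg import report as rpt

RUN_DIR = Path("results/analysis")
SEED = 1


def main() -> None:
    stage_path = RUN_DIR / "preterm_stage.json"
    if stage_path.exists():
        pt = json.loads(stage_path.read_text())
    else:
        cfg = rpt.load_config({"seed": SEED, "out_dir": str(RUN_DIR)})
        RUN_DIR.mkdir(parents=True, exist_ok=True)
        pt = rpt.run_preterm(cfg, RUN_DIR)
    print(f"screen: {pt['n_screen_passing']} genes pass "
          f"(q <= 0.05 and g >= 0.8)")
    print(f"top transcripts: {', '.join(pt['top_genes'])}")
    print(f"ensemble: {pt['n_combos']} unique 3-gene combinations")
    for name in ("discovery", "validation"):
        ev = pt[name]
        c = ev["confusion"]
        line = (f"{name}: mean AUC = {ev['mean_auc']:.2f}; "
                f"{c['tp']}/{c['tp'] + c['fn']} preterm identified, "
                f"{c['fp']}/{c['fp'] + c['tn']} term misclassified")
        if c["tp"] + c["fp"]:
            line += f" (PPV {100 * ev['ppv']:.0f}%)"
        print(line)


if __name__ == "__main__":
    main()
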