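"""Localization-accuracy evaluation over five simulated 512-μm blocks.

Automatic detections are simulated by degrading the ground-truth centers
with the eval_paper preset (12.64% misses, 5.85% false detections per kept
cell, 1-μm jitter) and scored against the truth with the co-detection
definitions: recall = co-detected / manual, precision = co-detected /
automatic, matched one-to-one within 10 μm. Writes the per-block table and
prints the aggregate mean ± SEM.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cytomap3d import synthgen as sg
from cytomap3d.evalmap import per_block_report

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = sg.DEFAULT_SEED


def main():
    fx = sg.make_fixture("eval_blocks", SEED)
    blocks = []
    for b in range(sg.EVAL_N_BLOCKS):
        truth = [c.center for c in fx.cells if c.block == b]
        auto = sg.degrade_detections(truth, "eval_paper", seed=1000 + b,
                                     domain_um=fx.block_domain_um)
        blocks.append((auto, truth))
    rep = per_block_report(blocks, max_dist_um=10.0)
    rows = [vars(bm) for bm in rep.blocks]
    pd.DataFrame(rows).to_csv(OUT / "localization_accuracy.csv", index=False)
    print(rep.summary())


if __name__ == "__main__":
    main()
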