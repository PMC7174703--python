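"""Betz-cell soma shape classes: morphometry and nearest-archetype typing.

On the betz_shapes fixture (93 pyramidal / 45 spindle / 118 flat / 30
spheroid somata), computes the three shape ratios (external rectangle axial
ratio, max-section distance ratio, max-section axial ratio) from the
ground-truth masks and assigns each soma to the nearest shape archetype.
Additionally segments the spindle and spheroid subpopulations to report
their mean soma volumes against the generating means (5223.36 and
1369.57 μm³). Writes the per-cell shape table under results/.
"""

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from cytomap3d import synthgen as sg
from cytomap3d.classify import CellRecord, classify_shape
from cytomap3d.morpho import masks_from_labels, shape_features
from cytomap3d.pipeline import extract_records

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = sg.DEFAULT_SEED


def main():
    fx = sg.make_fixture("betz_shapes", SEED)

    # shape typing on ground-truth masks
    masks = masks_from_labels(fx.labels, [c.id for c in fx.cells])
    recs = [CellRecord(cell_id=cid, ratios=shape_features(m))
            for cid, m in masks.items()]
    recs = classify_shape(recs)
    truth = {c.id: ("flat" if c.shape_class.startswith("flat") else c.shape_class)
             for c in fx.cells}
    rows = [{
        "cell_id": r.cell_id, "true_class": truth[r.cell_id],
        "assigned_class": r.shape_class,
        "rect_axial_ratio": r.ratios.rect_axial_ratio,
        "maxsec_distance_ratio": r.ratios.maxsec_distance_ratio,
        "maxsec_axial_ratio": r.ratios.maxsec_axial_ratio,
    } for r in recs]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "betz_shape_classes.csv", index=False)
    print("assigned counts:", dict(Counter(df.assigned_class)))
    print("misassigned:", int((df.true_class != df.assigned_class).sum()))

    # volume recovery for the two size-extreme classes
    sel = [c for c in fx.cells if c.population in ("betz_spindle", "betz_spheroid")]
    records, _ = extract_records(fx.grid, [c.center for c in sel],
                                 [c.id for c in sel], with_shape=False)
    pop = {c.id: c.population for c in sel}
    for name, target in (("betz_spindle", 5223.36), ("betz_spheroid", 1369.57)):
        v = np.array([r.features.volume for r in records if pop[r.cell_id] == name])
        print(f"{name}: mean segmented volume {v.mean():.1f} μm³ "
              f"(population mean {target}, {100 * (v.mean() / target - 1):+.1f}%)")


if __name__ == "__main__":
    main()
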