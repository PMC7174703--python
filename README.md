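# cytomap3d

Desk-scale analysis pipeline for mapping **giant pyramidal neurons (Betz
cells)** in whole-brain Nissl volumes: synthetic bright-field volume
generation with exact ground truth, chunked block storage, 3D soma
localization and volumetric segmentation, morphometric feature extraction,
K-means cell typing, soma-shape classification, localization-accuracy
evaluation, and brain-wide distribution export (SWC point clouds, coarse
density grids).

## The scientific problem

Block-face imaging of an en-bloc Nissl-stained brain produces a terabyte-
scale 8-bit volume (voxels of 0.33 μm × 0.33 μm × 1 μm) in which stained
somata appear dark on a bright background. Mapping a rare, unusually large
cell type — the layer-Vb giant pyramidal neuron of motor cortex — requires
a chain of operations: the volume is split into fixed-size blocks (512 μm
per side) for random access; candidate somata are localized; a 128-μm cube
around each center is cropped and the soma segmented volumetrically; each
cell is reduced to three typing features (soma volume *V*, mean gray value
*ḡ*, longest radius *r*<sub>max</sub>) and three shape ratios; k = 2
K-means on the z-scored typing features separates giant from other
pyramidal neurons; giant somata are assigned to one of four shape classes
(pyramidal, spindle, flat, spheroid) by nearest archetype in shape-ratio
space; and localization accuracy is scored by

&nbsp;&nbsp;recall = |co-detected| / |manual|,&nbsp;&nbsp;
precision = |co-detected| / |automatic|,

with co-detection established by one-to-one matching within 10 μm.

Because no raw whole-brain volume is publicly deposited, the package is
driven by its own synthetic-volume generator (`cytomap3d.synthgen`): cell
populations with published volume statistics (means with SDs recovered from
SEMs as SD = SEM·√n), sampled from moment-matched lognormals, placed as a
hard-core point process, rendered as implicit 3D shapes with additive noise
and a low-frequency illumination gain. Every downstream stage is therefore
testable against exact ground truth.

## Worked example

```python
import numpy as np
from cytomap3d import make_fixture, classify_giant
from cytomap3d.pipeline import extract_records

fx = make_fixture("fig4_mixture", seed=17)      # 631 cells, exact truth
records, failures = extract_records(
    fx.grid, [c.center for c in fx.cells], [c.id for c in fx.cells],
    with_shape=False,
)
records = classify_giant(records, seed=17)
giant = [r for r in records if r.class_label == "giant"]
print(len(giant), np.mean([r.features.volume for r in giant]))
```

prints

```
286 2991.2
```

— the K-means giant cluster contains exactly the 286 generated giant cells,
and their mean segmented soma volume is 2991.2 μm³ against a generating
population mean of 3101.31 μm³ (−3.6%, the cost of morphological cleanup of
dendrite stubs). The same run for the other-cell population gives
1003.5 μm³ vs 1004.32 μm³.

The numbered drivers under `analysis/` run the full analyses and write
their tables to `results/`:

```bash
python analysis/01_simulate_fixtures.py      # fixtures + population summary
python analysis/02_localization_accuracy.py  # recall 87.50 ± 1.48 %, precision 94.49 ± 0.07 %
python analysis/03_cell_typing.py            # 286-cell giant cluster, volume means
python analysis/04_shape_classes.py          # 93/45/118/30 shape classes, 0 misassigned
```

A CLI mirrors the stages (`cytomap3d simulate | blockify | detect |
features | classify | evaluate | export-swc | density | reslice | mip |
run`).

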