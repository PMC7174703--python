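"""Generator tests: sampling, placement, rendering, fixtures, degradation."""

import numpy as np
import pytest
from scipy import stats

from cytomap3d import synthgen as sg


class TestSamplePopulation:
    def test_empty(self):
        assert sg.sample_population("other_pyn", 0, seed=1) == []

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            sg.sample_population("other_pyn", -1, seed=1)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            sg.sample_population("purkinje", 5, seed=1)

    def test_deterministic(self):
        a = sg.sample_population("giant_pyn", 25, seed=9)
        b = sg.sample_population("giant_pyn", 25, seed=9)
        assert [c.target_volume for c in a] == [c.target_volume for c in b]
        assert all(np.allclose(x.orientation, y.orientation) for x, y in zip(a, b))

    @pytest.mark.parametrize("preset", list(sg.PRESETS))
    def test_monte_carlo_mean_matches_preset(self, preset):
        # oracle: the moment-matched (truncated) lognormal retains the
        # population mean; 10^4 draws pin the sample mean to ~1% (2% asserted)
        cells = sg.sample_population(preset, 10_000, seed=7)
        v = np.array([c.target_volume for c in cells])
        target = sg.PRESETS[preset].volume_mean
        assert abs(v.mean() - target) / target < 0.02

    def test_truncation_bounds_respected(self):
        from dataclasses import replace
        p = replace(sg.PRESETS["giant_pyn"], truncation_bounds=(1800.0, 9000.0))
        v = np.array([c.target_volume
                      for c in sg.sample_population(p, 5000, seed=3)])
        assert v.min() >= 1800.0 and v.max() <= 9000.0
        # mean retained after truncation (numeric recalibration)
        assert abs(v.mean() - p.volume_mean) / p.volume_mean < 0.02


class TestPlaceCells:
    def test_single_cell_inside_margin(self):
        cells = sg.sample_population("giant_pyn", 1, seed=2)
        placed = sg.place_cells(cells, (100.0, 100.0, 100.0), min_sep=5.0, seed=1)
        c = placed[0]
        r = c.bounding_radius
        assert all(r <= x <= 100.0 - r for x in c.center)

    def test_pairwise_separation(self):
        cells = sg.sample_population("other_pyn", 50, seed=2)
        placed = sg.place_cells(cells, (300.0, 300.0, 300.0), min_sep=15.0, seed=1)
        pts = np.array([c.center for c in placed])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d[np.diag_indices(len(pts))] = np.inf
        assert d.min() >= 15.0

    def test_infeasible_packing_raises(self):
        cells = sg.sample_population("other_pyn", 10_000, seed=2)
        with pytest.raises(sg.PlacementError):
            sg.place_cells(cells, (100.0, 100.0, 100.0), min_sep=20.0, seed=1,
                           max_attempts=300)

    def test_order_preserved(self):
        cells = sg.sample_population("giant_pyn", 10, seed=2)
        placed = sg.place_cells(cells, (300.0, 300.0, 300.0), min_sep=10.0, seed=1)
        assert [c.id for c in placed] == [c.id for c in cells]


class TestRenderScene:
    def test_single_spheroid_volume(self):
        # 4/3 π 10³ = 4188.79 μm³
        c = sg.CellTruth(id=1, population="t", class_label="giant",
                         shape_class="spheroid", target_volume=4188.79,
                         gray_level=80.0)
        c = sg.replace_center(c, np.array([40.0, 40.0, 40.0]))
        cfg = sg.RenderConfig(noise_sd=0.0, illumination_amplitude=0.0,
                              dendrite_stub_prob=0.0)
        _, labels = sg.render_scene([c], cfg, (80.0, 80.0, 80.0), seed=0)
        vol = (labels.data == 1).sum() * labels.voxel_volume_um3()
        assert abs(vol - 4188.79) / 4188.79 < 0.05

    def test_empty_scene(self):
        cfg = sg.RenderConfig(noise_sd=2.0, illumination_amplitude=0.0)
        grid, labels = sg.render_scene([], cfg, (40.0, 40.0, 40.0), seed=0)
        assert not labels.data.any()
        assert abs(float(grid.data.mean()) - cfg.background_mean) < 2.0

    def test_two_cells_disjoint_labels(self):
        cells = sg.sample_population("giant_pyn", 2, seed=5)
        cells = sg.place_cells(cells, (120.0, 120.0, 120.0), min_sep=20.0, seed=6)
        cfg = sg.RenderConfig(noise_sd=0.0, dendrite_stub_prob=0.0)
        grid, labels = sg.render_scene(cells, cfg, (120.0, 120.0, 120.0), seed=0)
        ids = set(np.unique(labels.data)) - {0}
        assert ids == {1, 2}
        # oracle: the two supports are disjoint connected components
        from scipy import ndimage
        lab, n = ndimage.label(labels.data > 0)
        assert n == 2

    def test_cell_gray_differs_from_background(self):
        cells = sg.sample_population("giant_pyn", 1, seed=5)
        cells = sg.place_cells(cells, (80.0, 80.0, 80.0), min_sep=5.0, seed=6)
        cfg = sg.RenderConfig(noise_sd=0.0, illumination_amplitude=0.0,
                              dendrite_stub_prob=0.0)
        grid, labels = sg.render_scene(cells, cfg, (80.0, 80.0, 80.0), seed=0)
        inside = grid.data[labels.data == 1].mean()
        outside = grid.data[labels.data == 0].mean()
        assert inside < outside - 50  # dark_cells polarity

    def test_geometry_shared(self):
        cells = sg.sample_population("other_pyn", 3, seed=1)
        cells = sg.place_cells(cells, (90.0, 90.0, 90.0), min_sep=10.0, seed=2)
        grid, labels = sg.render_scene(cells, sg.RenderConfig(), (90.0, 90.0, 90.0), seed=3)
        assert grid.same_geometry(labels)

    def test_volume_calibration_over_population(self):
        # mean labeled volume within 3% of the preset mean (1-μm voxels)
        cells = sg.sample_population("betz_spheroid", 40, seed=11)
        cells = sg.place_cells(cells, (200.0, 200.0, 200.0), min_sep=12.0, seed=12)
        cfg = sg.RenderConfig(noise_sd=0.0, dendrite_stub_prob=0.0)
        _, labels = sg.render_scene(cells, cfg, (200.0, 200.0, 200.0), seed=0)
        ids, counts = np.unique(labels.data[labels.data > 0], return_counts=True)
        target = {c.id: c.target_volume for c in cells}
        sampled = np.array([target[i] for i in ids])
        assert abs(counts.mean() - sampled.mean()) / sampled.mean() < 0.03


class TestFixtures:
    def test_fig4_counts(self, fig4):
        assert len(fig4.cells) == 631
        assert sum(c.class_label == "giant" for c in fig4.cells) == 286

    def test_betz_counts(self, betz):
        from collections import Counter
        pops = Counter(c.population for c in betz.cells)
        assert pops == {"betz_pyramidal": 93, "betz_spindle": 45,
                        "betz_flat": 118, "betz_spheroid": 30}
        flats = Counter(c.shape_class for c in betz.cells if c.population == "betz_flat")
        assert flats == {"flat_oval": 59, "flat_triangular": 59}

    def test_eval_blocks_structure(self):
        fx = sg.make_fixture("eval_blocks", 17)
        blocks = {b: [c for c in fx.cells if c.block == b] for b in range(5)}
        assert len(blocks) == 5
        assert all(len(v) == sg.EVAL_BLOCK_CELLS for v in blocks.values())

    def test_fixture_determinism(self):
        a = sg.make_fixture("eval_blocks", 23)
        b = sg.make_fixture("eval_blocks", 23)
        assert [c.center for c in a.cells] == [c.center for c in b.cells]

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            sg.make_fixture("fig9", 1)

    def test_fig4_hard_core_property(self, fig4):
        pts = np.array([c.center for c in fig4.cells])
        radii = np.array([c.bounding_radius for c in fig4.cells])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        need = np.maximum(12.0, radii[:, None] + radii[None] + 1.0)
        np.fill_diagonal(d, np.inf)
        assert np.all(d >= need - 1e-9)

    def test_fig4_disjoint_feature_supports(self, fig4):
        gv = [c.target_volume for c in fig4.cells if c.class_label == "giant"]
        ov = [c.target_volume for c in fig4.cells if c.class_label == "other"]
        assert min(gv) >= 1800.0 and max(ov) <= 1700.0
        gg = [c.gray_level for c in fig4.cells if c.class_label == "giant"]
        og = [c.gray_level for c in fig4.cells if c.class_label == "other"]
        assert max(gg) < min(og)


class TestDegradeDetections:
    def _centers(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(20, 480, size=(n, 3))

    def test_identity_preset(self):
        preset = sg.DegradationPreset("id", miss_prob=0.0, false_rate=0.0, jitter_sd=0.0)
        truth = self._centers(30)
        dets = sg.degrade_detections(truth, preset, seed=1, domain_um=(500,) * 3)
        assert np.allclose(np.array([d.center for d in dets]), truth)

    def test_total_miss(self):
        preset = sg.DegradationPreset("gone", miss_prob=1.0, false_rate=0.0, jitter_sd=0.0)
        assert sg.degrade_detections(self._centers(30), preset, seed=1) == []

    def test_kept_fraction_binomial(self):
        # binomial oracle: kept count within 3 SDs of n(1 - miss_prob)
        truth = self._centers(1000, seed=2)
        dets = sg.degrade_detections(truth, "eval_paper", seed=5, domain_um=(500,) * 3)
        p = 1.0 - sg.DEGRADATIONS["eval_paper"].miss_prob
        n_kept_expected = 1000 * p
        sd = np.sqrt(1000 * p * (1 - p))
        # kept = matched against truth within a generous radius (jitter SD 1 μm)
        from cytomap3d.evalmap import match_detections
        kept = len(match_detections(dets, truth, max_dist_um=6.0))
        assert abs(kept - n_kept_expected) <= 3 * sd
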