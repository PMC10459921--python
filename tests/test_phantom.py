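import numpy as np
import pytest

from fpmdetect.phantom import (
    Cell,
    GenerationError,
    PhantomConfig,
    generate_scene,
    make_resolution_target,
    render_highres,
    render_rgb,
    resolution_target_bar_centers,
    scene_to_annotations,
)


def cells_intersect(a, b):
    return np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]) < a.radius + b.radius


class TestGenerateScene:
    def test_empty_scene(self):
        scene = generate_scene(PhantomConfig(n_wbc=0, n_rbc=0), seed=0)
        assert scene.cells == []

    def test_wbc_count_conserved(self):
        cfg = PhantomConfig(field_of_view=120.0, n_wbc=5, n_rbc=30)
        scene = generate_scene(cfg, seed=1)
        assert len(scene.wbc) == 5
        assert len(scene.rbc) == 30

    def test_seed_determinism(self):
        cfg = PhantomConfig(field_of_view=100.0, n_wbc=3, n_rbc=20)
        s1 = generate_scene(cfg, seed=11)
        s2 = generate_scene(cfg, seed=11)
        assert s1.cells == s2.cells

    def test_contact_fraction_tracks_overlap_prob(self):
        cfg = PhantomConfig(field_of_view=400.0, n_wbc=0, n_rbc=200, overlap_prob=0.3)
        fractions = []
        for seed in range(20):
            scene = generate_scene(cfg, seed=seed)
            touching = sum(
                any(cells_intersect(c, o) for o in scene.cells if o is not c)
                for c in scene.cells
            )
            fractions.append(touching / len(scene.cells))
        assert abs(np.mean(fractions) - 0.3) <= 0.1

    def test_zero_overlap_prob_gives_isolated_cells(self):
        cfg = PhantomConfig(field_of_view=200.0, n_wbc=2, n_rbc=40, overlap_prob=0.0)
        scene = generate_scene(cfg, seed=2)
        for c in scene.cells:
            assert not any(cells_intersect(c, o) for o in scene.cells if o is not c)

    def test_infeasible_density_reported(self):
        cfg = PhantomConfig(field_of_view=20.0, n_wbc=0, n_rbc=100, overlap_prob=0.0)
        with pytest.raises(GenerationError):
            generate_scene(cfg, seed=0)

    def test_class_imbalance_default(self):
        cfg = PhantomConfig()  # defaults: 1 wbc per rbc_per_wbc rbc
        scene = generate_scene(cfg, seed=4)
        ratio = len(scene.rbc) / max(len(scene.wbc), 1)
        assert 600 <= ratio <= 1000

    def test_wbc_larger_than_typical_rbc(self):
        cfg = PhantomConfig(field_of_view=150.0, n_wbc=4, n_rbc=30)
        scene = generate_scene(cfg, seed=5)
        assert min(c.radius for c in scene.wbc) > np.mean([c.radius for c in scene.rbc])


class TestRenderHighres:
    def test_empty_scene_uniform(self):
        from fpmdetect.phantom import PhantomScene

        scene = PhantomScene(field_of_view=50.0, cells=[], seed=0, background_absorption=0.05)
        field = render_highres(scene, 64, "green")
        np.testing.assert_allclose(np.abs(field.values), 0.95, atol=1e-12)
        np.testing.assert_allclose(np.angle(field.values), 0.0, atol=1e-12)

    def test_single_centered_cell_symmetric_dip(self):
        from fpmdetect.phantom import PhantomScene

        cell = Cell(kind="rbc", center=(25.0, 25.0), radius=4.0, absorption=0.3, phase_delay=0.5)
        scene = PhantomScene(field_of_view=50.0, cells=[cell], seed=0)
        amp = np.abs(render_highres(scene, 100, "green").values)
        minima = np.argwhere(amp <= amp.min() + 1e-12)
        com = minima.mean(axis=0)  # flat disk bottom: use centroid of minima
        assert abs(com[0] - 49.5) <= 1 and abs(com[1] - 49.5) <= 1
        np.testing.assert_allclose(amp, amp.T, atol=1e-10)  # radial symmetry

    def test_amplitude_in_unit_interval(self):
        for seed in range(5):
            cfg = PhantomConfig(field_of_view=100.0, n_wbc=3, n_rbc=25, overlap_prob=0.4)
            scene = generate_scene(cfg, seed=seed)
            for ch in ("red", "green", "blue", None):
                amp = np.abs(render_highres(scene, 128, ch).values)
                assert amp.min() >= 0.0 and amp.max() <= 1.0

    def test_nucleus_darker_than_cytoplasm(self):
        from fpmdetect.phantom import PhantomScene

        cell = Cell(kind="wbc", center=(25.0, 25.0), radius=6.0, absorption=0.2,
                    phase_delay=0.8, nucleus_fraction=0.5)
        scene = PhantomScene(field_of_view=50.0, cells=[cell], seed=0)
        amp = np.abs(render_highres(scene, 128, "green").values)
        nucleus_amp = amp[64, 64]
        rim = amp[64, 64 + int(5.0 / 50.0 * 128)]  # cytoplasm ring at ~5 µm
        assert nucleus_amp < rim

    def test_render_deterministic(self):
        cfg = PhantomConfig(field_of_view=80.0, n_wbc=2, n_rbc=10)
        f1 = render_highres(generate_scene(cfg, 9), 64, "red")
        f2 = render_highres(generate_scene(cfg, 9), 64, "red")
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_odd_side_rejected(self, small_scene):
        with pytest.raises(ValueError):
            render_highres(small_scene, 63, "green")

    def test_render_rgb_shape_range(self, small_scene):
        img = render_rgb(small_scene, 64)
        assert img.shape == (64, 64, 3)
        assert img.min() >= 0 and img.max() <= 1


class TestSceneToAnnotations:
    def test_centered_wbc_box_geometry(self):
        from fpmdetect.phantom import PhantomScene

        cell = Cell(kind="wbc", center=(25.0, 25.0), radius=5.0, absorption=0.2,
                    phase_delay=0.8, nucleus_fraction=0.5)
        scene = PhantomScene(field_of_view=50.0, cells=[cell], seed=0)
        aset = scene_to_annotations(scene, 100)
        assert len(aset.annotations) == 1
        box = aset.annotations[0].box
        assert box.cx == pytest.approx(0.5)
        assert box.cy == pytest.approx(0.5)
        assert box.w == pytest.approx(2 * 5.0 / 50.0)

    def test_half_outside_clipped(self):
        from fpmdetect.phantom import PhantomScene

        cell = Cell(kind="wbc", center=(0.0, 25.0), radius=5.0, absorption=0.2,
                    phase_delay=0.8, nucleus_fraction=0.5)
        scene = PhantomScene(field_of_view=50.0, cells=[cell], seed=0)
        box = scene_to_annotations(scene, 100).annotations[0].box
        assert box.w == pytest.approx(5.0 / 50.0)  # half clipped
        assert box.w * box.h < (10.0 / 50.0) ** 2

    def test_rbc_produce_no_boxes(self):
        cfg = PhantomConfig(field_of_view=100.0, n_wbc=0, n_rbc=30)
        scene = generate_scene(cfg, seed=3)
        assert scene_to_annotations(scene, 128).annotations == []

    def test_box_count_over_random_scenes(self):
        count_ok = 0
        for seed in range(100):
            cfg = PhantomConfig(field_of_view=150.0, n_wbc=3, n_rbc=10, overlap_prob=0.1)
            scene = generate_scene(cfg, seed=seed)
            aset = scene_to_annotations(scene, 128)
            inside = [
                c for c in scene.wbc
                if 0 <= c.center[0] <= 150 and 0 <= c.center[1] <= 150
            ]
            assert len(aset.annotations) == len(inside)
            count_ok += 1
        assert count_ok == 100

    def test_box_contains_cell_absorption_minimum(self):
        for seed in range(10):
            cfg = PhantomConfig(field_of_view=100.0, n_wbc=2, n_rbc=0)
            scene = generate_scene(cfg, seed=seed)
            amp = np.abs(render_highres(scene, 128, "green").values)
            for ann, cell in zip(scene_to_annotations(scene, 128).annotations, scene.wbc):
                x0, y0, x1, y1 = ann.box.corners
                sl = amp[int(y0 * 128) : int(np.ceil(y1 * 128)),
                         int(x0 * 128) : int(np.ceil(x1 * 128))]
                assert sl.min() <= amp.min() + 1e-9 or sl.min() < np.median(amp)


class TestResolutionTarget:
    def test_bar_pixel_separation(self):
        field = make_resolution_target(256, [10.0], pixel_pitch=0.5)
        (xl, xr, y) = resolution_target_bar_centers(256, 0.5, [10.0])[0]
        assert (xr - xl) / 0.5 == pytest.approx(20.0)

    def test_binary_amplitude(self):
        field = make_resolution_target(128, [5.0], pixel_pitch=0.5)
        values = np.unique(np.abs(field.values))
        assert set(np.round(values, 6)) <= {0.2, 1.0}

    def test_bars_recoverable_by_peak_finding(self):
        sep = 8.0
        field = make_resolution_target(256, [sep], pixel_pitch=0.5)
        (xl, xr, y) = resolution_target_bar_centers(256, 0.5, [sep])[0]
        row = np.abs(field.values)[int(y / 0.5)]
        dark = np.nonzero(row < 0.5)[0] * 0.5
        mid = (xl + xr) / 2
        left = dark[dark < mid]
        right = dark[dark >= mid]
        assert abs(left.mean() - xl) < 1.0
        assert abs(right.mean() - xr) < 1.0

    def test_separation_below_pitch_rejected(self):
        with pytest.raises(ValueError):
            make_resolution_target(128, [0.3], pixel_pitch=0.5)


class TestCellValidation:
    def test_bad_kind(self):
        with pytest.raises(ValueError):
            Cell(kind="platelet", center=(0, 0), radius=1.0, absorption=0.1, phase_delay=0.1)

    def test_wbc_needs_nucleus(self):
        with pytest.raises(ValueError):
            Cell(kind="wbc", center=(0, 0), radius=5.0, absorption=0.1,
                 phase_delay=0.1, nucleus_fraction=0.0)
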