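"""Patch cutting, painted-pixel rates and the 21-level class binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swardcover as sc
from swardcover.patches import PatchWindow, label_window


class TestBinClass:
    @pytest.mark.parametrize(
        "rp,expected",
        [
            (0.0, 0),
            (1.0, 100),
            (0.475, 50),   # closed boundary of the 50 row
            (0.125, 10),   # 2.5 rounds half-to-even down
            (0.175, 20),   # 3.5 rounds half-to-even up
            (0.5, 50),
        ],
    )
    def test_boundary_values(self, rp, expected):
        assert sc.bin_class(rp) == expected

    def test_matches_interval_table_on_fine_grid(self):
        # closed form vs. the explicit 21-row interval lookup
        for k in range(0, 1001):
            rp = k / 1000
            assert sc.bin_class(rp) == sc.bin_class_interval(rp), rp

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(derandomize=True, max_examples=300)
    def test_monotone_and_in_range(self, rp):
        v = sc.bin_class(rp)
        assert v in sc.CLASS_VALUES
        eps = 1e-9
        if rp + eps <= 1.0:
            assert sc.bin_class(rp + eps) >= v

    def test_surjective_onto_class_values(self):
        hits = {sc.bin_class(k / 20) for k in range(21)}
        assert hits == set(sc.CLASS_VALUES)

    @pytest.mark.parametrize("rp", [-0.01, 1.01])
    def test_out_of_range_rejected(self, rp):
        with pytest.raises(ValueError):
            sc.bin_class(rp)
        with pytest.raises(ValueError):
            sc.bin_class_interval(rp)


class TestPatchRp:
    def test_all_and_half_painted(self):
        m = np.ones((64, 64), np.uint8)
        assert sc.patch_rp(m, PatchWindow("p", 0, 0)) == 1.0
        m[:, 32:] = 0  # 2048 of 4096 pixels
        assert sc.patch_rp(m, PatchWindow("p", 0, 0)) == 0.5

    def test_random_window_matches_loop_oracle(self, small_plot):
        rng = np.random.default_rng(3)
        m = small_plot.maps["WC"]
        for _ in range(5):
            x0, y0 = int(rng.integers(0, 448)), int(rng.integers(0, 448))
            win = PatchWindow("small", x0, y0)
            loop = sum(
                1
                for dy in range(64)
                for dx in range(64)
                if m[y0 + dy, x0 + dx]
            ) / 4096
            assert sc.patch_rp(m, win) == pytest.approx(loop, abs=0)

    def test_out_of_bounds_window(self):
        m = np.zeros((64, 64), np.uint8)
        with pytest.raises(ValueError):
            sc.patch_rp(m, PatchWindow("p", 1, 0))


class TestTrainingSampling:
    def test_count_and_strip_exclusion(self, small_plot):
        patches = sc.sample_training_patches(small_plot, n=300, seed=0)
        assert len(patches) == 300
        w = small_plot.shape[1]
        for p in patches:
            assert p.window.x0 + p.window.side <= w - sc.VALIDATION_STRIP
            assert p.window.y0 + p.window.side <= small_plot.shape[0]

    def test_deterministic_for_fixed_seed(self, small_plot):
        (a,) = sc.sample_training_patches(small_plot, n=1, seed=123)
        (b,) = sc.sample_training_patches(small_plot, n=1, seed=123)
        assert a.window == b.window and a.rp == b.rp

    def test_mean_rp_approaches_region_coverage(self, small_plot):
        # Monte-Carlo mean of rp vs. exact coverage of the sampling-eligible
        # region (all pixels left of the strip reachable by some window)
        patches = sc.sample_training_patches(small_plot, n=4000, seed=7)
        mean_rp = float(np.mean([p.rp["WC"] for p in patches]))
        region = small_plot.maps["WC"][:, : small_plot.shape[1] - sc.VALIDATION_STRIP]
        assert abs(mean_rp - region.mean()) <= 0.03

    def test_region_too_small(self):
        rec = sc.PlotRecord(
            plot_id="p", image=np.zeros((64, 128, 3), np.uint8),
            maps={"TY": np.zeros((64, 128), np.uint8)},
        )
        with pytest.raises(ValueError):
            sc.sample_training_patches(rec, n=1)


class TestValidationTiling:
    def test_expected_grid_counts(self):
        # 128-wide strip of a 1536-tall plot: 2 per row x 24 rows = 48 pieces
        rec = sc.PlotRecord(
            plot_id="p", image=np.zeros((1536, 512, 3), np.uint8),
            maps={"TY": np.zeros((1536, 512), np.uint8)},
        )
        pieces = sc.tile_validation_patches(rec)
        assert len(pieces) == 48

    def test_single_window_strip(self):
        rec = sc.PlotRecord(
            plot_id="p", image=np.zeros((64, 256, 3), np.uint8),
            maps={"TY": np.zeros((64, 256), np.uint8)},
        )
        assert len(sc.tile_validation_patches(rec, strip_width=64)) == 1

    def test_windows_disjoint_and_inside_strip(self, small_plot):
        pieces = sc.tile_validation_patches(small_plot)
        w = small_plot.shape[1]
        seen = set()
        for p in pieces:
            win = p.window
            assert win.x0 >= w - sc.VALIDATION_STRIP
            assert win.x0 + win.side <= w
            cells = {
                (x, y)
                for x in range(win.x0, win.x0 + win.side)
                for y in range(win.y0, win.y0 + win.side, 8)
            }
            assert not (cells & seen)
            seen |= cells

    def test_narrow_strip_rejected(self, small_plot):
        with pytest.raises(ValueError):
            sc.tile_validation_patches(small_plot, strip_width=32)

    def test_disjoint_from_training_windows(self, small_plot):
        train = sc.sample_training_patches(small_plot, n=100, seed=1)
        val = sc.tile_validation_patches(small_plot)
        max_train_x = max(p.window.x0 + p.window.side for p in train)
        min_val_x = min(p.window.x0 for p in val)
        assert max_train_x <= min_val_x


class TestEvaluationTiling:
    def test_grid_count_area_accounting(self, small_plot):
        pieces = sc.tile_evaluation_patches(small_plot)
        h, w = small_plot.shape
        assert len(pieces) == (w // 64) * (h // 64)
        covered = len(pieces) * 64 * 64
        assert covered == (w // 64) * 64 * (h // 64) * 64

    def test_single_window_image(self):
        rec = sc.PlotRecord(
            plot_id="p", image=np.zeros((64, 64, 3), np.uint8),
            maps={"TY": np.zeros((64, 64), np.uint8)},
        )
        assert len(sc.tile_evaluation_patches(rec)) == 1

    def test_too_small_image(self):
        rec = sc.PlotRecord(
            plot_id="p", image=np.zeros((63, 64, 3), np.uint8),
            maps={"TY": np.zeros((63, 64), np.uint8)},
        )
        with pytest.raises(ValueError):
            sc.tile_evaluation_patches(rec)


class TestResizePatch:
    def test_constant_patch_stays_constant(self):
        patch = np.full((64, 64, 3), 77, np.uint8)
        out = sc.resize_patch(patch)
        assert out.shape == (256, 256, 3)
        assert (out == 77).all()

    def test_checkerboard_becomes_4x4_blocks(self):
        patch = np.zeros((64, 64, 3), np.uint8)
        patch[::2, ::2] = 255
        out = sc.resize_patch(patch)
        assert np.array_equal(out[:4, :4], np.full((4, 4, 3), 255))
        assert np.array_equal(out[:4, 4:8], np.zeros((4, 4, 3)))

    def test_histogram_scales_by_16(self):
        rng = np.random.default_rng(2)
        patch = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        out = sc.resize_patch(patch)
        h_in = np.bincount(patch.reshape(-1), minlength=256)
        h_out = np.bincount(out.reshape(-1), minlength=256)
        assert np.array_equal(h_out, 16 * h_in)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            sc.resize_patch(np.zeros((64, 32, 3), np.uint8))


class TestDatasets:
    def test_label_window_consistent_with_binning(self, small_plot):
        win = PatchWindow("small", 10, 20)
        patch = label_window(small_plot, win)
        for cat in small_plot.categories:
            assert patch.class_value[cat] == sc.bin_class(patch.rp[cat])
            assert patch.class_value[cat] == sc.bin_class_interval(patch.rp[cat])

    def test_group_dataset_concatenates_with_provenance(self, study_by_id):
        plots = [study_by_id[f"plot {r}-1"] for r in (1, 2, 3)]
        train, val = sc.build_training_dataset(plots, n_per_plot=50, seed=0)
        assert len(train) == 150
        assert set(train.labels["plot_id"]) == {p.plot_id for p in plots}
        assert len(val) == 3 * len(sc.tile_validation_patches(plots[0]))

    def test_dataset_roundtrip(self, small_plot, tmp_path):
        train, _ = sc.build_training_dataset([small_plot], n_per_plot=20, seed=1)
        path = sc.save_dataset(train, tmp_path)
        import pandas as pd

        labels = pd.read_csv(path)
        assert len(labels) == 20
        assert (labels["class_WC"] == train.labels["class_WC"]).all()
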