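import numpy as np
import pytest

import circawave as cw
from circawave import phasemap


@pytest.fixture(scope="module")
def gradient_grid(noiseless_movie):
    _, movie, truth = noiseless_movie
    mask = cw.mask_scn(movie)
    return movie, truth, mask, cw.grid_rois(movie, mask, 8)


class TestMaskScn:
    def test_uniform_full_frame_all_in_mask(self):
        p = cw.MovieParams(height=16, width=16, n_cycles=3, mask_shape="full-frame",
                           phase_gradient_span=0.0, noise_model="none")
        movie, _ = cw.make_movie(p)
        assert cw.mask_scn(movie, 0.5).all()

    def test_bilateral_mask_recovered_on_dark_background(self, noiseless_movie):
        _, movie, truth = noiseless_movie
        assert np.array_equal(cw.mask_scn(movie), truth.mask)

    def test_bright_background_excluded(self):
        p = cw.MovieParams(height=32, width=32, n_cycles=3, amplitude=800.0,
                           baseline=800.0, background=80.0, noise_model="none")
        movie, truth = cw.make_movie(p)
        mask = cw.mask_scn(movie, threshold=0.5)
        assert not np.any(mask & ~truth.mask)

    def test_zero_movie_raises(self):
        movie = cw.MovieStack(np.zeros((5, 8, 8)), 0.5)
        with pytest.raises(cw.DegenerateInputError):
            cw.mask_scn(movie)


class TestGridRois:
    def test_single_cell_is_whole_field_mean(self, uniform_movie):
        _, movie, truth = uniform_movie
        grid = cw.grid_rois(movie, np.ones(movie.shape[1:], bool),
                            cell_size=movie.shape[1])
        assert grid.has_trace.sum() == 1
        assert np.allclose(grid.mean_trace().values,
                           movie.mean_trace().values)

    def test_uniform_movie_identical_traces(self):
        p = cw.MovieParams(height=16, width=16, n_cycles=3, mask_shape="full-frame",
                           phase_gradient_span=0.0, noise_model="none")
        movie, truth = cw.make_movie(p)
        grid = cw.grid_rois(movie, truth.mask, 4)
        traces = grid.traces[grid.has_trace]
        assert np.allclose(traces, traces[0])

    def test_half_covered_cells_excluded(self):
        mask = np.zeros((8, 8), bool)
        mask[:, :3] = True            # left cell 37.5% covered
        movie = cw.MovieStack(np.ones((4, 8, 8)), 0.5)
        grid = cw.grid_rois(movie, mask, 8)
        assert grid.has_trace.sum() == 0

    def test_oversized_cell_rejected(self, uniform_movie):
        _, movie, truth = uniform_movie
        with pytest.raises(cw.ParameterError):
            cw.grid_rois(movie, truth.mask, 1000)


class TestComputePhaseMap:
    def test_coincident_peak_is_ct12_and_offset_is_ct11(self):
        # three ROIs: aligned with the reference, 1 h earlier, 2 h later
        t = np.arange(0, 120, 0.5)
        frames = np.zeros((t.size, 2, 2))
        for (r, c), lag in {(0, 0): 0.0, (0, 1): -1.0, (1, 0): 2.0, (1, 1): 0.0}.items():
            frames[:, r, c] = 100 + 50 * np.cos(2 * np.pi * (t - lag) / 24.0)
        movie = cw.MovieStack(frames, 0.5)
        grid = cw.grid_rois(movie, np.ones((2, 2), bool), 1)
        reference = cw.TimeSeries(0, 0.5, 100 + 50 * np.cos(2 * np.pi * t / 24.0))
        pm = cw.compute_phase_map(grid, reference)
        assert pm.mean_phase[0, 0] == pytest.approx(12.0, abs=0.05)
        assert pm.mean_phase[0, 1] == pytest.approx(11.0, abs=0.05)
        assert pm.mean_phase[1, 0] == pytest.approx(14.0, abs=0.05)

    def test_gradient_recovery_rms(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        pm = cw.compute_phase_map(grid)
        cs = grid.cell_size
        errs = []
        for i, j in zip(*np.nonzero(pm.phased())):
            cell = truth.phase_ct[i * cs:(i + 1) * cs, j * cs:(j + 1) * cs]
            d = (pm.mean_phase[i, j] - np.nanmean(cell) + 12) % 24 - 12
            errs.append(d)
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms < 0.25
        assert pm.ensemble_period == pytest.approx(24.0, abs=0.1)

    def test_affine_intensity_invariance(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        pm1 = cw.compute_phase_map(grid)
        scaled = cw.MovieStack(3.0 * movie.frames + 250.0, movie.frame_interval)
        pm2 = cw.compute_phase_map(cw.grid_rois(scaled, mask, 8))
        a, b = pm1.mean_phase, pm2.mean_phase
        ok = np.isfinite(a) & np.isfinite(b)
        diff = (a[ok] - b[ok] + 12) % 24 - 12
        assert np.max(np.abs(diff)) < 1e-6

    def test_external_reference_matches_grid_mean(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        pm1 = cw.compute_phase_map(grid)
        pm2 = cw.compute_phase_map(grid, grid.mean_trace())
        assert np.allclose(pm1.mean_phase, pm2.mean_phase, equal_nan=True)


class TestClassifyPhaseClusters:
    def _pm(self, phases):
        arr = np.asarray(phases, float)[None, :]
        return phasemap.PhaseMap(arr[None], arr, 24.0, np.array([12.0]),
                                 np.array([24.0]))

    def test_single_category(self):
        cm = cw.classify_phase_clusters(self._pm([12.5, 12.5, 12.5]))
        labels = cm.labels[cm.labels >= 0]
        assert set(labels) == {3}
        assert cm.categories[3] == "CT12-13"

    def test_edge_categories(self):
        cm = cw.classify_phase_clusters(self._pm([9.5, 10.5, 14.5]))
        names = [cm.categories[k] for k in cm.labels[0]]
        assert names == ["<CT10", "CT10-11", ">CT14"]

    def test_gradient_movie_gives_ordered_bands(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        pm = cw.compute_phase_map(grid)
        cm = cw.classify_phase_clusters(pm)
        # phase advances down the rows: per-row mean label must be monotone
        row_means = []
        for i in range(cm.labels.shape[0]):
            lab = cm.labels[i][cm.labels[i] >= 0]
            if lab.size:
                row_means.append(lab.mean())
        assert len(row_means) >= 3
        assert all(b >= a for a, b in zip(row_means, row_means[1:]))

    def test_deterministic_function_of_map(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        pm = cw.compute_phase_map(grid)
        c1 = cw.classify_phase_clusters(pm)
        c2 = cw.classify_phase_clusters(pm)
        assert np.array_equal(c1.labels, c2.labels)


class TestRegionOverlay:
    def test_uniform_image_labels_none_inside(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        ov = cw.region_overlay(np.ones(movie.shape[1:]), grid)
        vals = ov[np.isfinite(ov)]
        assert np.allclose(vals, 1.0)
        assert not np.any(vals > 1.0)         # strict inequality: boundary outside

    def test_left_right_split(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        img = np.zeros(movie.shape[1:])
        img[:, : movie.shape[2] // 2] = 2.0
        ov = cw.region_overlay(img, grid)
        inside = ov > 1.0
        cols = np.nonzero(grid.has_trace)[1]
        half_col = (movie.shape[2] // 2) // grid.cell_size
        for i, j in zip(*np.nonzero(grid.has_trace)):
            assert inside[i, j] == (j < half_col)

    def test_zero_image_rejected(self, gradient_grid):
        movie, truth, mask, grid = gradient_grid
        with pytest.raises(cw.DegenerateInputError):
            cw.region_overlay(np.zeros(movie.shape[1:]), grid)


class TestNormalizedChangeMap:
    def _step_movie(self, factor):
        frames = np.full((40, 8, 8), 100.0)
        frames[20:] *= factor
        return cw.MovieStack(frames, 0.5)

    def test_no_change_gives_zero(self):
        movie = self._step_movie(1.0)
        grid = cw.grid_rois(movie, np.ones((8, 8), bool), 4)
        out = cw.normalized_change_map(movie, grid, baseline_window=10.0)
        assert np.allclose(out[grid.has_trace], 0.0)

    def test_fifty_percent_step(self):
        movie = self._step_movie(1.5)
        grid = cw.grid_rois(movie, np.ones((8, 8), bool), 4)
        out = cw.normalized_change_map(movie, grid, baseline_window=10.0)
        assert np.allclose(out[grid.has_trace][:, 20:], 0.5)
        assert np.allclose(out[grid.has_trace][:, :20], 0.0)

    def test_transient_peak_location(self):
        t = np.arange(80) * 0.5
        bump = np.exp(-0.5 * ((t - 15.0) / 3.0) ** 2)
        frames = np.tile(100.0 * (1 + bump)[:, None, None], (1, 8, 8))
        movie = cw.MovieStack(frames, 0.5)
        grid = cw.grid_rois(movie, np.ones((8, 8), bool), 4)
        out = cw.normalized_change_map(movie, grid, baseline_window=5.0)
        mean_change = out[grid.has_trace].mean(axis=0)
        assert abs(t[np.argmax(mean_change)] - 15.0) <= 0.5


def test_render_phase_map(tmp_path, gradient_grid):
    movie, truth, mask, grid = gradient_grid
    pm = cw.compute_phase_map(grid)
    out = tmp_path / "pm.png"
    phasemap.render_phase_map(pm, out)
    assert out.stat().st_size > 0
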