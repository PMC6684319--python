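"""Background subtraction, Otsu segmentation, volumetry and intensities."""

import numpy as np
import pytest

import pcmkit as pk
from pcmkit.quantify import (centriole_connected_volume,
                             centrosome_and_packet_intensity, label_components,
                             per_centriole_residual, segment_pcm,
                             subtract_background, total_intensity)


def brute_otsu_threshold(stack, nbins=256):
    """Exhaustive between-class-variance scan over the 256-bin histogram."""
    counts, edges = np.histogram(stack.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_t = -1.0, centers[0]
    w = counts / counts.sum()
    for k in range(1, nbins):
        w0, w1 = w[:k].sum(), w[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (w[:k] * centers[:k]).sum() / w0
        mu1 = (w[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best:
            best, best_t = var, centers[k - 1]
    return best_t


def between_class_variance(stack, thr, nbins=256):
    """Histogram-level Otsu objective: what a 256-bin scan maximizes."""
    counts, edges = np.histogram(stack.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo = centers <= thr
    w0, w1 = counts[lo].sum(), counts[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[lo] * centers[lo]).sum() / w0
    mu1 = (counts[~lo] * centers[~lo]).sum() / w1
    return w0 / counts.sum() * w1 / counts.sum() * (mu0 - mu1) ** 2


def flood_fill_components(mask):
    """BFS flood fill with 26-connectivity: list of voxel-index sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            z, y, x = queue.pop()
            comp.add((z, y, x))
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        q = (z + dz, y + dy, x + dx)
                        if (0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx
                                and mask[q] and not seen[q]):
                            seen[q] = True
                            queue.append(q)
        comps.append(comp)
    return comps


class TestBackgroundSubtraction:
    def test_uniform_background_removed_exactly(self, small_sphere_grid):
        grid, sphere, _ = small_sphere_grid
        corrected, means = subtract_background(grid, 0, 0,
                                               rng=np.random.default_rng(0))
        assert np.allclose(means, 100.0)
        assert np.allclose(corrected[~sphere], 0.0)
        assert np.allclose(corrected[sphere], 1000.0)

    def test_estimator_mean_and_spread_match_sampling_theory(self):
        # mean of 10 Poisson(100) points: mean 100, sd ~ sqrt(100/10) = 3.16
        rng = np.random.default_rng(42)
        cal = pk.PhysicalCalibration()
        data = rng.poisson(100.0, size=(1, 1, 1, 60, 60)).astype(float)
        grid = pk.VoxelGrid(data, cal)
        none = np.zeros((1, 60, 60), dtype=bool)
        means = []
        for i in range(400):
            _, m = subtract_background(grid, 0, 0, rng=np.random.default_rng(i),
                                       exclusion_mask=none, exclusion_radius_um=0)
            means.append(m[0])
        means = np.asarray(means)
        mc = np.random.default_rng(7).poisson(100.0, size=(10_000, 10)).mean(axis=1)
        assert means.mean() == pytest.approx(100.0, abs=3 * mc.std() / 20)
        assert means.std() == pytest.approx(mc.std(), rel=0.15)

    def test_insufficient_cytoplasm_is_an_error(self, small_sphere_grid):
        grid, _, _ = small_sphere_grid
        full = np.ones(grid.shape_zyx, dtype=bool)
        full[0, 0, :5] = False
        with pytest.raises(ValueError, match="cytoplasm"):
            subtract_background(grid, 0, 0, n_points=10, exclusion_mask=full,
                                exclusion_radius_um=0.0,
                                rng=np.random.default_rng(0))


class TestSegmentation:
    def test_bimodal_stack_recovers_support_exactly(self, small_sphere_grid):
        grid, sphere, _ = small_sphere_grid
        corrected, _ = subtract_background(grid, 0, 0, rng=np.random.default_rng(0))
        mask, thr = segment_pcm(corrected, smooth_sigma_px=0.0)
        assert 0.0 < thr < 1000.0
        assert np.array_equal(mask, sphere)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_matches_brute_force_scan(self, seed):
        # overlapping classes: the histogram has no empty gap, the maximizer
        # is unique, and the thresholds must agree exactly
        rng = np.random.default_rng(seed)
        stack = np.concatenate([rng.normal(60, 30, 4000),
                                rng.normal(200, 30, 800)]).reshape(8, 20, 30)
        stack = np.clip(stack, 0, None)
        mask, thr = segment_pcm(stack)
        brute = brute_otsu_threshold(stack)
        assert thr == pytest.approx(brute, abs=1e-9)
        assert np.array_equal(mask, stack >= brute)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gapped_histogram_thresholds_are_equivalent_maximizers(self, seed):
        # well-separated classes leave empty histogram bins across which the
        # between-class variance is flat; any threshold on the plateau is an
        # equally optimal maximizer, so compare objective values
        rng = np.random.default_rng(seed)
        stack = np.concatenate([rng.normal(20, 5, 4000),
                                rng.normal(200, 20, 800)]).reshape(8, 20, 30)
        stack = np.clip(stack, 0, None)
        _, thr = segment_pcm(stack)
        brute = brute_otsu_threshold(stack)
        assert between_class_variance(stack, thr) == \
            pytest.approx(between_class_variance(stack, brute), rel=1e-12)

    def test_two_level_histogram_threshold_between_modes(self):
        stack = np.zeros(1000)
        stack[:100] = 1000.0
        mask, thr = segment_pcm(stack.reshape(10, 10, 10))
        assert 0 < thr < 1000
        assert thr == pytest.approx(brute_otsu_threshold(stack), abs=1e-9)

    def test_constant_stack_is_an_error(self):
        with pytest.raises(ValueError):
            segment_pcm(np.full((4, 5, 5), 7.0))


class TestComponents:
    def test_random_masks_match_flood_fill_oracle(self):
        cal = pk.PhysicalCalibration(dx_um=0.2, dz_um=0.4)
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = rng.random((6, 10, 10)) < 0.25
            comps = label_components(mask, cal)
            oracle = flood_fill_components(mask)
            assert comps.n_components == len(oracle)
            assert sorted(comps.voxel_counts) == sorted(len(c) for c in oracle)
            assert np.allclose(sorted(comps.volumes_um3),
                               sorted(len(c) * cal.voxel_volume_um3 for c in oracle))

    def test_digital_sphere_volume(self):
        cal = pk.PhysicalCalibration(dx_um=1.0, dz_um=1.0)
        R = 8
        z, y, x = np.mgrid[:24, :24, :24]
        mask = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= R * R
        comps = label_components(mask, cal)
        assert comps.n_components == 1
        assert comps.voxel_counts[0] == mask.sum()  # exact voxel-count oracle
        assert comps.volumes_um3[0] == pytest.approx(4 / 3 * np.pi * R**3, rel=0.05)

    def test_empty_and_separated_masks(self):
        cal = pk.PhysicalCalibration()
        assert label_components(np.zeros((4, 5, 5), bool), cal).n_components == 0
        two = np.zeros((3, 10, 10), bool)
        two[1, 2:4, 2:4] = True
        two[1, 7:9, 7:9] = True
        assert label_components(two, cal).n_components == 2


class TestConnectivity:
    def _two_spheres(self):
        cal = pk.PhysicalCalibration(dx_um=0.15, dz_um=0.5)
        mask = np.zeros((8, 40, 40), bool)
        z, y, x = np.mgrid[:8, :40, :40]
        d1 = ((z - 4) * 0.5) ** 2 + ((y - 10) * 0.15) ** 2 + ((x - 10) * 0.15) ** 2
        d2 = ((z - 4) * 0.5) ** 2 + ((y - 28) * 0.15) ** 2 + ((x - 28) * 0.15) ** 2
        mask[d1 <= 0.6 ** 2] = True
        mask[d2 <= 0.4 ** 2] = True
        return cal, mask

    def test_only_centriole_containing_component_counts(self):
        cal, mask = self._two_spheres()
        comps = label_components(mask, cal)
        vol = centriole_connected_volume(comps, [(2.0, 1.5, 1.5)])
        assert len(comps.centriole_labels) == 1
        assert vol < comps.volumes_um3.sum()
        assert vol == pytest.approx(max(comps.volumes_um3))

    def test_centriole_in_background_warns_and_returns_zero(self):
        cal, mask = self._two_spheres()
        comps = label_components(mask, cal)
        with pytest.warns(UserWarning):
            vol = centriole_connected_volume(comps, [(0.0, 0.0, 0.0)])
        assert vol == 0.0

    def test_missing_positions_rejected(self):
        cal, mask = self._two_spheres()
        comps = label_components(mask, cal)
        with pytest.raises(ValueError):
            centriole_connected_volume(comps, [])


class TestIntensities:
    def test_uniform_image_total_is_zero(self):
        grid = pk.VoxelGrid(np.full((1, 1, 16, 64, 96), 40.0),
                            pk.PhysicalCalibration())
        tot = total_intensity(grid, 0, 0, (4.0, 4.8, 4.8))
        assert tot == pytest.approx(0.0, abs=1e-6)

    def test_sphere_signal_recovered_within_one_percent(self, noiseless_movie):
        grid, truth = noiseless_movie
        t = 0
        tot = total_intensity(grid, "outer_scaffold", t, truth.center_um)
        assert tot == pytest.approx(truth.noiseless_totals["outer_scaffold"][t],
                                    rel=0.01)

    def test_box_exceeding_field_is_an_error(self, small_sphere_grid):
        grid, _, center = small_sphere_grid
        with pytest.raises(ValueError, match="box"):
            total_intensity(grid, 0, 0, center, box_xy_um=20.0)

    def test_overlapping_boxes_rejected(self, noiseless_movie):
        grid, truth = noiseless_movie
        with pytest.raises(ValueError, match="overlap"):
            total_intensity(grid, "outer_scaffold", 0, truth.center_um,
                            cyto_center_um=truth.center_um)

    def test_prerupture_packet_intensity_is_zero(self, noiseless_movie):
        grid, truth = noiseless_movie
        corrected, _ = subtract_background(grid, "outer_scaffold", 0,
                                           rng=np.random.default_rng(0))
        mask, _ = segment_pcm(corrected, smooth_sigma_px=1.0)
        comps = label_components(mask, grid.calibration, corrected)
        centriole_connected_volume(comps, truth.centriole_positions_um[0])
        tot = total_intensity(grid, "outer_scaffold", 0, truth.center_um)
        cen, packet, direct = centrosome_and_packet_intensity(corrected, comps, tot)
        assert direct == pytest.approx(0.0, abs=1e-6)
        assert packet <= 0.01 * tot

    def test_postrupture_packet_intensity_matches_direct_sum(self, noiseless_movie):
        grid, truth = noiseless_movie
        t = int(truth.onsets_min["outer_scaffold"]["packet"])
        corrected, _ = subtract_background(grid, "outer_scaffold", t,
                                           rng=np.random.default_rng(0))
        mask, _ = segment_pcm(corrected, smooth_sigma_px=1.0)
        comps = label_components(mask, grid.calibration, corrected)
        centriole_connected_volume(comps, truth.centriole_positions_um[t])
        tot = total_intensity(grid, "outer_scaffold", t, truth.center_um)
        cen, packet, direct = centrosome_and_packet_intensity(corrected, comps, tot)
        assert direct > 0
        assert packet == pytest.approx(direct, rel=0.15)

    @pytest.mark.parametrize("foci,n,expected", [
        ((500.0, 500.0), 2, 500.0),
        ((800.0,), 1, 800.0),
        ((400.0, 600.0), 2, 500.0),  # arithmetic-mean oracle
    ])
    def test_per_centriole_residual(self, foci, n, expected):
        assert per_centriole_residual(sum(foci), n) == pytest.approx(expected)

    def test_per_centriole_residual_rejects_zero_foci(self):
        with pytest.raises(ValueError):
            per_centriole_residual(100.0, 0)


class TestTimecourse:
    def test_static_noiseless_preset_gives_constant_series(self):
        preset = pk.make_preset("control", channels=("outer_scaffold",)).static()
        grid, truth = pk.generate_movie(preset, 1, noise=False)
        cpos = [[tuple(p) for p in f] for f in truth.centriole_positions_um]
        tc = pk.measure_timecourse(grid, "outer_scaffold",
                                   centriole_positions_um=cpos,
                                   rng=np.random.default_rng(0))
        tab = tc.series.table
        assert tab["pcm_volume_um3"].nunique() == 1
        assert np.ptp(tab["centrosome_au"]) <= 1e-4 * tab["centrosome_au"].max()
        assert (tab["n_packets"] == 0).all()

    def test_gpr12_movie_has_no_packets_in_any_frame(self):
        preset = pk.make_preset("gpr12_rnai", channels=("outer_scaffold",))
        grid, truth = pk.generate_movie(preset, 9)
        cpos = [[tuple(p) for p in f] for f in truth.centriole_positions_um]
        tc = pk.measure_timecourse(grid, "outer_scaffold",
                                   centriole_positions_um=cpos,
                                   rng=np.random.default_rng(9))
        assert (tc.series.table["n_packets"] == 0).all()
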