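"""Event-onset detectors and centriole-stage classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcmkit as pk
from pcmkit.events import (EventTimes, classify_centriole_stages,
                           detect_dissolution_onset, detect_packet_onset,
                           detect_rupture_onset, detect_volume_decrease_onset)
from pcmkit.quantify import label_components


class TestDissolution:
    def test_constructed_decline_onset_at_last_peak_frame(self):
        # constant 1000 through t = 3, then linear decline to 0
        times = np.arange(10.0)
        y = np.array([1000.0] * 4 + list(np.linspace(1000, 0, 7)[1:]))
        assert detect_dissolution_onset(times, y) == 3.0

    def test_monotone_series_has_no_onset(self):
        times = np.arange(6.0)
        assert detect_dissolution_onset(times, [1, 2, 3, 3, 4, 5]) is None

    def test_small_dips_below_threshold_are_ignored(self):
        times = np.arange(6.0)
        y = [1000, 990, 995, 1000, 990, 995]  # 1% wobble
        assert detect_dissolution_onset(times, y, min_drop_frac=0.05) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_dissolution_onset([0, 1], [5, 4])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(f1=st.floats(0.02, 0.2), f2=st.floats(0.2, 0.6))
    def test_raising_drop_threshold_never_advances_onset(self, f1, f2):
        times = np.arange(12.0)
        rng = np.random.default_rng(5)
        y = np.concatenate([np.full(4, 1000.0),
                            1000 * 0.7 ** np.arange(1, 9)])
        y = y * (1 + rng.normal(0, 0.01, y.size))
        lo = detect_dissolution_onset(times, y, min_drop_frac=f1)
        hi = detect_dissolution_onset(times, y, min_drop_frac=f2)
        if hi is not None:
            assert lo is not None and lo <= hi


class TestRupture:
    @staticmethod
    def _solid_box_masks(n_frames=10, carve_at=6):
        masks = []
        base = np.zeros((7, 20, 20), bool)
        base[1:6, 4:16, 4:16] = True
        for t in range(n_frames):
            m = base.copy()
            if t >= carve_at:
                m[2:4, 8:12, 8:12] = False  # interior cavity
            masks.append(m)
        volumes = [m.sum() * 0.01125 for m in masks]
        return masks, volumes

    def test_carved_cavity_detected_at_its_frame(self):
        masks, volumes = self._solid_box_masks(carve_at=6)
        det = detect_rupture_onset(masks, volumes, np.arange(10.0))
        assert det.hole_onset_min == 6.0
        assert det.onset_min == 6.0

    def test_static_masks_have_no_rupture(self):
        masks, volumes = self._solid_box_masks(carve_at=99)
        det = detect_rupture_onset(masks, volumes, np.arange(10.0))
        assert det.onset_min is None
        assert det.hole_onset_min is None and det.volume_onset_min is None

    def test_volume_drop_fallback(self):
        masks, _ = self._solid_box_masks(carve_at=99)
        volumes = [10.0] * 5 + [7.0] * 5  # 30% drop at frame 5, no holes
        det = detect_rupture_onset(masks, volumes, np.arange(10.0))
        assert det.volume_onset_min == 5.0
        assert det.hole_onset_min is None
        assert det.onset_min == 5.0

    def test_missing_volume_series_rejected(self):
        masks, _ = self._solid_box_masks()
        with pytest.raises(ValueError):
            detect_rupture_onset(masks, None, np.arange(10.0))

    def test_volume_decrease_onset_is_first_reduced_frame(self):
        v = [10, 10, 10, 8.5, 7, 6]
        assert detect_volume_decrease_onset(np.arange(6.0), v) == 3.0


class TestPackets:
    @staticmethod
    def _components_series(appear_at=7, n_frames=10):
        cal = pk.PhysicalCalibration()
        series = []
        for t in range(n_frames):
            mask = np.zeros((6, 30, 30), bool)
            mask[2:4, 12:18, 12:18] = True  # centrosome blob
            if t >= appear_at:
                mask[2:4, 12:15, 24:27] = True  # packet ~1 um away
            comps = label_components(mask, cal)
            pk.centriole_connected_volume(comps, [(1.25, 2.2, 2.2)])
            series.append(comps)
        return series

    def test_packet_component_detected_at_its_frame(self):
        series = self._components_series(appear_at=7)
        assert detect_packet_onset(series, np.arange(10.0)) == 7.0

    def test_empty_movie_has_no_packets(self):
        cal = pk.PhysicalCalibration()
        series = [label_components(np.zeros((4, 10, 10), bool), cal)
                  for _ in range(5)]
        assert detect_packet_onset(series, np.arange(5.0)) is None

    def test_minimum_size_filters_specks(self):
        series = self._components_series(appear_at=2)
        assert detect_packet_onset(series, np.arange(10.0), min_voxels=1000) is None


class TestStages:
    @staticmethod
    def _foci_grid(separations_um, amplitude=400.0):
        """Render two in-plane foci per frame at the given separations."""
        cal = pk.PhysicalCalibration(dx_um=0.15, dz_um=0.5)
        nz, ny, nx = 9, 64, 64
        center = np.array([2.0, 4.8, 4.8])
        z = (np.arange(nz) * cal.dz_um)[:, None, None]
        y = (np.arange(ny) * cal.dx_um)[None, :, None]
        x = (np.arange(nx) * cal.dx_um)[None, None, :]
        frames = []
        for sep in separations_um:
            frame = np.zeros((nz, ny, nx))
            for sign in (+1, -1):
                c = center + sign * np.array([0.0, 0.0, sep / 2])
                d = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
                frame += amplitude / (1 + np.exp((d - 0.15) / 0.1))
            frames.append(frame)
        data = np.asarray(frames)[:, None]
        return pk.VoxelGrid(data, cal, ("centriole",))

    def test_single_static_focus_has_no_stages(self):
        grid = self._foci_grid([0.0] * 6)
        st_times = classify_centriole_stages(grid, "centriole")
        assert st_times.stage1_onset_min is None
        assert st_times.stage2_onset_min is None

    def test_constant_speed_separation_crosses_one_micron_on_schedule(self):
        # separation 0.3 um/min from t = 4 min: 1.2 um (> 1 um) first at t = 8
        times = np.arange(12)
        seps = np.clip(0.3 * (times - 4), 0.0, None)
        grid = self._foci_grid(seps)
        st_times = classify_centriole_stages(grid, "centriole")
        assert st_times.stage2_onset_min == 8.0
        measured = st_times.separations_um[8]
        assert measured == pytest.approx(1.2, abs=0.1)

    def test_stage_recovery_on_noiseless_movie(self):
        preset = pk.make_preset("control", channels=("centriole", "kinase_inner"))
        grid, truth = pk.generate_movie(preset, 6, noise=False)
        st_times = classify_centriole_stages(grid, "centriole")
        assert st_times.stage1_onset_min == truth.onsets_min["centriole"]["stage1"]
        assert st_times.stage2_onset_min == truth.onsets_min["centriole"]["stage2"]


class TestEventTimes:
    def test_ordering_invariants_enforced(self):
        with pytest.raises(ValueError):
            EventTimes(dissolution_onset_min=5.0, rupture_onset_min=3.0)
        with pytest.raises(ValueError):
            EventTimes(stage1_onset_min=6.0, stage2_onset_min=5.0)

    def test_noiseless_movie_recovers_ground_truth_onsets(self, noiseless_movie):
        grid, truth = noiseless_movie
        cpos = [[tuple(p) for p in f] for f in truth.centriole_positions_um]
        tc, ev = pk.analyze_channel(grid, "outer_scaffold",
                                    centriole_positions_um=cpos,
                                    rng=np.random.default_rng(0))
        tr = truth.onsets_min["outer_scaffold"]
        dt = grid.calibration.dt_min
        assert abs(ev.rupture_onset_min - tr["rupture"]) <= dt
        assert abs(ev.packet_onset_min - tr["packet"]) <= dt
        assert abs(ev.dissolution_onset_min - tr["peak"]) <= dt

    def test_disassembly_ordering_on_noisy_movie(self, noisy_movie):
        grid, truth = noisy_movie
        cpos = [[tuple(p) for p in f] for f in truth.centriole_positions_um]
        rng = np.random.default_rng(3)
        _, ev_in = pk.analyze_channel(grid, "inner_scaffold",
                                      centriole_positions_um=cpos, rng=rng)
        _, ev_out = pk.analyze_channel(grid, "outer_scaffold",
                                       centriole_positions_um=cpos, rng=rng)
        dt = grid.calibration.dt_min
        assert ev_in.dissolution_onset_min <= ev_out.rupture_onset_min
        assert ev_out.rupture_onset_min <= ev_out.packet_onset_min + dt
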