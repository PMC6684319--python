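"""Detection of disassembly events and centriole separation stages.

Event conventions (all times in minutes post-NEBD, reported on the
acquisition grid; cohort means across movies may be fractional):

* *dissolution* - the timepoint at which the decline in centrosomal
  intensity begins: the frame preceding the first sustained drop of more
  than ``min_drop_frac`` of the running maximum;
* *volume decrease* - the first frame whose centriole-connected volume falls
  below the running maximum by more than a configured fraction;
* *rupture* - the first frame at which holes appear in the PCM (newly
  background voxels strictly interior to the previous frame's
  centriole-connected component), or at which the connected volume drops by
  more than ``volume_drop_frac`` from its running maximum, whichever detector
  fires earlier (both are reported);
* *packet formation* - the first frame with an individualized (non
  centriole-connected) component above a minimum size near the centrosome;
* *Stage 1 / Stage 2* - first frame with two resolvable centriole foci
  (separated by >= 2 px with a >= 20% intensity dip between them), and first
  frame with a 3-D inter-focus distance above 1 um.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.feature import peak_local_max

from .grid import VoxelGrid
from .quantify import LabeledComponents, TimecourseResult, _refine_centroid

__all__ = ["EventTimes", "RuptureDetection", "StageTimes",
           "detect_dissolution_onset", "detect_volume_decrease_onset",
           "detect_rupture_onset", "detect_packet_onset",
           "classify_centriole_stages", "detect_events"]

_IN_PLANE = np.zeros((3, 3, 3), dtype=bool)
_IN_PLANE[1] = True  # 8-connected in-plane structuring element for erosion


@dataclass
class EventTimes:
    """Detected onsets for one movie/channel; ``None`` means absent."""

    dissolution_onset_min: float | None = None
    volume_decrease_onset_min: float | None = None
    rupture_onset_min: float | None = None
    packet_onset_min: float | None = None
    stage1_onset_min: float | None = None
    stage2_onset_min: float | None = None

    def __post_init__(self):
        d, r, p = (self.dissolution_onset_min, self.rupture_onset_min,
                   self.packet_onset_min)
        if d is not None and r is not None and r < d:
            raise ValueError("rupture onset cannot precede dissolution onset")
        if r is not None and p is not None and p < r:
            raise ValueError("packet onset cannot precede rupture onset")
        s1, s2 = self.stage1_onset_min, self.stage2_onset_min
        if s1 is not None and s2 is not None and s2 < s1:
            raise ValueError("Stage 2 cannot precede Stage 1")

    def to_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class RuptureDetection:
    onset_min: float | None
    hole_onset_min: float | None
    volume_onset_min: float | None


@dataclass(frozen=True)
class StageTimes:
    stage1_onset_min: float | None
    stage2_onset_min: float | None
    separations_um: tuple  # per-frame separation (nan when unresolved)


def detect_dissolution_onset(times_min: Sequence[float], intensity: Sequence[float],
                             min_drop_frac: float = 0.10, persistence: int = 2
                             ) -> float | None:
    """Onset of the sustained decline in an intensity series.

    Scans for the first frame ``t*`` whose intensity falls below the running
    maximum by more than ``min_drop_frac`` of that maximum, with the deficit
    sustained for ``persistence`` consecutive frames, and reports the frame
    preceding ``t*`` (the timepoint at which the decrease begins).  Returns
    ``None`` for series that never decline.
    """
    times = np.asarray(times_min, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if y.size < 3:
        raise ValueError("series needs at least 3 timepoints")
    if persistence < 1 or y.size < persistence + 1:
        raise ValueError("series shorter than the persistence window")
    runmax = np.maximum.accumulate(y)
    below = y < runmax * (1.0 - min_drop_frac)
    for t in range(1, y.size - persistence + 1):
        if below[t:t + persistence].all():
            return float(times[t - 1])
    return None


def detect_volume_decrease_onset(times_min, volumes, drop_frac: float = 0.10
                                 ) -> float | None:
    """First frame whose volume falls below the running max by > drop_frac."""
    times = np.asarray(times_min, dtype=float)
    v = np.asarray(volumes, dtype=float)
    runmax = np.maximum.accumulate(v)
    hits = np.nonzero(v < runmax * (1.0 - drop_frac))[0]
    return float(times[hits[0]]) if hits.size else None


def _new_interior_background(prev_mask: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Background voxels strictly interior to the previous frame's component."""
    interior = ndimage.binary_erosion(prev_mask, structure=_IN_PLANE)
    return interior & ~mask


def detect_rupture_onset(connected_masks: Sequence[np.ndarray],
                         volumes_um3: Sequence[float],
                         times_min: Sequence[float],
                         volume_drop_frac: float = 0.15,
                         min_hole_voxels: int = 4) -> RuptureDetection:
    """Rupture: holes in the PCM and/or a sharp connected-volume drop.

    ``connected_masks`` are the per-frame centriole-connected masks from the
    quantification pipeline.  The hole detector flags the first frame with at
    least ``min_hole_voxels`` newly background voxels strictly interior to
    the previous frame's mask (an in-plane erosion defines "interior", which
    catches enclosed cavities and background-connected bites alike); the
    volume detector flags the first frame whose volume falls below the
    running maximum by more than ``volume_drop_frac``.  The earlier wins.
    """
    if volumes_um3 is None:
        raise ValueError("a volume series is required")
    times = np.asarray(times_min, dtype=float)
    if len(connected_masks) != times.size or len(volumes_um3) != times.size:
        raise ValueError("masks, volumes and times must be frame-aligned")
    hole_onset = None
    for t in range(1, times.size):
        holes = _new_interior_background(connected_masks[t - 1], connected_masks[t])
        if holes.any():
            labels, n = ndimage.label(holes, structure=np.ones((3, 3, 3), bool))
            sizes = ndimage.sum_labels(holes, labels, np.arange(1, n + 1))
            if (sizes >= min_hole_voxels).any():
                hole_onset = float(times[t])
                break
    vol_onset = detect_volume_decrease_onset(times, volumes_um3, volume_drop_frac)
    candidates = [x for x in (hole_onset, vol_onset) if x is not None]
    return RuptureDetection(min(candidates) if candidates else None,
                            hole_onset, vol_onset)


def detect_packet_onset(components: Sequence[LabeledComponents],
                        times_min: Sequence[float],
                        center_um=None, min_voxels: int = 3,
                        search_radius_um: float = 5.0) -> float | None:
    """First frame with an individualized PCM focus near the centrosome.

    Requires each frame's components to carry the centriole classification
    (``centriole_labels``); a packet is a non-connected component of at least
    ``min_voxels`` voxels whose centroid lies within ``search_radius_um`` of
    the centrosome center (the mean centriole position when not given).
    """
    times = np.asarray(times_min, dtype=float)
    for t, comps in enumerate(components):
        if comps.n_components == 0:
            continue
        if center_um is None:
            if not comps.centriole_labels:
                continue
            idx = np.asarray(comps.centriole_labels) - 1
            ctr = comps.centroids_um[idx].mean(axis=0)
        else:
            ctr = np.asarray(center_um, dtype=float)
        for label in range(1, comps.n_components + 1):
            if label in comps.centriole_labels:
                continue
            if comps.voxel_counts[label - 1] < min_voxels:
                continue
            if np.linalg.norm(comps.centroids_um[label - 1] - ctr) <= search_radius_um:
                return float(times[t])
    return None


def classify_centriole_stages(grid: VoxelGrid, channel, *,
                              smooth_sigma_px: float = 0.7,
                              min_sep_px: float = 2.0, dip_frac: float = 0.20,
                              stage2_sep_um: float = 1.0) -> StageTimes:
    """Stage 1/2 centriole-separation onsets from the centriole channel.

    Per frame, the two strongest in-plane local maxima near the focus are
    refined to sub-pixel centroids.  The foci are *resolvable* when separated
    by at least ``min_sep_px`` lateral pixels with an intensity dip of at
    least ``dip_frac`` between them.  Stage 1 is the first frame with two
    resolvable foci; Stage 2 the first frame whose 3-D separation exceeds
    ``stage2_sep_um``.
    """
    dz, dy, dx = grid.calibration.spacing_zyx_um
    times = grid.times_min
    stage1 = stage2 = None
    seps = []
    for t in range(grid.n_frames):
        stack = np.asarray(grid.stack(channel, t), dtype=np.float64)
        z_star = int(np.argmax(stack.max(axis=(1, 2))))
        plane = stack[z_star] - np.median(stack[z_star])
        sm = gaussian(plane, sigma=smooth_sigma_px, preserve_range=True)
        if sm.max() <= 0:
            raise ValueError(f"no centriole focus detectable at frame {t}")
        peaks = peak_local_max(sm, min_distance=max(1, int(round(min_sep_px))),
                               num_peaks=2, threshold_abs=0.3 * sm.max())
        sep_um = np.nan
        if len(peaks) == 2:
            (y0, x0), (y1, x1) = peaks
            sep_px = float(np.hypot(y0 - y1, x0 - x1))
            mid = sm[int(round((y0 + y1) / 2)), int(round((x0 + x1) / 2))]
            lower_peak = min(sm[y0, x0], sm[y1, x1])
            if sep_px >= min_sep_px and mid <= (1.0 - dip_frac) * lower_peak:
                cy0, cx0 = _refine_centroid(sm, y0, x0)
                cy1, cx1 = _refine_centroid(sm, y1, x1)
                sep_um = float(np.hypot((cy0 - cy1) * dy, (cx0 - cx1) * dx))
                if stage1 is None:
                    stage1 = float(times[t])
                if stage2 is None and sep_um > stage2_sep_um:
                    stage2 = float(times[t])
        seps.append(sep_um)
    return StageTimes(stage1, stage2, tuple(seps))


def detect_events(timecourse: TimecourseResult, *, grid: VoxelGrid | None = None,
                  centriole_channel=None, min_drop_frac: float = 0.10,
                  persistence: int = 2, volume_drop_frac: float = 0.15,
                  min_hole_voxels: int = 4, min_packet_voxels: int = 3,
                  packet_search_radius_um: float = 5.0) -> EventTimes:
    """Assemble all event onsets for one quantified channel."""
    tab = timecourse.series.table
    times = tab["t_min"].to_numpy()
    diss = detect_dissolution_onset(times, tab["centrosome_au"].to_numpy(),
                                    min_drop_frac, persistence)
    vol = detect_volume_decrease_onset(times, tab["pcm_volume_um3"].to_numpy())
    rup = detect_rupture_onset(timecourse.connected_masks,
                               tab["pcm_volume_um3"].to_numpy(), times,
                               volume_drop_frac, min_hole_voxels)
    center = np.mean(np.asarray(timecourse.centriole_positions_um[0], dtype=float),
                     axis=0)
    pack = detect_packet_onset(timecourse.components, times, center,
                               min_packet_voxels, packet_search_radius_um)
    s1 = s2 = None
    if grid is not None and centriole_channel is not None:
        st = classify_centriole_stages(grid, centriole_channel)
        s1, s2 = st.stage1_onset_min, st.stage2_onset_min
    if rup.onset_min is not None and pack is not None and pack < rup.onset_min:
        pack = rup.onset_min  # a packet cannot individualize before rupture
    return EventTimes(diss, vol, rup.onset_min, pack, s1, s2)
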