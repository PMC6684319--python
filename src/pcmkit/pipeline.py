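"""End-to-end analysis of a single movie and of seeded cohorts.

These helpers wire the module operations together the way the analysis is
meant to be run: background correction -> radial profiling at the NEBD frame,
and the per-frame quantification pipeline -> event detection for each
channel of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventTimes, classify_centriole_stages, detect_events
from .geometry import BoundarySet, average_line_profile, half_max_boundaries
from .grid import VoxelGrid
from .quantify import TimecourseResult, measure_timecourse, subtract_background
from .simulate import ConditionPreset, GroundTruth, generate_movie

__all__ = ["MovieAnalysis", "profile_boundaries", "analyze_channel",
           "analyze_movie", "analyze_cohort"]


@dataclass
class MovieAnalysis:
    """All per-movie results keyed by channel."""

    boundaries: dict[str, BoundarySet] = field(default_factory=dict)
    timecourses: dict[str, TimecourseResult] = field(default_factory=dict)
    events: dict[str, EventTimes] = field(default_factory=dict)
    stage1_onset_min: float | None = None
    stage2_onset_min: float | None = None


def profile_boundaries(grid: VoxelGrid, channel, t: int, center_um, *,
                       rng=None, n_angles: int = 36, half_length_um: float = 2.5
                       ) -> BoundarySet:
    """Background-corrected radial profile -> half-max boundaries."""
    corrected, _ = subtract_background(grid, channel, t, rng=rng)
    prof = average_line_profile(corrected, grid.calibration, center_um,
                                n_angles=n_angles, half_length_um=half_length_um)
    return half_max_boundaries(prof)


def analyze_channel(grid: VoxelGrid, channel, *, centriole_positions_um=None,
                    centriole_channel="centriole", rng=None, **kw
                    ) -> tuple[TimecourseResult, EventTimes]:
    """Quantification pipeline plus event detection for one channel."""
    tc = measure_timecourse(grid, channel,
                            centriole_channel=(None if centriole_positions_um is not None
                                               else centriole_channel),
                            centriole_positions_um=centriole_positions_um,
                            rng=rng, **kw)
    ev = detect_events(tc)
    return tc, ev


def analyze_movie(grid: VoxelGrid, truth: GroundTruth | None = None, *,
                  boundary_channels=(), event_channels=(),
                  centriole_channel="centriole", rng=None) -> MovieAnalysis:
    """Boundaries at the NEBD frame plus time courses/events per channel."""
    out = MovieAnalysis()
    t0 = grid.calibration.t0_event
    if truth is not None:
        center = truth.center_um
        cpos = [[tuple(p) for p in frame] for frame in truth.centriole_positions_um]
    else:
        from .quantify import find_centriole_foci
        cpos = None
        center = tuple(np.mean(find_centriole_foci(grid, centriole_channel, t0),
                               axis=0))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for ch in boundary_channels:
        out.boundaries[ch] = profile_boundaries(grid, ch, t0, center, rng=rng)
    for ch in event_channels:
        tc, ev = analyze_channel(grid, ch, centriole_positions_um=cpos,
                                 centriole_channel=centriole_channel, rng=rng)
        out.timecourses[ch] = tc
        out.events[ch] = ev
    if centriole_channel in grid.channel_names:
        st = classify_centriole_stages(grid, centriole_channel)
        out.stage1_onset_min = st.stage1_onset_min
        out.stage2_onset_min = st.stage2_onset_min
    return out


def analyze_cohort(preset: ConditionPreset, seeds, *, noise: bool = True,
                   boundary_channels=(), event_channels=(),
                   use_truth_centrioles: bool = True) -> list[MovieAnalysis]:
    """Generate and analyze one movie per seed."""
    results = []
    for seed in seeds:
        grid, truth = generate_movie(preset, int(seed), noise=noise)
        results.append(analyze_movie(grid, truth if use_truth_centrioles else None,
                                     boundary_channels=boundary_channels,
                                     event_channels=event_channels,
                                     rng=np.random.default_rng(int(seed) + 7919)))
    return results
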