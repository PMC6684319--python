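"""Seeded synthetic centrosome movies with ground truth.

The generator renders an end-on centrosome as concentric layered spheres (and
one toroidal shell) whose half-maximum radii, disassembly kinetics and noise
structure emulate live spinning-disk imaging of a *C. elegans* ABp centrosome:

* each channel is a radially symmetric intensity field with a logistic edge of
  softness ``w`` (0.1 um), so the half-maximum radius equals the nominal
  radius analytically;
* inner-sphere proteins leave by *dissolution* (exponential intensity decay to
  a residual floor, plus a gradual radius shrink once the volume starts to
  decrease);
* the outer sphere *ruptures*: background-connected cavities are carved into
  the shell, after which ``n_packets`` individualized foci are released and
  translate radially outward while decaying;
* the centriole channel is a single focus that resolves into two foci
  (Stage 1) which then separate beyond 1 um (Stage 2);
* a uniform cytoplasmic background with per-plane jitter is added, and the
  frame is corrupted with Poisson shot noise (gain ``g``) and additive
  Gaussian read noise.

Per-movie biological variability of event times is modelled on the
acquisition grid: every onset is realized as ``floor(mean)`` or ``ceil(mean)``
with probability equal to the fractional part, drawn from a golden-ratio
low-discrepancy sequence keyed on the seed, so cohorts of ~10 consecutive
seeds reproduce the cohort-mean onsets with sub-frame accuracy (mirroring how
frame-quantized per-embryo onsets average to fractional minutes).

RNG contract: a single integer seed drives all stochastic draws through one
``numpy`` Generator, consumed in a documented order: (1) per-plane background
jitter, (2) centriole separation direction, (3) per channel (preset order):
packet direction jitters, (4) Poisson shot noise, (5) Gaussian read noise.
Identical (preset, seed, flags) give bit-identical movies and ground truth.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit

from .grid import PhysicalCalibration, VoxelGrid

__all__ = [
    "ChannelSpec",
    "KineticsSpec",
    "NoiseSpec",
    "ConditionPreset",
    "GroundTruth",
    "CONDITIONS",
    "make_preset",
    "generate_movie",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _strat_uniform(seed: int, tag: str) -> float:
    """Low-discrepancy uniform in [0, 1) keyed on (seed, tag).

    Consecutive seeds map to a golden-ratio sequence (equidistributed with
    discrepancy ~1/n over any n consecutive seeds); the tag adds a constant
    per-event phase.
    """
    phase = (zlib.crc32(tag.encode()) & 0xFFFFFFFF) / 2.0**32
    return (seed * _GOLDEN + phase) % 1.0


def realize_onset(mean_min: float | None, seed: int, tag: str) -> int | None:
    """Quantize a mean onset (min) to this movie's frame-grid onset."""
    if mean_min is None:
        return None
    lo = math.floor(mean_min)
    frac = mean_min - lo
    return int(lo) + (1 if _strat_uniform(seed, tag) < frac - 1e-12 else 0)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """Geometry of one fluorescent channel.

    ``shape`` is ``solid_sphere`` (filled ball), ``toroid`` (spherical shell
    between ``r_inner_um`` and ``r_outer_um``, an annulus end-on) or
    ``point_pair`` (centriole foci).  ``r_halfmax_um`` is the half-maximum
    radius in um; ``amplitude`` the peak intensity in a.u.
    """

    name: str
    shape: str
    r_halfmax_um: float = 0.0
    r_inner_um: float = 0.0
    r_outer_um: float = 0.0
    amplitude: float = 300.0
    edge_softness_um: float = 0.1
    focus_r_um: float = 0.15  # radius of each centriole focus once split

    def __post_init__(self):
        if self.shape not in ("solid_sphere", "toroid", "point_pair"):
            raise ValueError(f"unknown channel shape {self.shape!r}")
        if self.shape == "toroid":
            if not 0 < self.r_inner_um < self.r_outer_um:
                raise ValueError("toroid requires 0 < r_inner_um < r_outer_um")
        elif self.r_halfmax_um <= 0:
            raise ValueError("r_halfmax_um must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.edge_softness_um <= 0:
            raise ValueError("edge_softness_um must be positive")

    @property
    def outer_radius_um(self) -> float:
        return self.r_outer_um if self.shape == "toroid" else self.r_halfmax_um


@dataclass(frozen=True)
class KineticsSpec:
    """Disassembly kinetics of one channel (all times in minutes post-NEBD).

    ``None`` onsets disable the corresponding behaviour.  ``peak_time_min``
    channels ramp linearly from ``(1 - rise_fraction) * amplitude`` at NEBD to
    the full amplitude at the peak, then decay; ``dissolution_onset_min``
    channels hold the plateau until the onset frame, then decay.  Decay is
    exponential with ``decay_halflife_min`` toward
    ``residual_fraction * amplitude``.
    """

    dissolution_onset_min: float | None = None
    volume_decrease_onset_min: float | None = None
    peak_time_min: float | None = None
    decay_halflife_min: float | None = None
    rise_fraction: float = 0.2
    shrink_rate_per_min: float = 0.06
    rupture_onset_min: float | None = None
    packet_onset_min: float | None = None
    n_packets: int = 0
    packet_speed_um_per_min: float = 0.8
    packet_decay_halflife_min: float = 1.5
    packet_r_um: float = 0.3
    packet_release_radius_um: float = 1.8
    stage1_onset_min: float | None = None
    stage2_onset_min: float | None = None
    residual_fraction: float = 0.0

    def __post_init__(self):
        for name in ("dissolution_onset_min", "volume_decrease_onset_min",
                     "peak_time_min", "rupture_onset_min", "packet_onset_min",
                     "stage1_onset_min", "stage2_onset_min"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must be in [0, 1]")
        if self.rupture_onset_min is not None:
            start = self.dissolution_onset_min or self.peak_time_min
            if start is not None and self.rupture_onset_min < start:
                raise ValueError("rupture_onset_min must be >= dissolution/peak onset")
        if (self.stage1_onset_min is not None and self.stage2_onset_min is not None
                and self.stage2_onset_min < self.stage1_onset_min):
            raise ValueError("stage2_onset_min must be >= stage1_onset_min")

    @property
    def first_change_min(self) -> float | None:
        """Earliest time at which this channel's signal changes."""
        candidates = [t for t in (self.dissolution_onset_min,
                                  self.volume_decrease_onset_min,
                                  self.rupture_onset_min) if t is not None]
        if self.peak_time_min is not None and self.rise_fraction > 0:
            candidates.append(0.0)
        elif self.peak_time_min is not None:
            candidates.append(self.peak_time_min)
        return min(candidates) if candidates else None


@dataclass(frozen=True)
class NoiseSpec:
    background_level: float = 50.0
    poisson_gain: float = 1.0
    read_noise_sd: float = 1.0
    plane_jitter: float = 0.02

    def __post_init__(self):
        if self.background_level < 0 or self.poisson_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ConditionPreset:
    """Full generative parameter set for one experimental condition."""

    name: str
    channels: tuple[ChannelSpec, ...]
    kinetics: Mapping[str, KineticsSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    grid_shape: tuple[int, int, int, int] = (12, 24, 96, 128)  # nT, nZ, nY, nX
    calibration: PhysicalCalibration = field(default_factory=PhysicalCalibration)
    center_um: tuple[float, float, float] = (6.0, 7.2, 7.2)  # z, y, x

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        shapes = {c.shape for c in self.channels}
        if "point_pair" not in shapes or shapes == {"point_pair"}:
            raise ValueError("preset needs at least one PCM channel and one "
                             "centriole (point_pair) channel")
        for n in names:
            if n not in self.kinetics:
                raise ValueError(f"missing kinetics for channel {n!r}")
        self._check_geometry_fits()

    def _check_geometry_fits(self):
        nT, nZ, nY, nX = self.grid_shape
        dz, dy, dx = self.calibration.spacing_zyx_um
        field_um = (nZ * dz, nY * dy, nX * dx)
        horizon = (nT - 1 - self.calibration.t0_event) * self.calibration.dt_min
        for ch in self.channels:
            kin = self.kinetics[ch.name]
            reach = ch.outer_radius_um
            if kin.packet_onset_min is not None and kin.n_packets > 0:
                travel = max(0.0, horizon - kin.packet_onset_min) * kin.packet_speed_um_per_min
                reach = max(reach, kin.packet_release_radius_um + travel + kin.packet_r_um)
            for axis in (1, 2):  # lateral containment only; z clips are tolerated
                lo = self.center_um[axis]
                hi = field_um[axis] - self.center_um[axis]
                if reach > min(lo, hi):
                    raise ValueError(
                        f"grid too small: channel {ch.name!r} reaches {reach:.2f} um "
                        f"from the center but the field allows {min(lo, hi):.2f} um"
                    )

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "ConditionPreset":
        """Preset restricted to a subset of channels (must keep a centriole)."""
        names = tuple(names)
        return replace(self, channels=tuple(c for c in self.channels if c.name in names),
                       kinetics={n: k for n, k in self.kinetics.items() if n in names})

    def static(self) -> "ConditionPreset":
        """All kinetics neutralized: a time-invariant centrosome."""
        return replace(self, kinetics={n: KineticsSpec() for n in self.kinetics})

    def without_noise(self) -> "ConditionPreset":
        return replace(self, noise=NoiseSpec(background_level=self.noise.background_level,
                                             poisson_gain=0.0, read_noise_sd=0.0,
                                             plane_jitter=0.0))


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------

def _control_channels() -> tuple[ChannelSpec, ...]:
    return (
        ChannelSpec("centriole", "point_pair", r_halfmax_um=0.25, amplitude=400.0),
        ChannelSpec("kinase_inner", "solid_sphere", r_halfmax_um=0.45, amplitude=260.0),
        ChannelSpec("inner_scaffold", "solid_sphere", r_halfmax_um=0.575, amplitude=300.0),
        ChannelSpec("intermediate", "solid_sphere", r_halfmax_um=0.72, amplitude=280.0),
        ChannelSpec("outer_scaffold", "solid_sphere", r_halfmax_um=0.83, amplitude=300.0),
        ChannelSpec("gamma_turc", "solid_sphere", r_halfmax_um=0.84, amplitude=290.0),
        ChannelSpec("aurora_toroid", "toroid", r_inner_um=0.48, r_outer_um=1.20,
                    amplitude=250.0),
    )


def _control_kinetics() -> dict[str, KineticsSpec]:
    return {
        "centriole": KineticsSpec(stage1_onset_min=5.0, stage2_onset_min=6.429),
        "kinase_inner": KineticsSpec(dissolution_onset_min=2.0,
                                     volume_decrease_onset_min=3.0,
                                     decay_halflife_min=1.5, residual_fraction=0.10),
        "inner_scaffold": KineticsSpec(dissolution_onset_min=2.2,
                                       volume_decrease_onset_min=3.0,
                                       decay_halflife_min=1.5, residual_fraction=0.10),
        "intermediate": KineticsSpec(dissolution_onset_min=3.0,
                                     volume_decrease_onset_min=3.0,
                                     decay_halflife_min=1.5, residual_fraction=0.10),
        "outer_scaffold": KineticsSpec(peak_time_min=3.0, decay_halflife_min=2.0,
                                       rupture_onset_min=5.91, packet_onset_min=6.5,
                                       n_packets=4, packet_decay_halflife_min=1.5,
                                       residual_fraction=0.10),
        "gamma_turc": KineticsSpec(peak_time_min=3.0, decay_halflife_min=2.0,
                                   rupture_onset_min=6.0, packet_onset_min=6.5,
                                   n_packets=4, packet_decay_halflife_min=1.0,
                                   residual_fraction=0.10),
        "aurora_toroid": KineticsSpec(peak_time_min=3.0, decay_halflife_min=2.0,
                                      residual_fraction=0.10),
    }


def _scale_amplitude(channels, name, factor):
    return tuple(replace(c, amplitude=c.amplitude * factor) if c.name == name else c
                 for c in channels)


def make_preset(condition_name: str, channels: Iterable[str] | None = None) -> ConditionPreset:
    """Build the generative preset for a named experimental condition.

    Conditions: ``control`` (lacZ RNAi), ``gpr12_rnai`` (reduced cortical
    forces: no rupture or packets, delayed centriole separation, elevated
    outer-channel residual), ``csnk1_rnai`` (increased forces: earlier rupture,
    lower outer-channel level, earlier separation) and ``let92_rnai``
    (PP2A-depleted one-cell zygote, abstracted to the same grid: 5x slower
    decay, long-lived packets shed from inner and outer scaffolds, no rupture
    holes, large residual).

    ``channels`` optionally restricts the preset to a subset of channel names
    (the centriole channel is always retained).
    """
    kin = _control_kinetics()
    chans = _control_channels()
    noise = NoiseSpec()
    grid_shape = (12, 24, 96, 128)

    if condition_name == "control":
        pass
    elif condition_name == "gpr12_rnai":
        kin["centriole"] = replace(kin["centriole"], stage1_onset_min=9.091,
                                   stage2_onset_min=12.100)
        for name in ("outer_scaffold", "gamma_turc"):
            kin[name] = replace(kin[name], rupture_onset_min=None,
                                packet_onset_min=None, n_packets=0,
                                residual_fraction=0.24)
        grid_shape = (16, 24, 96, 128)
    elif condition_name == "csnk1_rnai":
        kin["centriole"] = replace(kin["centriole"], stage1_onset_min=4.714,
                                   stage2_onset_min=5.714)
        kin["outer_scaffold"] = replace(kin["outer_scaffold"], rupture_onset_min=5.4,
                                        packet_onset_min=6.0)
        chans = _scale_amplitude(chans, "outer_scaffold", 0.85)
    elif condition_name == "let92_rnai":
        for name in ("kinase_inner", "inner_scaffold", "intermediate",
                     "outer_scaffold", "gamma_turc", "aurora_toroid"):
            k = kin[name]
            kin[name] = replace(k, decay_halflife_min=(k.decay_halflife_min or 1.5) * 5,
                                residual_fraction=0.25)
        # packets without rupture holes, long-lived, from both scaffolds
        kin["outer_scaffold"] = replace(kin["outer_scaffold"], rupture_onset_min=None,
                                        packet_onset_min=8.0, n_packets=4,
                                        packet_decay_halflife_min=6.0,
                                        packet_speed_um_per_min=0.5)
        kin["inner_scaffold"] = replace(kin["inner_scaffold"], packet_onset_min=9.0,
                                        n_packets=3, packet_decay_halflife_min=6.0,
                                        packet_speed_um_per_min=0.5)
        kin["gamma_turc"] = replace(kin["gamma_turc"], rupture_onset_min=None,
                                    packet_onset_min=None, n_packets=0)
        grid_shape = (16, 24, 96, 128)
    else:
        valid = ["control", "gpr12_rnai", "csnk1_rnai", "let92_rnai"]
        raise ValueError(f"unknown condition {condition_name!r}; valid conditions: {valid}")

    if channels is not None:
        keep = set(channels) | {"centriole"}
        chans = tuple(c for c in chans if c.name in keep)
        kin = {n: k for n, k in kin.items() if n in keep}
    return ConditionPreset(name=condition_name, channels=chans, kinetics=kin,
                           noise=noise, grid_shape=grid_shape)


CONDITIONS = ("control", "gpr12_rnai", "csnk1_rnai", "let92_rnai")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows about one realized movie."""

    condition: str
    seed: int
    radii_um: dict[str, float]
    onsets_min: dict[str, dict[str, float | None]]  # channel -> event -> time
    centriole_positions_um: list[list[tuple[float, float, float]]]  # per frame
    packet_tracks_um: dict[str, list[list[tuple[float, float, float]]]]  # ch -> per packet per frame
    noiseless_totals: dict[str, list[float]]  # ch -> per-frame summed signal (no background)
    center_um: tuple[float, float, float]

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["centriole_positions_um"] = [[tuple(p) for p in frame]
                                         for frame in doc["centriole_positions_um"]]
        doc["packet_tracks_um"] = {ch: [[tuple(p) for p in tr] for tr in trs]
                                   for ch, trs in doc["packet_tracks_um"].items()}
        doc["center_um"] = tuple(doc["center_um"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _distance_field(shape_zyx, spacing, center_um, dtype=np.float32):
    nz, ny, nx = shape_zyx
    dz, dy, dx = spacing
    z = (np.arange(nz, dtype=dtype) * dz - center_um[0])[:, None, None]
    y = (np.arange(ny, dtype=dtype) * dy - center_um[1])[None, :, None]
    x = (np.arange(nx, dtype=dtype) * dx - center_um[2])[None, None, :]
    return np.sqrt(z * z + y * y + x * x)


def _solid(d, r, w):
    return expit((r - d) / w)


def _shell(d, r_in, r_out, w):
    return expit((d - r_in) / w) * expit((r_out - d) / w)


def _local_box(shape_zyx, spacing, center_um, radius_um):
    """Slices covering a ball of ``radius_um`` around ``center_um``."""
    sl = []
    for ax in range(3):
        lo = int(math.floor((center_um[ax] - radius_um) / spacing[ax])) - 1
        hi = int(math.ceil((center_um[ax] + radius_um) / spacing[ax])) + 2
        sl.append(slice(max(lo, 0), min(hi, shape_zyx[ax])))
    return tuple(sl)


def _add_focus(field_zyx, spacing, center_um, r, w, amplitude):
    """Add a logistic-edged ball to ``field_zyx`` in place (local crop)."""
    box = _local_box(field_zyx.shape, spacing, center_um, r + 6 * w)
    if any(s.start >= s.stop for s in box):
        return
    sub_center = tuple(center_um[ax] - box[ax].start * spacing[ax] for ax in range(3))
    d = _distance_field(tuple(s.stop - s.start for s in box), spacing, sub_center)
    field_zyx[box] += amplitude * _solid(d, r, w)


def _carve_notch(field_zyx, spacing, center_um, r, w):
    """Multiply a logistic-edged void into ``field_zyx`` in place."""
    box = _local_box(field_zyx.shape, spacing, center_um, r + 6 * w)
    if any(s.start >= s.stop for s in box):
        return
    sub_center = tuple(center_um[ax] - box[ax].start * spacing[ax] for ax in range(3))
    d = _distance_field(tuple(s.stop - s.start for s in box), spacing, sub_center)
    field_zyx[box] *= 1.0 - _solid(d, r, w)


def _amplitude_profile(kin: KineticsSpec, onsets: dict, amplitude: float,
                       times: np.ndarray) -> np.ndarray:
    """Per-frame peak amplitude of a channel, given realized onsets."""
    a = np.full(times.shape, amplitude, dtype=np.float64)
    resid = kin.residual_fraction
    tau = kin.decay_halflife_min
    if kin.peak_time_min is not None:
        p = onsets["peak"]
        if p > 0 and kin.rise_fraction > 0:
            pre = times <= p
            ramp = np.clip((p - times[pre]) / p, 0.0, 1.0)
            a[pre] = amplitude * (1.0 - kin.rise_fraction * ramp)
        if tau:
            post = times > p
            decay = np.exp2(-(times[post] - p) / tau)
            a[post] = amplitude * (resid + (1.0 - resid) * decay)
    elif kin.dissolution_onset_min is not None and tau:
        k = onsets["dissolution"]
        post = times > k
        decay = np.exp2(-(times[post] - k) / tau)
        a[post] = amplitude * (resid + (1.0 - resid) * decay)
    return a


def _realize_onsets(preset: ConditionPreset, seed: int) -> dict[str, dict]:
    """Quantize every kinetic mean onto this movie's frame grid."""
    out: dict[str, dict] = {}
    for name in preset.channel_names:
        kin = preset.kinetics[name]
        tag = f"{preset.name}:{name}"
        o: dict[str, float | None] = {}
        o["dissolution"] = realize_onset(kin.dissolution_onset_min, seed, tag + ":diss")
        o["volume_decrease"] = realize_onset(kin.volume_decrease_onset_min, seed, tag + ":vol")
        o["peak"] = realize_onset(kin.peak_time_min, seed, tag + ":peak")
        o["rupture"] = realize_onset(kin.rupture_onset_min, seed, tag + ":rupt")
        o["packet"] = realize_onset(kin.packet_onset_min, seed, tag + ":pack")
        if o["rupture"] is not None and o["packet"] is not None:
            o["packet"] = max(o["packet"], o["rupture"])
        o["stage1"] = realize_onset(kin.stage1_onset_min, seed, tag + ":s1")
        o["stage2"] = realize_onset(kin.stage2_onset_min, seed, tag + ":s2")
        if o["stage1"] is not None and o["stage2"] is not None:
            o["stage2"] = max(o["stage2"], o["stage1"] + 1)
        out[name] = o
    return out


def _centriole_separation_um(t: float, s1: float | None, s2: float | None) -> float:
    """Inter-focus distance: unresolvable, slow Stage-1 drift, fast Stage-2.

    Capped at 1.3 um so both centrioles remain inside the outer sphere for
    the whole movie (the PCM surrounds the separating centrioles).
    """
    if s1 is None or t < s1:
        return 0.0
    if s2 is None or t < s2:
        return min(0.6 + 0.10 * (t - s1), 0.85)
    return min(1.15 + 0.35 * (t - s2), 1.3)


def generate_movie(preset: ConditionPreset, seed: int, *, noise: bool = True,
                   pre_event_frames: int = 0) -> tuple[VoxelGrid, GroundTruth]:
    """Render one synthetic centrosome movie and its ground truth.

    Deterministic for fixed ``(preset, seed, flags)``.  ``noise=False``
    disables Poisson/read noise and background jitter (the uniform background
    is still added), which is the mode exact-recovery tests rely on.
    ``pre_event_frames`` prepends a growth phase before NEBD (amplitudes ramp
    up to their NEBD plateau; frame ``pre_event_frames`` becomes t = 0).
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    nT, nZ, nY, nX = preset.grid_shape
    nT += int(pre_event_frames)
    cal = preset.calibration.replace(t0_event=preset.calibration.t0_event
                                     + int(pre_event_frames))
    spacing = cal.spacing_zyx_um
    center = preset.center_um
    times = cal.times_min(nT)
    rng = np.random.default_rng(seed)

    onsets = _realize_onsets(preset, seed)

    # (1) background jitter per (t, z) plane
    if noise and preset.noise.plane_jitter > 0:
        jitter = rng.normal(0.0, preset.noise.plane_jitter, size=(nT, nZ))
    else:
        jitter = np.zeros((nT, nZ))

    # (2) centriole separation direction (in plane)
    theta_sep = rng.uniform(0.0, 2.0 * np.pi)
    sep_dir = np.array([0.0, math.sin(theta_sep), math.cos(theta_sep)])

    d_center = _distance_field((nZ, nY, nX), spacing, center)

    movie = np.zeros((nT, len(preset.channels), nZ, nY, nX), dtype=np.float32)
    truth_positions: list[list[tuple[float, float, float]]] = [[] for _ in range(nT)]
    packet_tracks: dict[str, list[list[tuple[float, float, float]]]] = {}
    noiseless_totals: dict[str, list[float]] = {}

    for ci, ch in enumerate(preset.channels):
        kin = preset.kinetics[ch.name]
        o = onsets[ch.name]
        amp = _amplitude_profile(kin, o, ch.amplitude, times)
        if pre_event_frames > 0:  # growth phase: ramp up to the NEBD level
            neg = times < 0
            amp[neg] *= np.clip(1.0 + 0.7 * times[neg] / (pre_event_frames * cal.dt_min),
                                0.3, 1.0)
        w = ch.edge_softness_um

        # rupture notches: two bites into the shell equator, perpendicular to
        # the centriole separation axis so the centrioles are never carved out
        notches = []
        if o["rupture"] is not None:
            for phi in (theta_sep + np.pi / 2, theta_sep - np.pi / 2):
                notches.append(np.array([0.0, math.sin(phi), math.cos(phi)]))
        # (3) packet directions: jittered equal angular spacing, in plane
        packets = []
        if o["packet"] is not None and kin.n_packets > 0:
            base = rng.uniform(0.0, 2.0 * np.pi)
            jit = rng.uniform(-0.2, 0.2, size=kin.n_packets)
            for i in range(kin.n_packets):
                phi = base + 2.0 * np.pi * (i + jit[i]) / kin.n_packets
                packets.append(np.array([0.0, math.sin(phi), math.cos(phi)]))
            packet_tracks[ch.name] = [[] for _ in packets]

        totals = []
        shape_cache: dict[float, np.ndarray] = {}
        for t in range(nT):
            tm = times[t]
            if ch.shape == "point_pair":
                sep = _centriole_separation_um(tm, o["stage1"], o["stage2"])
                frame = np.zeros((nZ, nY, nX), dtype=np.float32)
                if sep <= 0:
                    _add_focus(frame, spacing, center, ch.r_halfmax_um, w, amp[t])
                    truth_positions[t].append(tuple(float(v) for v in center))
                else:
                    for sign in (+1.0, -1.0):
                        pos = np.asarray(center) + sign * 0.5 * sep * sep_dir
                        _add_focus(frame, spacing, tuple(pos), ch.focus_r_um, w, amp[t])
                        truth_positions[t].append(tuple(float(v) for v in pos))
            else:
                r = ch.r_halfmax_um
                amp_t = amp[t]
                if (o["volume_decrease"] is not None and tm >= o["volume_decrease"]
                        and kin.shrink_rate_per_min > 0 and ch.shape == "solid_sphere"):
                    shrink = max(0.55, 1.0 - kin.shrink_rate_per_min * (tm - o["volume_decrease"] + 1.0))
                    r = r * shrink
                    # compaction: shrinking concentrates, it does not remove,
                    # protein - the intensity time course is set by decay alone
                    amp_t = amp_t / shrink ** 3
                key = round(r, 6)
                if key not in shape_cache:
                    if ch.shape == "toroid":
                        shape_cache[key] = _shell(d_center, ch.r_inner_um, ch.r_outer_um, w)
                    else:
                        shape_cache[key] = _solid(d_center, key, w)
                frame = (amp_t * shape_cache[key]).astype(np.float32)
                if o["rupture"] is not None and tm >= o["rupture"]:
                    shell_r = ch.outer_radius_um
                    for direction in notches:
                        pos = np.asarray(center) + shell_r * direction
                        _carve_notch(frame, spacing, tuple(pos), 0.55, w)
                if o["packet"] is not None and tm >= o["packet"]:
                    p_frame = int(round(o["packet"] / cal.dt_min)) + cal.t0_event
                    a0 = 0.9 * amp[p_frame] if 0 <= p_frame < nT else 0.0
                    decay = 2.0 ** (-(tm - o["packet"]) / kin.packet_decay_halflife_min)
                    dist = kin.packet_release_radius_um + kin.packet_speed_um_per_min * (tm - o["packet"])
                    for pi, direction in enumerate(packets):
                        pos = np.asarray(center) + dist * direction
                        _add_focus(frame, spacing, tuple(pos), kin.packet_r_um, w, a0 * decay)
                        packet_tracks[ch.name][pi].append(tuple(float(v) for v in pos))
            totals.append(float(frame.sum()))
            movie[t, ci] = frame
        noiseless_totals[ch.name] = totals

    # background
    bg = preset.noise.background_level
    if bg > 0:
        movie += bg * (1.0 + jitter[:, None, :, None, None]).astype(np.float32)

    # (4) Poisson shot noise, (5) read noise
    if noise and preset.noise.poisson_gain > 0:
        g = preset.noise.poisson_gain
        movie = (rng.poisson(np.clip(movie, 0, None) / g) * g).astype(np.float32)
    if noise and preset.noise.read_noise_sd > 0:
        movie = movie + rng.normal(0.0, preset.noise.read_noise_sd, size=movie.shape).astype(np.float32)
    np.clip(movie, 0.0, None, out=movie)

    grid = VoxelGrid(movie, cal, preset.channel_names)
    radii = {c.name: (c.r_outer_um if c.shape == "toroid" else c.r_halfmax_um)
             for c in preset.channels}
    truth = GroundTruth(
        condition=preset.name, seed=int(seed), radii_um=radii,
        onsets_min={n: {k: (None if v is None else float(v)) for k, v in o.items()}
                    for n, o in onsets.items()},
        centriole_positions_um=truth_positions,
        packet_tracks_um=packet_tracks,
        noiseless_totals=noiseless_totals,
        center_um=tuple(float(v) for v in center),
    )
    return grid, truth
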