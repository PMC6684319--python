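"""Calibrated in-memory containers for multi-channel time-lapse z-stacks.

The universal image currency of the package is the :class:`VoxelGrid`: a
``T x C x Z x Y x X`` array of non-negative intensities (arbitrary camera
units) together with a :class:`PhysicalCalibration`.  Conventions:

* voxel indices are 0-based; physical positions refer to voxel centers;
* distances are in micrometers, times in minutes;
* frame ``calibration.t0_event`` is the reference event (NEBD), so frame ``t``
  sits at ``(t - t0_event) * dt_min`` minutes post-event;
* intensities are raw camera units and are never rescaled implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["PhysicalCalibration", "VoxelGrid"]


@dataclass(frozen=True)
class PhysicalCalibration:
    """Physical calibration of a time-lapse z-stack.

    Parameters
    ----------
    dx_um : float
        Lateral pixel size (um/px).  Identical in y and x.
    dz_um : float
        Axial step between z-planes (um).
    dt_min : float
        Frame interval (min).
    t0_event : int
        Index of the reference-event frame (NEBD); all event times are
        reported relative to this frame.
    """

    dx_um: float = 0.15
    dz_um: float = 0.5
    dt_min: float = 1.0
    t0_event: int = 0

    def __post_init__(self) -> None:
        for name in ("dx_um", "dz_um", "dt_min"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {getattr(self, name)!r}")
        if self.t0_event < 0:
            raise ValueError(f"t0_event must be >= 0, got {self.t0_event}")

    @property
    def spacing_zyx_um(self) -> tuple[float, float, float]:
        """Voxel spacing as (dz, dy, dx) in um."""
        return (self.dz_um, self.dx_um, self.dx_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dx_um * self.dz_um

    def times_min(self, n_frames: int) -> np.ndarray:
        """Frame times in minutes relative to the event frame."""
        return (np.arange(n_frames) - self.t0_event) * self.dt_min

    def replace(self, **kw) -> "PhysicalCalibration":
        return replace(self, **kw)


@dataclass
class VoxelGrid:
    """A calibrated ``T x C x Z x Y x X`` intensity stack.

    ``intensities`` must be finite and non-negative; ``channel_names`` labels
    the C axis.  Instances validate on construction.
    """

    intensities: np.ndarray
    calibration: PhysicalCalibration = field(default_factory=PhysicalCalibration)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 5:
            raise ValueError(
                f"intensities must be 5-D (T, C, Z, Y, X), got shape {self.intensities.shape}"
            )
        if min(self.intensities.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.intensities.shape}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.intensities.shape[1]))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[1]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.intensities.shape[1]} channels"
            )
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.calibration.t0_event >= self.intensities.shape[0]:
            raise ValueError(
                f"t0_event={self.calibration.t0_event} outside movie of "
                f"{self.intensities.shape[0]} frames"
            )

    # -- shape helpers -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape[2:]

    @property
    def times_min(self) -> np.ndarray:
        return self.calibration.times_min(self.n_frames)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; available: {list(self.channel_names)}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel index {channel} out of range")
        return int(channel)

    def stack(self, channel: int | str, t: int) -> np.ndarray:
        """The (Z, Y, X) stack of one channel at one frame (a view)."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} outside movie of {self.n_frames} frames")
        return self.intensities[t, self.channel_index(channel)]

    # -- coordinate conversions -------------------------------------------
    def um_to_index(self, pos_um: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index (z, y, x) for a physical position in um."""
        dz, dy, dx = self.calibration.spacing_zyx_um
        idx = (round(pos_um[0] / dz), round(pos_um[1] / dy), round(pos_um[2] / dx))
        return tuple(int(i) for i in idx)

    def index_to_um(self, idx: Sequence[int]) -> tuple[float, float, float]:
        dz, dy, dx = self.calibration.spacing_zyx_um
        return (idx[0] * dz, idx[1] * dy, idx[2] * dx)
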