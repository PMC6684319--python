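"""Reading and writing calibrated multi-channel time-lapse stacks.

Movies travel as OME-TIFF (primary) or plain multi-page TIFF with the
calibration supplied through the run configuration.  Axes are normalized to
``T, C, Z, Y, X`` on read; physical sizes are embedded in (and parsed from)
the OME ``Pixels`` attributes.  Values and calibration round-trip exactly
for float32 output.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile

from .config import load_config, validate_config  # noqa: F401  (re-exported)
from .grid import PhysicalCalibration, VoxelGrid

__all__ = ["read_movie", "write_movie", "load_config", "normalize_axes"]

_CANONICAL = "TCZYX"


def normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with axis labels to the canonical T,C,Z,Y,X.

    Idempotent: normalizing an already canonical array is the identity.
    """
    axes = axes.upper().replace("S", "C").replace("Q", "T")
    if data.ndim != len(axes):
        raise ValueError(f"axes {axes!r} do not match array of ndim {data.ndim}")
    unknown = set(axes) - set(_CANONICAL)
    if unknown:
        raise ValueError(f"ambiguous axis labels {sorted(unknown)}; expected {_CANONICAL}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis labels in {axes!r}")
    for i, ax in enumerate(_CANONICAL):
        if ax not in axes:
            data = np.expand_dims(data, i)
            axes = axes[:i] + ax + axes[i:]
    order = [axes.index(ax) for ax in _CANONICAL]
    return np.transpose(data, order)


def _parse_ome_calibration(xml: str) -> dict:
    out = {}
    try:
        root = ElementTree.fromstring(xml)
    except ElementTree.ParseError:
        return out
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            for attr, key in (("PhysicalSizeX", "dx_um"), ("PhysicalSizeZ", "dz_um"),
                              ("TimeIncrement", "dt_min")):
                v = pixels.get(attr)
                if v is not None:
                    out[key] = float(v)
            break
    return out


def read_movie(path, config: dict | None = None) -> VoxelGrid:
    """Read an OME-TIFF / multi-page TIFF movie into a :class:`VoxelGrid`.

    Calibration is parsed from the OME metadata when present; otherwise it
    must be supplied via ``config["calibration"]`` (a missing pixel size with
    no override is an error).  Channel names default to ``ch0, ch1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tif.ome_metadata
    data = normalize_axes(data, axes)

    cal_kw = _parse_ome_calibration(ome) if ome else {}
    names: tuple[str, ...] = ()
    if ome:
        try:
            root = ElementTree.fromstring(ome)
            chans = [el.get("Name") for el in root.iter() if el.tag.endswith("Channel")]
            if chans and all(chans):
                names = tuple(chans)[: data.shape[1]]
        except ElementTree.ParseError:
            pass
    if config is not None:
        overrides = config.get("calibration") or {}
        cal_kw.update({k: v for k, v in overrides.items()
                       if v is not None and k in ("dx_um", "dz_um", "dt_min", "t0_event")})
    missing = {"dx_um", "dz_um", "dt_min"} - set(cal_kw)
    if missing - {"dt_min"}:
        raise ValueError(
            f"movie {path.name} lacks calibration metadata ({sorted(missing)}); "
            "supply it via the configuration's 'calibration' section"
        )
    cal_kw.setdefault("dt_min", 1.0)
    cal = PhysicalCalibration(**{k: cal_kw[k] for k in ("dx_um", "dz_um", "dt_min")},
                              t0_event=int(cal_kw.get("t0_event", 0)))
    return VoxelGrid(np.asarray(data, dtype=np.float32), cal, names)


def write_movie(grid: VoxelGrid, path, dtype: str = "float32", clip: bool = False):
    """Write a :class:`VoxelGrid` as OME-TIFF with embedded calibration.

    ``dtype='float32'`` is lossless; ``dtype='uint16'`` requires values
    within [0, 65535] unless ``clip=True`` (clipping is then applied and is
    the documented behaviour).
    """
    path = Path(path)
    data = grid.intensities
    if dtype == "uint16":
        if data.max() > 65535 and not clip:
            raise ValueError(
                "values exceed the 16-bit range; pass clip=True to clip, or "
                "write float32"
            )
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    cal = grid.calibration
    metadata = {
        "axes": _CANONICAL,
        "PhysicalSizeX": cal.dx_um, "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": cal.dx_um, "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": cal.dz_um, "PhysicalSizeZUnit": "µm",
        "TimeIncrement": cal.dt_min, "TimeIncrementUnit": "min",
        "Channel": {"Name": list(grid.channel_names)},
    }
    tifffile.imwrite(path, data, ome=True, photometric="minisblack",
                     metadata=metadata)
    return path
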