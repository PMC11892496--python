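"""Typed containers for 3D/4D fluorescence stacks and lossless TIFF round-tripping.

The canonical in-memory layout is ``(t, z, y, x)`` with 0-based indices and z
increasing with depth below the tissue surface; on disk, volumes are stored as
multi-page TIFF in t-major / z-minor page order ("volume after volume").
Intensities are carried as floating-point values internally regardless of the
file bit depth.  Acquisition metadata (axial spacing, volume rate, per-slice
delays, rest window) travels in a YAML side-car config, never in TIFF tags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml


class FormatError(ValueError):
    """File contents violate the expected stack format (e.g. ragged pages)."""


class ShapeError(ValueError):
    """Array shapes are inconsistent with the declared geometry."""


class RangeError(ValueError):
    """Values fall outside the representable range of the requested format."""


_AXIS_ORDERS = ("tzyx", "ztyx")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition constants shared by every frame of a recording.

    Parameters
    ----------
    dz_um:
        Axial slice spacing in micrometres (> 0).
    volume_rate_hz:
        Volumes acquired per second (> 0).
    delay_map:
        Per-z-slice acquisition time offset within one volume period, in
        seconds.  ``None`` means all-zero delays (length then unconstrained).
    axis_order:
        Declared hyperstack page convention, ``"tzyx"`` (t-major, the on-disk
        canonical order) or ``"ztyx"`` (z-major).
    rest_window:
        Half-open ``(start, end)`` frame interval of the quiescent baseline
        period used for ΔF/F normalisation.
    """

    dz_um: float
    volume_rate_hz: float
    delay_map: np.ndarray | None = None
    axis_order: str = "tzyx"
    rest_window: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not self.dz_um > 0:
            raise ValueError(f"dz_um must be > 0, got {self.dz_um}")
        if not self.volume_rate_hz > 0:
            raise ValueError(f"volume_rate_hz must be > 0, got {self.volume_rate_hz}")
        if self.axis_order not in _AXIS_ORDERS:
            raise ValueError(f"axis_order must be one of {_AXIS_ORDERS}")
        if self.rest_window[0] >= self.rest_window[1]:
            raise ValueError("rest_window start must be < end")
        if self.delay_map is not None:
            dm = np.asarray(self.delay_map, dtype=float)
            period = 1.0 / self.volume_rate_hz
            if dm.ndim != 1:
                raise ValueError("delay_map must be 1-D (one entry per z-slice)")
            if np.any(dm < 0) or np.any(dm >= period):
                raise ValueError("delays must lie in [0, 1/volume_rate_hz)")
            object.__setattr__(self, "delay_map", dm)

    @property
    def period_s(self) -> float:
        return 1.0 / self.volume_rate_hz

    def with_delay_map(self, delay_map: np.ndarray) -> "AcquisitionMeta":
        return dataclasses.replace(self, delay_map=np.asarray(delay_map, float))


def linear_delay_map(n_slices: int, period_s: float) -> np.ndarray:
    """Delays for a constant-velocity axial sweep: d_z = (z/Z) * T."""
    return (np.arange(n_slices) / n_slices) * period_s


def sinusoidal_delay_map(n_slices: int, period_s: float) -> np.ndarray:
    """Delays following the sinusoidal phase of a resonant varifocal lens.

    Slice z sits at axial position cos(phi); the slice is acquired when the
    lens phase reaches arccos of its normalized depth, over half a period.
    """
    depth = 1.0 - 2.0 * (np.arange(n_slices) + 0.5) / n_slices  # 1 .. -1
    phase = np.arccos(depth) / np.pi  # 0 .. 1
    return phase * period_s * (1.0 - 1e-12)


@dataclass
class Volume3D:
    """One volumetric frame, indexed ``(z, y, x)``, finite non-negative reals."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume3D data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Volume4D:
    """A time series of 3D volumes sharing one :class:`AcquisitionMeta`.

    ``data`` has layout ``(t, z, y, x)``; ``t0`` is the acquisition start
    time in seconds.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ShapeError(f"Volume4D data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ShapeError("Volume4D needs at least one frame")
        if self.meta.delay_map is not None and len(self.meta.delay_map) != self.data.shape[1]:
            raise ShapeError(
                f"delay_map length {len(self.meta.delay_map)} != z-depth {self.data.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.data[t], self.meta)

    @property
    def frames(self) -> list[Volume3D]:
        return [self.frame(t) for t in range(self.n_frames)]


@dataclass
class LabelMask:
    """Integer ROI label image: 0 = background, k > 0 = ROI id."""

    labels: np.ndarray
    names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError("LabelMask must be 3-D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("LabelMask labels must be non-negative")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# TIFF I/O


def read_stack(
    path: str | Path,
    z_depth: int | None = None,
    axis_order: str = "tzyx",
    meta: AcquisitionMeta | None = None,
) -> Volume4D:
    """Read a multi-page TIFF as a :class:`Volume4D`.

    A flat page series is folded into ``(t, z, y, x)`` using the declared
    ``z_depth`` and ``axis_order``; no axis inference is attempted.  With
    ``z_depth=None`` a 3-page-series file is read as a single volume (t=1).
    Integer pixel types are widened losslessly to float64.
    """
    if axis_order not in _AXIS_ORDERS:
        raise ValueError(f"axis_order must be one of {_AXIS_ORDERS}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # ragged pages, truncated file, not a TIFF
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        n_pages = arr.shape[0]
        if z_depth is None:
            arr = arr[None]  # single volume
        else:
            if n_pages % z_depth:
                raise ShapeError(
                    f"page count {n_pages} not divisible by declared z-depth {z_depth}"
                )
            if axis_order == "tzyx":
                arr = arr.reshape(n_pages // z_depth, z_depth, *arr.shape[1:])
            else:  # z-major pages: page = z * T + t
                arr = arr.reshape(z_depth, n_pages // z_depth, *arr.shape[1:])
                arr = arr.transpose(1, 0, 2, 3)
    elif arr.ndim == 4:
        if axis_order == "ztyx":
            arr = arr.transpose(1, 0, 2, 3)
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")
    if meta is None:
        meta = AcquisitionMeta(dz_um=1.0, volume_rate_hz=1.0, axis_order=axis_order,
                               rest_window=(0, max(1, arr.shape[0] // 4)))
    return Volume4D(arr.astype(np.float64), meta)


def write_stack(volume: Volume4D, path: str | Path, dtype: str | None = None) -> None:
    """Write a :class:`Volume4D` as a t-major, z-minor multi-page TIFF.

    ``dtype`` selects the sample format (``"uint16"`` or ``"float32"``; default
    ``float32``).  Requesting an integer format for data containing negative
    values raises :class:`RangeError`; integer data are written bit-exactly.
    """
    dt = np.dtype(dtype if dtype is not None else "float32")
    data = volume.data
    if np.issubdtype(dt, np.integer):
        if data.min() < 0:
            raise RangeError("negative values cannot be written with an integer sample format")
        if data.max() > np.iinfo(dt).max:
            raise RangeError(f"values exceed the {dt} range")
        out = np.rint(data).astype(dt)
    else:
        out = data.astype(dt)
    t, z, y, x = out.shape
    tifffile.imwrite(str(path), out.reshape(t * z, y, x), photometric="minisblack")


def read_labels(path: str | Path) -> LabelMask:
    """Read a 3D ROI label image stored as an integer multi-page TIFF."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMask(arr.astype(np.int64))


def write_labels(mask: LabelMask, path: str | Path) -> None:
    labels = mask.labels
    dt = np.uint16 if labels.max() < 2**16 else np.int32
    tifffile.imwrite(str(path), labels.astype(dt), photometric="minisblack")


# ---------------------------------------------------------------------------
# YAML config carrying AcquisitionMeta


def load_meta(path: str | Path, n_slices: int | None = None) -> AcquisitionMeta:
    """Load :class:`AcquisitionMeta` from a YAML config.

    The ``delay_map`` entry may be an explicit list of per-slice delays or a
    model name (``"linear"`` / ``"sinusoidal"``), in which case ``n_slices``
    must be supplied to expand it.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    dm = cfg.get("delay_map")
    if isinstance(dm, str):
        if n_slices is None:
            raise ValueError("n_slices required to expand a named delay model")
        period = 1.0 / float(cfg["volume_rate_hz"])
        builder = {"linear": linear_delay_map, "sinusoidal": sinusoidal_delay_map}[dm]
        dm = builder(n_slices, period)
    elif dm is not None:
        dm = np.asarray(dm, float)
    rw = cfg.get("rest_window", (0, 1))
    return AcquisitionMeta(
        dz_um=float(cfg["dz_um"]),
        volume_rate_hz=float(cfg["volume_rate_hz"]),
        delay_map=dm,
        axis_order=cfg.get("axis_order", "tzyx"),
        rest_window=(int(rw[0]), int(rw[1])),
    )


def save_meta(meta: AcquisitionMeta, path: str | Path) -> None:
    cfg = {
        "dz_um": float(meta.dz_um),
        "volume_rate_hz": float(meta.volume_rate_hz),
        "axis_order": meta.axis_order,
        "rest_window": [int(meta.rest_window[0]), int(meta.rest_window[1])],
    }
    if meta.delay_map is not None:
        cfg["delay_map"] = [float(d) for d in meta.delay_map]
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
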