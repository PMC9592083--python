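"""Core in-memory containers shared by every stage of the pipeline.

Conventions used throughout the package:

* axis order is ``(t, channel, z, y, x)`` for time-lapse volumes and
  ``(z, y, x)`` for single stacks and masks;
* voxel indices are 0-based; physical units are micrometres and seconds;
* a voxel's physical position is ``index * voxel_size`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "VolumeSeries",
    "Mask3D",
    "DistanceField",
    "KineticTrace",
    "Trajectory",
]


@dataclass
class VolumeSeries:
    """A multichannel 3D time lapse.

    Parameters
    ----------
    data
        Intensity grid indexed ``(t, channel, z, y, x)``, finite, >= 0.
    voxel_size
        Physical spacing ``(dz, dy, dx)`` in micrometres.
    frame_interval
        Seconds between consecutive stacks (30 s in the live assays this
        pipeline was built for).
    channel_names
        One name per channel, e.g. ``("antigen", "ftractin", "nucleus")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5:
            raise InvalidParameterError(
                f"expected (t, c, z, y, x) data, got ndim={self.data.ndim}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise InvalidParameterError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if not np.isfinite(self.data).all():
            raise InvalidParameterError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` sub-array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.data[:, idx]

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        dz, dy, dx = self.voxel_size
        return abs(dz - dx) <= rtol * dx and abs(dy - dx) <= rtol * dx


@dataclass
class Mask3D:
    """Boolean voxel grid sharing the geometry of its source volume."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    label: str = "object"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise InvalidParameterError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel_size must be positive")

    @property
    def volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return float(self.voxels.sum()) * dz * dy * dx

    def centroid_um(self) -> np.ndarray:
        """Physical (z, y, x) centroid of the mask in micrometres."""
        idx = np.argwhere(self.voxels)
        if idx.size == 0:
            raise InvalidParameterError("centroid of empty mask")
        return idx.mean(axis=0) * np.asarray(self.voxel_size)


@dataclass
class DistanceField:
    """Euclidean distance (um) from each voxel to a source mask.

    Zero on and inside the source; the field is 1-Lipschitz with respect
    to physical voxel distance.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    source_label: str = "droplet"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def at_position(self, position_um) -> float:
        """Field value at the voxel whose center is nearest to a physical point."""
        idx = np.round(np.asarray(position_um, float) / np.asarray(self.voxel_size)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.values.shape) - 1)
        return float(self.values[tuple(idx)])


@dataclass
class KineticTrace:
    """Time-stamped scalar series for a single cell (distance, enrichment, ...)."""

    times: np.ndarray
    values: np.ndarray
    metric_name: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be equal-length 1D arrays")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise InvalidParameterError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InvalidParameterError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise InvalidParameterError("trace too short to define a frame interval")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray) -> "KineticTrace":
        return KineticTrace(self.times.copy(), np.asarray(values, float),
                            self.metric_name, self.cell_id)


@dataclass
class Trajectory:
    """2D migration track: uniform timestamps (s) and positions (um)."""

    times: np.ndarray
    positions: np.ndarray
    cell_id: str = ""
    short_flag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must be (n, 2)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise InvalidParameterError("times and positions length mismatch")
        if len(self.times) < 2:
            raise InvalidParameterError("a trajectory needs at least 2 points")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidParameterError("trajectory sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    @property
    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive points, shape (n-1, 2)."""
        return np.diff(self.positions, axis=0)
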