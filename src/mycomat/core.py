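"""Core value types and exceptions shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MycomatError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(MycomatError):
    """Invalid configuration or parameters."""


class GeometryError(MycomatError):
    """Requested geometry is infeasible (e.g. radius larger than volume)."""


class DegenerateHistogramError(MycomatError):
    """Grey-level histogram has fewer distinct values than requested classes."""


class NoSubstrateError(MycomatError):
    """No substrate voxels found; reference surface undefined."""


class NoHyphaeError(MycomatError):
    """Empty hyphal mask/skeleton where a non-empty one is required."""


class InsufficientRangeError(MycomatError):
    """Measured curve does not span the evaluation point."""


class NoSteadyStateError(MycomatError):
    """No steady-state window found in a time series."""


class UnitError(MycomatError):
    """Inconsistent or missing unit tags."""


@dataclass
class VoxelVolume:
    """A 3D grayscale image with isotropic voxel size.

    Parameters
    ----------
    values:
        3D array of grey values (unsigned integer or real).
    voxel_size_um:
        Edge length of one (cubic) voxel in micrometres.
    slice_axis:
        Axis along which CT slices are indexed (default 0).
    provenance:
        Free-text description of where the volume came from.
    """

    values: np.ndarray
    voxel_size_um: float
    slice_axis: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConfigError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ConfigError(f"all dimensions must be >= 1, got {self.values.shape}")
        if not self.voxel_size_um > 0:
            raise ConfigError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.slice_axis not in (0, 1, 2):
            raise ConfigError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def iter_slices(self):
        """Yield 2D slices along ``slice_axis``."""
        for i in range(self.values.shape[self.slice_axis]):
            yield np.take(self.values, i, axis=self.slice_axis)


def moved_to_front(arr: np.ndarray, axis: int) -> np.ndarray:
    """View of ``arr`` with ``axis`` moved to position 0."""
    return np.moveaxis(arr, axis, 0)
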