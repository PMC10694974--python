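"""Grayscale CT segmentation of shive substrate and hyphal network.

Pipeline stages (composed by :func:`run_segmentation_pipeline`):

1. slice-wise non-local-means denoising + adaptive binarization, then
   multiplication of the binary mask with the grey volume (background -> 0);
2. multilevel Otsu classing of the remaining grey values;
3. shive extraction: brightest class, connected components, minimum-volume
   rule (default 140,000 um^3);
4. apparent substrate volume: per-slice disk closing + hole filling
   (fills the xylem-vessel channels);
5. solid fraction eps = V_solid / V_solid+pores and apparent density;
6. hyphae extraction: shives removed from the grey volume, single Otsu
   threshold, minimum-volume rule (default 280 um^3).

The adaptive threshold is the local Gaussian mean plus a sensitivity
offset, clamped from above by the global Otsu threshold so that interiors
of large bright objects survive (a plain local-mean rule would hollow
them out).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.restoration import denoise_nl_means

from .core import (
    ConfigError,
    DegenerateHistogramError,
    NoSubstrateError,
    VoxelVolume,
)
from .properties import DEFAULT_SOLID_DENSITY_KG_M3

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation pipeline.

    Size filters are expressed in um^3 and converted to voxel counts with
    the threshold rounded up (an object must strictly reach the count).
    ``connectivity`` is the 3D neighbourhood (6, 18 or 26) used for
    connected components. ``adaptive_3d`` switches the adaptive
    binarization from per-slice 2D to a full 3D local mean.
    """

    nlm_strength: float = 8.0
    nlm_patch_um: float = 4.5
    adaptive_window_um: float = 70.0
    adaptive_sensitivity: float = 0.05
    n_otsu_classes: int = 3
    shive_min_volume_um3: float = 140_000.0
    hyphae_min_volume_um3: float = 280.0
    closing_radius_um: float = 30.0
    connectivity: int = 26
    adaptive_3d: bool = False
    denoise: bool = True

    def __post_init__(self) -> None:
        if self.shive_min_volume_um3 <= 0 or self.hyphae_min_volume_um3 <= 0:
            raise ConfigError("minimum volumes must be positive")
        if self.n_otsu_classes < 2:
            raise ConfigError("n_otsu_classes must be >= 2")
        if self.closing_radius_um <= 0:
            raise ConfigError("closing_radius_um must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)

    def min_voxels(self, min_volume_um3: float, voxel_size_um: float) -> int:
        return int(math.ceil(min_volume_um3 / voxel_size_um**3))


@dataclass
class ShiveSegmentation:
    """Substrate segmentation result and bookkeeping volumes."""

    solid_mask: np.ndarray
    labels: np.ndarray
    voxel_size_um: float
    slice_axis: int = 0
    apparent_mask: np.ndarray | None = None
    epsilon_substrate: float | None = None
    apparent_density_kg_m3: float | None = None

    @property
    def V_solid_um3(self) -> float:
        return float(self.solid_mask.sum()) * self.voxel_size_um**3

    @property
    def V_solid_plus_pores_um3(self) -> float:
        if self.apparent_mask is None:
            raise NoSubstrateError("apparent mask not yet computed")
        return float(self.apparent_mask.sum()) * self.voxel_size_um**3


@dataclass
class HyphaeSegmentation:
    mask: np.ndarray
    voxel_size_um: float
    n_objects: int = 0
    otsu_threshold: float | None = None

    @property
    def V_hyphae_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size_um**3


@dataclass
class PipelineResult:
    shive: ShiveSegmentation
    hyphae: HyphaeSegmentation
    run_log: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.shive, self.hyphae))


# ---------------------------------------------------------------------------
# Stage 1: denoise + adaptive foreground masking
# ---------------------------------------------------------------------------

def preprocess_volume(
    vol: VoxelVolume, params: SegmentationParams, *, run_log: dict | None = None
) -> VoxelVolume:
    """Denoise slice-by-slice, binarize adaptively, multiply with the grey
    volume: background voxels become exactly 0, foreground keeps its
    (denoised) grey value."""
    values = np.asarray(vol.values, dtype=np.float32)
    axis = vol.slice_axis
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        out = np.zeros_like(values)
        if run_log is not None:
            run_log["preprocess"] = {"constant_volume": True}
        return VoxelVolume(out, vol.voxel_size_um, axis, vol.provenance + "|masked")

    window_vox = params.adaptive_window_um / vol.voxel_size_um
    slice_shape = tuple(s for i, s in enumerate(values.shape) if i != axis)
    if window_vox > min(slice_shape):
        raise ConfigError(
            f"adaptive window {params.adaptive_window_um} um = {window_vox:.0f} vox "
            f"exceeds the slice extent {slice_shape}"
        )

    moved = np.moveaxis(values, axis, 0)
    denoised = np.empty_like(moved)
    patch_size = max(3, int(round(params.nlm_patch_um / vol.voxel_size_um)) | 1)
    for i in range(moved.shape[0]):
        if params.denoise and params.nlm_strength > 0:
            denoised[i] = denoise_nl_means(
                moved[i],
                h=params.nlm_strength,
                patch_size=patch_size,
                patch_distance=2 * patch_size,
                fast_mode=True,
            )
        else:
            denoised[i] = moved[i]

    global_otsu = float(threshold_otsu(denoised.ravel()))
    offset = params.adaptive_sensitivity * (vmax - vmin)
    sigma = window_vox / 4.0
    binary = np.empty(moved.shape, dtype=bool)
    if params.adaptive_3d:
        local = ndimage.gaussian_filter(denoised, sigma=sigma)
        binary = denoised > np.minimum(local + offset, global_otsu)
    else:
        for i in range(moved.shape[0]):
            local = ndimage.gaussian_filter(denoised[i], sigma=sigma)
            binary[i] = denoised[i] > np.minimum(local + offset, global_otsu)

    masked = np.where(binary, denoised, 0.0).astype(np.float32)
    masked = np.moveaxis(masked, 0, axis)
    if run_log is not None:
        run_log["preprocess"] = {
            "global_otsu": global_otsu,
            "adaptive_offset": float(offset),
            "nlm_strength": params.nlm_strength if params.denoise else 0.0,
            "patch_size_vox": patch_size,
            "foreground_voxels": int(binary.sum()),
        }
    return VoxelVolume(masked, vol.voxel_size_um, axis, vol.provenance + "|masked")


# ---------------------------------------------------------------------------
# Stage 2: multilevel Otsu classes
# ---------------------------------------------------------------------------

def multilevel_classes(
    masked: VoxelVolume, params: SegmentationParams, *, run_log: dict | None = None
) -> np.ndarray:
    """Assign each nonzero voxel one of ``n_otsu_classes`` ordered classes
    (1 .. n, brightest = n); zero voxels keep class 0.

    Thresholds are computed over nonzero voxels only. Raises
    :class:`DegenerateHistogramError` when there are fewer distinct
    nonzero values than classes.
    """
    values = masked.values
    nonzero = values != 0
    fg = values[nonzero]
    n = params.n_otsu_classes
    if fg.size == 0 or np.unique(fg).size < n:
        raise DegenerateHistogramError(
            f"need >= {n} distinct nonzero grey values, got "
            f"{0 if fg.size == 0 else np.unique(fg).size}"
        )
    try:
        thresholds = threshold_multiotsu(fg, classes=n)
    except ValueError as exc:  # pragma: no cover - histogram edge cases
        raise DegenerateHistogramError(str(exc)) from exc
    classes = np.zeros(values.shape, dtype=np.uint8)
    classes[nonzero] = np.digitize(values[nonzero], thresholds) + 1
    if run_log is not None:
        run_log["multilevel"] = {"otsu_thresholds": [float(t) for t in thresholds]}
    return classes


# ---------------------------------------------------------------------------
# Stage 3: shive extraction by the minimum-volume rule
# ---------------------------------------------------------------------------

def extract_shive_mask(
    classes: np.ndarray,
    vol: VoxelVolume,
    params: SegmentationParams,
    *,
    run_log: dict | None = None,
) -> ShiveSegmentation:
    """Brightest class, connected components, keep components whose volume
    reaches ``shive_min_volume_um3``."""
    if not classes.any():
        return ShiveSegmentation(
            solid_mask=np.zeros(classes.shape, dtype=bool),
            labels=np.zeros(classes.shape, dtype=np.int32),
            voxel_size_um=vol.voxel_size_um,
            slice_axis=vol.slice_axis,
        )
    bright = classes == params.n_otsu_classes
    labeled, n_comp = ndimage.label(bright, structure=params.structure())
    min_vox = params.min_voxels(params.shive_min_volume_um3, vol.voxel_size_um)
    sizes = np.bincount(labeled.ravel())
    keep = np.nonzero(sizes >= min_vox)[0]
    keep = keep[keep != 0]
    solid = np.isin(labeled, keep)
    relabeled = np.zeros_like(labeled, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        relabeled[labeled == old] = new
    if run_log is not None:
        run_log["shive"] = {
            "components_total": int(n_comp),
            "components_kept": int(keep.size),
            "min_voxels": int(min_vox),
        }
    return ShiveSegmentation(
        solid_mask=solid,
        labels=relabeled,
        voxel_size_um=vol.voxel_size_um,
        slice_axis=vol.slice_axis,
    )


# ---------------------------------------------------------------------------
# Stage 4: apparent volume (closing + vessel filling per slice)
# ---------------------------------------------------------------------------

def _disk_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean dilation of a 2D mask by ``radius`` voxels (EDT-based)."""
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def _disk_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius


def _disk_close_and_fill(slice_mask: np.ndarray, radius: float) -> np.ndarray:
    pad = int(math.ceil(radius)) + 1
    padded = np.pad(slice_mask, pad, constant_values=False)
    closed = _disk_erode(_disk_dilate(padded, radius), radius)
    filled = ndimage.binary_fill_holes(closed)
    return filled[pad:-pad, pad:-pad]


def compute_apparent_mask(
    shive: ShiveSegmentation,
    params: SegmentationParams,
    *,
    run_log: dict | None = None,
) -> ShiveSegmentation:
    """Per-slice disk closing (radius ``closing_radius_um``) followed by
    hole filling; fills the vessel channels so the apparent mask bounds
    solid plus pores. Guarantees solid_mask is a subset."""
    radius_vox = params.closing_radius_um / shive.voxel_size_um
    axis = shive.slice_axis
    slice_shape = tuple(
        s for i, s in enumerate(shive.solid_mask.shape) if i != axis
    )
    if radius_vox >= min(slice_shape):
        raise ConfigError(
            f"closing radius {params.closing_radius_um} um >= slice extent"
        )
    moved = np.moveaxis(shive.solid_mask, axis, 0)
    apparent = np.empty_like(moved)
    for i in range(moved.shape[0]):
        apparent[i] = _disk_close_and_fill(moved[i], radius_vox)
    apparent = np.moveaxis(apparent, 0, axis) | shive.solid_mask
    shive.apparent_mask = apparent
    if run_log is not None:
        run_log["apparent"] = {
            "closing_radius_vox": float(radius_vox),
            "apparent_voxels": int(apparent.sum()),
        }
    return shive


# ---------------------------------------------------------------------------
# Stage 5: solid fraction
# ---------------------------------------------------------------------------

def shive_solid_fraction(
    shive: ShiveSegmentation,
    solid_density_kg_m3: float = DEFAULT_SOLID_DENSITY_KG_M3,
) -> tuple[float, float]:
    """eps = V_solid / V_solid+pores from voxel counts; apparent density
    is eps times the solid material density."""
    if shive.apparent_mask is None or not shive.apparent_mask.any():
        raise NoSubstrateError("apparent mask empty: no substrate to measure")
    n_solid = int(shive.solid_mask.sum())
    n_apparent = int(shive.apparent_mask.sum())
    eps = n_solid / n_apparent
    shive.epsilon_substrate = eps
    shive.apparent_density_kg_m3 = eps * solid_density_kg_m3
    return eps, shive.apparent_density_kg_m3


# ---------------------------------------------------------------------------
# Stage 6: hyphae extraction
# ---------------------------------------------------------------------------

def extract_hyphae_mask(
    vol: VoxelVolume,
    shive: ShiveSegmentation,
    params: SegmentationParams,
    *,
    run_log: dict | None = None,
) -> HyphaeSegmentation:
    """Remove shives from the grey volume, single-Otsu the remainder to
    separate hyphae from background, drop objects below
    ``hyphae_min_volume_um3``."""
    values = np.asarray(vol.values, dtype=np.float32).copy()
    values[shive.solid_mask] = 0.0
    remainder = values[~shive.solid_mask]
    if remainder.size == 0 or np.unique(remainder).size < 2:
        warnings.warn("remainder is uniform; returning empty hyphae mask", stacklevel=2)
        return HyphaeSegmentation(
            mask=np.zeros(values.shape, dtype=bool), voxel_size_um=vol.voxel_size_um
        )
    thr = float(threshold_otsu(remainder))
    mask = (values > thr) & ~shive.solid_mask
    min_vox = params.min_voxels(params.hyphae_min_volume_um3, vol.voxel_size_um)
    labeled, _ = ndimage.label(mask, structure=params.structure())
    sizes = np.bincount(labeled.ravel())
    keep = np.nonzero(sizes >= min_vox)[0]
    keep = keep[keep != 0]
    mask = np.isin(labeled, keep)
    if run_log is not None:
        run_log["hyphae"] = {
            "otsu_threshold": thr,
            "min_voxels": int(min_vox),
            "objects_kept": int(keep.size),
        }
    return HyphaeSegmentation(
        mask=mask,
        voxel_size_um=vol.voxel_size_um,
        n_objects=int(keep.size),
        otsu_threshold=thr,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_segmentation_pipeline(
    vol: VoxelVolume,
    params: SegmentationParams | None = None,
    solid_density_kg_m3: float = DEFAULT_SOLID_DENSITY_KG_M3,
) -> PipelineResult:
    """Compose all stages; deterministic for fixed inputs.

    An (effectively) empty volume yields empty segmentations instead of an
    error. The run log records every threshold actually used.
    """
    params = params or SegmentationParams()
    run_log: dict = {
        "voxel_size_um": vol.voxel_size_um,
        "shape": list(vol.shape),
        "slice_axis": vol.slice_axis,
    }
    masked = preprocess_volume(vol, params, run_log=run_log)
    empty = not (masked.values != 0).any() or np.unique(
        masked.values[masked.values != 0]
    ).size < params.n_otsu_classes
    if empty:
        logger.warning("volume is empty/degenerate after masking; empty result")
        run_log["empty"] = True
        shape = vol.shape
        shive = ShiveSegmentation(
            solid_mask=np.zeros(shape, dtype=bool),
            labels=np.zeros(shape, dtype=np.int32),
            voxel_size_um=vol.voxel_size_um,
            slice_axis=vol.slice_axis,
            apparent_mask=np.zeros(shape, dtype=bool),
        )
        hyphae = HyphaeSegmentation(
            mask=np.zeros(shape, dtype=bool), voxel_size_um=vol.voxel_size_um
        )
        return PipelineResult(shive, hyphae, run_log)

    classes = multilevel_classes(masked, params, run_log=run_log)
    shive = extract_shive_mask(classes, vol, params, run_log=run_log)
    if shive.solid_mask.any():
        compute_apparent_mask(shive, params, run_log=run_log)
        eps, rho = shive_solid_fraction(shive, solid_density_kg_m3)
        run_log["solid_fraction"] = {
            "epsilon_substrate": eps,
            "apparent_density_kg_m3": rho,
        }
    else:
        shive.apparent_mask = np.zeros(vol.shape, dtype=bool)
        run_log["solid_fraction"] = None
    hyphae = extract_hyphae_mask(vol, shive, params, run_log=run_log)
    assert not (hyphae.mask & shive.solid_mask).any(), "mask disjointness violated"
    assert (shive.solid_mask <= shive.apparent_mask).all(), "solid not in apparent"
    return PipelineResult(shive, hyphae, run_log)
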