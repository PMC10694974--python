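"""File I/O: TIFF volumes with YAML sidecars, CSV records, JSON results.

Voxel size is mandatory metadata. It is never inferred from TIFF tags
(tags are unreliable across CT exports): a volume without a sidecar (or
an explicit override) cannot be loaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ConfigError, VoxelVolume
from .morphometry import HyphalSummary, ShellProfile
from .properties import (
    BoardGeometry,
    StressStrainCurve,
    VapourSeries,
)


def _sidecar_path(volume_path: Path) -> Path:
    return volume_path.with_suffix(volume_path.suffix + ".yaml")


def read_volume(
    path: str | Path,
    sidecar: str | Path | None = None,
    *,
    voxel_size_um: float | None = None,
    slice_axis: int | None = None,
) -> VoxelVolume:
    """Load a multi-page TIFF stack; metadata comes from the YAML sidecar
    (default ``<path>.yaml``) or the explicit overrides.

    Raises :class:`ConfigError` when no voxel size is available.
    """
    path = Path(path)
    values = tifffile.imread(path)
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if voxel_size_um is None:
        voxel_size_um = meta.get("voxel_size_um")
    if voxel_size_um is None:
        raise ConfigError(
            f"no voxel size for {path}: provide a sidecar with 'voxel_size_um' "
            "or pass voxel_size_um explicitly"
        )
    if slice_axis is None:
        slice_axis = int(meta.get("slice_axis", 0))
    return VoxelVolume(
        values=values,
        voxel_size_um=float(voxel_size_um),
        slice_axis=slice_axis,
        provenance=str(path),
    )


def write_volume(vol: VoxelVolume, path: str | Path, *, sidecar: bool = True) -> Path:
    """Write a volume as a multi-page TIFF (pages along ``slice_axis``)
    plus a YAML sidecar with the voxel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(vol.values, vol.slice_axis, 0)
    tifffile.imwrite(path, pages)
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(
                {"voxel_size_um": float(vol.voxel_size_um), "slice_axis": 0}, fh
            )
    return path


def write_mask(
    mask: np.ndarray, path: str | Path, voxel_size_um: float, slice_axis: int = 0
) -> Path:
    """Write a binary mask as an 8-bit TIFF stack with values 0/255."""
    vol = VoxelVolume(
        (np.asarray(mask, bool) * np.uint8(255)), voxel_size_um, slice_axis
    )
    return write_volume(vol, path)


def read_mask(path: str | Path, **kwargs) -> tuple[np.ndarray, float]:
    vol = read_volume(path, **kwargs)
    return vol.values > 0, vol.voxel_size_um


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def load_stress_strain_csv(
    path: str | Path, A0_mm2: float, d0_mm: float, **kwargs
) -> StressStrainCurve:
    """Read a ``displacement_mm,force_N`` CSV into a curve record."""
    df = pd.read_csv(path)
    return StressStrainCurve(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        A0_mm2=A0_mm2,
        d0_mm=d0_mm,
        **kwargs,
    )


def save_stress_strain_csv(curve: StressStrainCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"displacement_mm": curve.displacement_mm, "force_N": curve.force_N}
    ).to_csv(path, index=False)
    return path


def load_vapour_series_csv(
    path: str | Path, sidecar: str | Path | None = None, **overrides
) -> VapourSeries:
    """Read a ``time_h,mass_g`` CSV; area/delta_p/thickness come from the
    YAML sidecar (default ``<path>.yaml``) or keyword overrides."""
    path = Path(path)
    df = pd.read_csv(path)
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    meta.update(overrides)
    missing = {"area_m2", "delta_p_Pa", "thickness_m"} - set(meta)
    if missing:
        raise ConfigError(f"vapour series metadata missing: {sorted(missing)}")
    return VapourSeries(
        time_h=df["time_h"].to_numpy(),
        mass_g=df["mass_g"].to_numpy(),
        area_m2=float(meta["area_m2"]),
        delta_p_Pa=float(meta["delta_p_Pa"]),
        thickness_m=float(meta["thickness_m"]),
        condition=meta.get("condition"),
    )


def save_vapour_series_csv(series: VapourSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_h": series.time_h, "mass_g": series.mass_g}).to_csv(
        path, index=False
    )
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {
                "area_m2": float(series.area_m2),
                "delta_p_Pa": float(series.delta_p_Pa),
                "thickness_m": float(series.thickness_m),
                "condition": series.condition,
            },
            fh,
        )
    return path


def save_bending_csv(rec, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"deflection_mm": rec.deflection_mm, "force_N": rec.force_N}
    ).to_csv(path, index=False)
    return path


def load_bending_csv(path: str | Path, geometry: BoardGeometry):
    from .properties import BendingRecord

    df = pd.read_csv(path)
    return BendingRecord(
        deflection_mm=df["deflection_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# Structured outputs + manifest
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: dict | None) -> str:
    """Stable SHA-256 of a configuration mapping."""
    payload = json.dumps(_jsonable(config or {}), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(
    results: dict,
    out_dir: str | Path,
    *,
    config: dict | None = None,
    seed: int | None = None,
    voxel_size_um: float | None = None,
) -> dict:
    """Write heterogeneous results to ``out_dir`` and return the manifest.

    Dispatch by value type: boolean/uint8 3D arrays -> TIFF masks,
    DataFrames and ShellProfiles -> CSV, dataclasses/dicts/scalars -> JSON.
    The manifest records artifact names, the config hash, the seed and
    library versions, and is itself written as ``manifest.json``.
    """
    import scipy
    import skimage

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    scalars: dict = {}
    for name, value in results.items():
        if isinstance(value, np.ndarray) and value.ndim == 3:
            if voxel_size_um is None:
                raise ConfigError("voxel_size_um required to write volume outputs")
            p = out_dir / f"{name}.tif"
            if value.dtype == bool:
                write_mask(value, p, voxel_size_um)
            else:
                write_volume(VoxelVolume(value, voxel_size_um), p)
            artifacts[name] = p.name
        elif isinstance(value, ShellProfile):
            p = out_dir / f"{name}.csv"
            value.to_dataframe().to_csv(p, index=False)
            artifacts[name] = p.name
        elif isinstance(value, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            value.to_csv(p, index=False)
            artifacts[name] = p.name
        elif isinstance(value, HyphalSummary):
            scalars[name] = value.to_dict()
        else:
            scalars[name] = _jsonable(value)
    if scalars:
        with open(out_dir / "results.json", "w") as fh:
            json.dump(scalars, fh, indent=2)
        artifacts["results"] = "results.json"
    manifest = {
        "artifacts": artifacts,
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {
            "mycomat": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
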