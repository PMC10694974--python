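"""Voxel phantoms: a porous shive slab plus a tubular hyphal network.

The phantom geometry is deliberately simple so that every derived
quantity has an exact, independently countable ground truth:

* the substrate is a slab at the bottom of the volume (axis 0), perforated
  by straight cylindrical channels of two radius classes drilled along
  axis 0 (so cross-sectional slices show enclosed circular pores);
* hyphae are grown as fixed-step persistent random walks seeded on the
  slab surface, with a distance-dependent Bernoulli branching rate
  r(dist) = r0 * exp(-dist / decay), then dilated to a tube radius.

Label codes: 0 background, 1 hypha, 2 shive solid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ..core import ConfigError, GeometryError, VoxelVolume

LABEL_BACKGROUND = 0
LABEL_HYPHA = 1
LABEL_SHIVE = 2


@dataclass
class PhantomConfig:
    """Parameters of the voxel phantom generator.

    ``vessel_radii_um`` are the (small, large) channel radius classes and
    ``vessel_class_counts`` their relative sampling weights during the
    iterative solid-fraction targeting. ``branch_rate_decay_um`` may be
    ``math.inf`` for a distance-independent branching rate.
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size_um: float = 1.41
    shive_slab_fraction: float = 0.25
    vessel_radii_um: tuple[float, float] = (7.5, 30.0)
    vessel_class_counts: tuple[int, int] = (3, 1)
    target_solid_fraction: float = 0.25
    hypha_radius_um: float = 1.44  # ~2.9 um diameter tube
    branch_rate_at_surface: float = 0.02  # branch points per um of hypha
    branch_rate_decay_um: float = 100.0
    hypha_length_budget_um: float = 20000.0
    class_means: tuple[float, float, float] = (20.0, 140.0, 220.0)
    noise_sd: float = 10.0
    seed: int = 0
    n_seed_hyphae: int = 25
    max_turn_deg: float = 30.0
    branch_angle_deg: float = 50.0

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ConfigError("voxel_size_um must be > 0")
        if not 0 < self.target_solid_fraction <= 1:
            raise ConfigError("target_solid_fraction must be in (0, 1]")
        if any(r < 0 for r in self.vessel_radii_um) or self.hypha_radius_um < 0:
            raise ConfigError("radii must be >= 0")
        m = self.class_means
        if not (m[0] < m[1] < m[2]):
            raise ConfigError(f"class means must be strictly ordered, got {m}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 < self.shive_slab_fraction <= 1:
            raise ConfigError("shive_slab_fraction must be in (0, 1]")
        if any(s < 1 for s in self.shape):
            raise ConfigError("zero-size volume")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    Coordinates are (axis0, axis1, axis2) voxel indices. ``labels`` uses
    the module label codes; ``apparent_shive_mask`` is the slab including
    its vessel channels.
    """

    labels: np.ndarray
    apparent_shive_mask: np.ndarray
    skeleton_voxels: np.ndarray  # (N, 3) int
    branch_points: np.ndarray  # (B, 3) int
    tips: np.ndarray  # (T, 3) int
    true_total_length_um: float
    true_diameter_um: float
    true_solid_fraction: float
    voxel_size_um: float
    segment_lengths_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    # per-event records (with multiplicity) for exact shell statistics:
    # skeleton_voxels/branch_points above are deduplicated coordinate sets
    step_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    branch_event_voxels: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), int)
    )

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError on violation."""
        n_total = self.labels.size
        counts = np.bincount(self.labels.ravel(), minlength=3)
        assert counts.sum() == n_total, "label codes not disjoint/exhaustive"
        n_apparent = int(self.apparent_shive_mask.sum())
        if n_apparent:
            solid = int((self.labels == LABEL_SHIVE).sum())
            assert abs(self.true_solid_fraction - solid / n_apparent) < 1e-12
        skel = {tuple(v) for v in self.skeleton_voxels}
        assert all(tuple(v) in skel for v in self.branch_points), "branch outside skeleton"
        assert all(tuple(v) in skel for v in self.tips), "tip outside skeleton"
        assert self.true_total_length_um >= 0


def _slab_thickness_vox(config: PhantomConfig) -> int:
    return max(1, int(round(config.shive_slab_fraction * config.shape[0])))


def generate_shive_phantom(
    config: PhantomConfig, seed: int | None = None, *, max_attempts: int = 10_000
) -> PhantomTruth:
    """Generate the porous slab substrate with exact solid-fraction truth.

    Channels are added one at a time (class sampled with weights
    ``vessel_class_counts``) until the achieved solid fraction is within
    0.02 of ``target_solid_fraction``. Raises :class:`GeometryError` when
    the target cannot be hit with the configured radii.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nz, ny, nx = config.shape
    thickness = _slab_thickness_vox(config)
    vox = config.voxel_size_um

    radii_vox = [r / vox for r in config.vessel_radii_um]
    target = config.target_solid_fraction
    tol = 0.02

    solid = np.zeros(config.shape, dtype=bool)
    solid[:thickness] = True
    apparent = solid.copy()
    n_apparent = int(apparent.sum())

    weights = np.asarray(config.vessel_class_counts, dtype=float)
    drill = target < 1.0 - tol and any(r > 0 for r in radii_vox)
    if drill:
        if weights.sum() <= 0:
            raise GeometryError("no vessel classes to drill but target < 1")
        weights = weights / weights.sum()
        r_max = max(radii_vox)
        if 2 * r_max >= min(ny, nx):
            raise GeometryError("largest vessel does not fit into the slab plane")
        yy, xx = np.mgrid[0:ny, 0:nx]
        plane_solid = np.ones((ny, nx), dtype=bool)
        for attempt in range(max_attempts):
            achieved = plane_solid.mean()  # channels are axis-0 prisms
            if abs(achieved - target) <= tol:
                break
            if achieved < target - tol:
                raise GeometryError(
                    f"overshot target solid fraction: {achieved:.3f} < {target} - {tol}"
                )
            # try classes from the sampled one downwards so a too-large
            # channel near the target falls back to the small class
            k = int(rng.choice(len(radii_vox), p=weights))
            order = sorted(range(len(radii_vox)), key=lambda i: (i != k, radii_vox[i]))
            placed = False
            would_fragment = False
            for cls in order:
                r = radii_vox[cls]
                if r <= 0:
                    continue
                # voxel indices run 0..n-1: keep the full disk strictly
                # inside so channels stay enclosed pores in cross-section
                cy = rng.uniform(r, (ny - 1) - r)
                cx = rng.uniform(r, (nx - 1) - r)
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
                removed = int((plane_solid & disk).sum())
                new_frac = (plane_solid.sum() - removed) / plane_solid.size
                if new_frac >= target - tol or removed == 0:
                    trial = plane_solid & ~disk
                    # substrate must stay one object: a shive fragmented by
                    # overlapping channels would be split by the downstream
                    # minimum-volume rule
                    if ndimage.label(trial)[1] > 1:
                        would_fragment = True
                        continue
                    plane_solid = trial
                    placed = True
                    break
            if not placed and not would_fragment:
                raise GeometryError(
                    "every remaining channel class overshoots the target"
                )
        else:
            raise GeometryError(
                f"could not reach solid fraction {target} in {max_attempts} attempts"
            )
        solid[:thickness] = plane_solid[None, :, :]

    labels = np.zeros(config.shape, dtype=np.uint8)
    labels[solid] = LABEL_SHIVE
    n_solid = int(solid.sum())
    frac = n_solid / n_apparent if n_apparent else 0.0
    return PhantomTruth(
        labels=labels,
        apparent_shive_mask=apparent,
        skeleton_voxels=np.empty((0, 3), dtype=int),
        branch_points=np.empty((0, 3), dtype=int),
        tips=np.empty((0, 3), dtype=int),
        true_total_length_um=0.0,
        true_diameter_um=2.0 * config.hypha_radius_um,
        true_solid_fraction=frac,
        voxel_size_um=vox,
    )


def _unit_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def _perturb_directions(
    rng: np.random.Generator, directions: np.ndarray, max_angle_rad: float
) -> np.ndarray:
    """Rotate each row of ``directions`` by a uniform angle in
    [0, max_angle] about a random perpendicular axis (vectorized)."""
    theta = rng.uniform(0.0, max_angle_rad, size=len(directions))[:, None]
    g = rng.normal(size=directions.shape)
    perp = np.cross(directions, g)
    norms = np.linalg.norm(perp, axis=1)
    bad = norms < 1e-12
    if bad.any():  # g parallel to dir: retry with a fixed offset
        perp[bad] = np.cross(directions[bad], directions[bad] + [0.5, 0.25, 0.125])
    perp = _unit_rows(perp)
    return _unit_rows(np.cos(theta) * directions + np.sin(theta) * perp)


def grow_hyphae_phantom(
    truth: PhantomTruth, config: PhantomConfig, seed: int | None = None
) -> PhantomTruth:
    """Grow the tubular hyphal network on top of a shive phantom.

    Fixed-step (one voxel) persistent random walk with bounded turning
    angle; per-step branching probability r(dist) * step_length, where
    dist is the distance to the apparent shive surface. Stops once the
    summed centerline length reaches ``hypha_length_budget_um``. Walkers
    die at the volume boundary or when entering shive solid; their last
    exterior voxel becomes a tip. Centerlines are then dilated to
    ``hypha_radius_um`` without overwriting shive-solid voxels.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vox = config.voxel_size_um
    shape = config.shape
    if config.hypha_radius_um / vox > max(shape):
        raise GeometryError("hypha radius exceeds the volume extent")

    labels = truth.labels.copy()
    solid = labels == LABEL_SHIVE
    # distance (um) from any exterior voxel to the apparent substrate
    dist_um = ndimage.distance_transform_edt(~truth.apparent_shive_mask) * vox

    budget = float(config.hypha_length_budget_um)
    step_um = vox
    skeleton: set[tuple[int, int, int]] = set()
    branch_pts: set[tuple[int, int, int]] = set()
    tips: list[tuple[int, int, int]] = []
    seg_lengths: list[float] = []
    step_vox: list[np.ndarray] = []
    branch_vox: list[np.ndarray] = []
    total_um = 0.0

    if budget >= step_um and config.n_seed_hyphae > 0:
        # seed points: exterior voxels just above the apparent surface
        surf_ax0 = int(_slab_thickness_vox(config))
        if surf_ax0 >= shape[0]:
            raise GeometryError("slab fills the volume; nowhere to grow hyphae")
        n0 = config.n_seed_hyphae
        pos = np.column_stack(
            [
                np.full(n0, float(surf_ax0)),
                rng.integers(0, shape[1], size=n0).astype(float),
                rng.integers(0, shape[2], size=n0).astype(float),
            ]
        )
        dirs = _unit_rows(
            np.column_stack([np.ones(n0), np.zeros(n0), np.zeros(n0)])
            + 0.5 * rng.normal(size=(n0, 3))
        )
        dirs[:, 0] = np.abs(dirs[:, 0]) + 1e-3
        dirs = _unit_rows(dirs)
        for v in np.round(pos).astype(int):
            skeleton.add(tuple(v))

        max_turn = math.radians(config.max_turn_deg)
        branch_angle = math.radians(config.branch_angle_deg)
        finite_decay = math.isfinite(config.branch_rate_decay_um)
        shape_arr = np.asarray(shape)

        # advance all alive walkers together; when the remaining budget
        # covers fewer steps than walkers, only the first k walkers move
        while budget - total_um >= step_um and len(pos) > 0:
            k = min(len(pos), int((budget - total_um) // step_um))
            dirs[:k] = _perturb_directions(rng, dirs[:k], max_turn)
            new_pos = pos[:k] + dirs[:k]
            v = np.round(new_pos).astype(int)
            inside = np.all((v >= 0) & (v < shape_arr), axis=1)
            hit_solid = np.zeros(k, dtype=bool)
            vi = v[inside]
            hit_solid[inside] = solid[vi[:, 0], vi[:, 1], vi[:, 2]]
            die = ~inside | hit_solid
            for w in np.round(pos[:k][die]).astype(int):
                tips.append(tuple(w))
            live = ~die
            n_step = int(live.sum())
            if n_step:
                pos[:k][live] = new_pos[live]
                vl = v[live]
                step_vox.append(vl.copy())
                for w in vl:
                    skeleton.add(tuple(w))
                total_um += n_step * step_um
                seg_lengths.extend([step_um] * n_step)
                if finite_decay:
                    rate = config.branch_rate_at_surface * np.exp(
                        -dist_um[vl[:, 0], vl[:, 1], vl[:, 2]]
                        / config.branch_rate_decay_um
                    )
                else:
                    rate = np.full(n_step, config.branch_rate_at_surface)
                branch = rng.random(n_step) < np.minimum(1.0, rate * step_um)
                if branch.any():
                    branch_vox.append(vl[branch].copy())
                    for w in vl[branch]:
                        branch_pts.add(tuple(w))
                    child_pos = new_pos[live][branch]
                    child_dirs = _perturb_directions(
                        rng, dirs[:k][live][branch], branch_angle
                    )
                else:
                    child_pos = np.empty((0, 3))
                    child_dirs = np.empty((0, 3))
            else:
                child_pos = np.empty((0, 3))
                child_dirs = np.empty((0, 3))
            keep = np.ones(len(pos), dtype=bool)
            keep[:k] = live
            pos = np.vstack([pos[keep], child_pos])
            dirs = np.vstack([dirs[keep], child_dirs])
        for w in np.round(pos).astype(int):
            tips.append(tuple(w))

    skel_arr = np.array(sorted(skeleton), dtype=int).reshape(-1, 3)
    if skel_arr.size:
        skel_mask = np.zeros(shape, dtype=bool)
        skel_mask[tuple(skel_arr.T)] = True
        tube = ndimage.distance_transform_edt(~skel_mask) * vox <= config.hypha_radius_um
        labels[tube & ~solid] = LABEL_HYPHA

    return replace(
        truth,
        labels=labels,
        skeleton_voxels=skel_arr,
        branch_points=np.array(sorted(branch_pts), dtype=int).reshape(-1, 3),
        tips=np.array(sorted(set(tips)), dtype=int).reshape(-1, 3),
        true_total_length_um=total_um,
        true_diameter_um=2.0 * config.hypha_radius_um,
        segment_lengths_um=np.asarray(seg_lengths),
        step_voxels=(
            np.vstack(step_vox) if step_vox else np.empty((0, 3), int)
        ),
        branch_event_voxels=(
            np.vstack(branch_vox) if branch_vox else np.empty((0, 3), int)
        ),
    )


def render_grayscale(
    truth: PhantomTruth, config: PhantomConfig, seed: int | None = None
) -> VoxelVolume:
    """Render the label volume to grey values: class mean + Gaussian noise,
    clipped to [0, 255]."""
    m = config.class_means
    if not (m[0] < m[1] < m[2]):
        raise ConfigError(f"class means must be strictly ordered, got {m}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means = np.array(m, dtype=np.float32)
    values = means[truth.labels]
    if config.noise_sd > 0:
        values = values + rng.normal(
            0.0, config.noise_sd, size=values.shape
        ).astype(np.float32)
    values = np.clip(values, 0.0, 255.0)
    return VoxelVolume(
        values=values.astype(np.float32),
        voxel_size_um=config.voxel_size_um,
        slice_axis=0,
        provenance="synthetic phantom render",
    )


def truth_shell_profile(
    truth: PhantomTruth,
    shell_width_um: float = 50.0,
    *,
    normalize: str = "per_length",
) -> dict[str, np.ndarray]:
    """Per-shell branch statistics computed directly from generator truth.

    Bins exterior skeleton voxels and branch points into concentric
    distance shells around the apparent substrate. ``normalize`` selects
    the branching-frequency convention: ``per_length`` divides each
    shell's branch count by the hyphal length in that shell; ``grand_total``
    divides by the total branch count.

    Returns arrays: shell inner/outer radii (um), branch_count,
    length_um, frequency.
    """
    if normalize not in ("per_length", "grand_total"):
        raise ConfigError(f"unknown normalization {normalize!r}")
    vox = truth.voxel_size_um
    dist_um = ndimage.distance_transform_edt(~truth.apparent_shive_mask) * vox
    # per-event records carry multiplicity (several steps/branch events can
    # share a voxel); fall back to the deduplicated sets when absent
    steps = truth.step_voxels if truth.step_voxels.size else truth.skeleton_voxels
    events = (
        truth.branch_event_voxels
        if truth.branch_event_voxels.size
        else truth.branch_points
    )
    if steps.size == 0:
        return {
            "r_inner_um": np.empty(0),
            "r_outer_um": np.empty(0),
            "branch_count": np.empty(0, dtype=int),
            "length_um": np.empty(0),
            "frequency": np.empty(0),
        }
    d_skel = dist_um[tuple(steps.T)]
    d_branch = dist_um[tuple(events.T)] if events.size else np.empty(0)
    n_shells = int(np.floor(d_skel.max() / shell_width_um)) + 1
    edges = np.arange(n_shells + 1) * shell_width_um
    skel_counts, _ = np.histogram(d_skel, bins=edges)
    branch_counts, _ = np.histogram(d_branch, bins=edges)
    length_um = skel_counts * vox
    with np.errstate(divide="ignore", invalid="ignore"):
        if normalize == "per_length":
            freq = np.where(length_um > 0, branch_counts / length_um, np.nan)
        else:
            total = branch_counts.sum()
            freq = branch_counts / total if total else np.full(n_shells, np.nan)
    return {
        "r_inner_um": edges[:-1],
        "r_outer_um": edges[1:],
        "branch_count": branch_counts,
        "length_um": length_um,
        "frequency": freq,
    }
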