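"""Synthetic mechanical/physical test records with closed-form truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import ConfigError
from ..properties import (
    BendingRecord,
    BoardGeometry,
    StressStrainCurve,
    VapourSeries,
)


@dataclass
class FoamModel:
    """Piecewise foam stress-strain law with a density-scaled modulus.

    Regions: a quadratic toe up to ``toe_strain`` (slope ramps 0 -> E),
    a linear elastic region up to ``yield_strain``, then a hardening
    plateau of slope ``hardening_kPa``. The elastic modulus scales
    linearly with density: E = modulus_ref_kPa * density / density_ref.
    """

    toe_strain: float = 0.02
    yield_strain: float = 0.30
    modulus_ref_kPa: float = 300.0
    density_ref_kg_m3: float = 80.0
    hardening_kPa: float = 20.0

    def modulus_kPa(self, density_kg_m3: float) -> float:
        return self.modulus_ref_kPa * density_kg_m3 / self.density_ref_kg_m3

    def stress_kPa(self, strain, density_kg_m3: float):
        """Closed-form stress (kPa) at the given strain(s); monotone
        non-decreasing in strain for non-negative parameters."""
        e = np.asarray(strain, dtype=float)
        E = self.modulus_kPa(density_kg_m3)
        et, ey = self.toe_strain, self.yield_strain
        toe = E * e**2 / (2.0 * et) if et > 0 else E * e
        lin = E * (e - et / 2.0)
        plat = E * (ey - et / 2.0) + self.hardening_kPa * (e - ey)
        out = np.where(e <= et, toe, np.where(e <= ey, lin, plat))
        return out if out.ndim else float(out)

    def sigma10_kPa(self, density_kg_m3: float) -> float:
        """Closed-form stress at 10% strain."""
        return float(self.stress_kPa(0.10, density_kg_m3))


def synth_compression_curve(
    density_kg_m3: float,
    model: FoamModel,
    seed: int = 0,
    *,
    A0_mm2: float = 10_000.0,
    d0_mm: float = 100.0,
    max_strain: float = 0.5,
    n_samples: int = 201,
    noise_rel: float = 0.0,
) -> StressStrainCurve:
    """Force-displacement samples of the foam model for one specimen.

    The displacement origin is already zeroed (``preload_applied=True``);
    multiplicative force noise is optional and off by default.
    """
    if density_kg_m3 <= 0:
        raise ConfigError("density must be positive")
    if A0_mm2 <= 0 or d0_mm <= 0:
        raise ConfigError("geometry must be positive")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_samples)
    stress = model.stress_kPa(strain, density_kg_m3)  # kPa
    force = stress * A0_mm2 / 1e3  # N  (sigma = 1e3 F / A0)
    if noise_rel > 0:
        force = force * (1.0 + noise_rel * rng.normal(size=force.shape))
    return StressStrainCurve(
        displacement_mm=strain * d0_mm,
        force_N=force,
        A0_mm2=A0_mm2,
        d0_mm=d0_mm,
        preload_applied=True,
        density_kg_m3=density_kg_m3,
    )


def synth_vapour_series(
    W_true_mg_per_m2_h_Pa: float,
    area_m2: float,
    delta_p_Pa: float,
    thickness_m: float,
    n_points: int = 20,
    noise_sd_g: float = 0.0,
    seed: int = 0,
    *,
    m0_g: float = 500.0,
    t_end_h: float = 72.0,
    condition: str | None = None,
) -> VapourSeries:
    """Linear cup-method mass-gain series with known transmittance.

    mass(t) = m0 + W_true * area * delta_p * t (+ Gaussian noise);
    W_true in mg (m^2 h Pa)^-1, masses in g, time in h.
    """
    if not (W_true_mg_per_m2_h_Pa > 0 and area_m2 > 0 and delta_p_Pa > 0):
        raise ConfigError("physical quantities must be positive")
    if not thickness_m > 0:
        raise ConfigError("thickness must be positive")
    if n_points < 3:
        raise ConfigError("need at least 3 points")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end_h, n_points)
    slope_g_per_h = W_true_mg_per_m2_h_Pa * 1e-3 * area_m2 * delta_p_Pa
    mass = m0_g + slope_g_per_h * t
    if noise_sd_g > 0:
        mass = mass + rng.normal(0.0, noise_sd_g, size=mass.shape)
    return VapourSeries(
        time_h=t,
        mass_g=mass,
        area_m2=area_m2,
        delta_p_Pa=delta_p_Pa,
        thickness_m=thickness_m,
        condition=condition,
    )


def synth_bending_record(
    f_m_true_N_mm2: float,
    geometry: BoardGeometry,
    stiffness_N_per_mm: float,
    seed: int = 0,
    *,
    n_points: int = 100,
) -> BendingRecord:
    """Linear force-deflection ramp breaking at the force implied by the
    target flexural strength: F_max = f_m * 2 b t^2 / (3 l1); the force
    drops to zero after the break."""
    if stiffness_N_per_mm <= 0:
        raise ConfigError("stiffness must be positive")
    if f_m_true_N_mm2 < 0:
        raise ConfigError("flexural strength cannot be negative")
    g = geometry
    f_max = f_m_true_N_mm2 * 2.0 * g.b_mm * g.t_mm**2 / (3.0 * g.l1_mm)
    a_break = f_max / stiffness_N_per_mm
    if f_max == 0:
        defl = np.linspace(0.0, 1.0, n_points)
        force = np.zeros(n_points)
    else:
        defl_ramp = np.linspace(0.0, a_break, n_points)
        force_ramp = stiffness_N_per_mm * defl_ramp
        defl = np.concatenate([defl_ramp, [a_break * 1.01, a_break * 1.05]])
        force = np.concatenate([force_ramp, [0.0, 0.0]])
    return BendingRecord(deflection_mm=defl, force_N=force, geometry=g)
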