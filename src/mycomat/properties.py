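"""EN-norm material-property calculations for mycelium-composite specimens.

Covers compression (stress at 10% strain), three-point bending (flexural
strength, modulus of elasticity), transverse tension, raw density, water
soak (thickness swell, absorption), cup-method vapour diffusion, guarded
two-plate thermal conductivity, and the small-flame flammability classing
rules.

Unit conventions follow the test norms: forces in N, lengths in mm unless
a field name says otherwise, masses in g, times in h, pressures in Pa,
stresses in kPa (compression) or N mm^-2 (boards). Every result type tags
its units in the field names; converters are explicit, never implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConfigError,
    InsufficientRangeError,
    NoSteadyStateError,
    UnitError,
)

#: Partial vapour-pressure difference (Pa) for the named standard test
#: conditions of the cup method (23 degC; humidity pairs per condition).
STANDARD_VAPOUR_CONDITIONS_PA: dict[str, float] = {"A": 1400.0, "B": 2390.0, "C": 1210.0}

#: Vapour diffusion conductivity of still air, mg (m h Pa)^-1, at 23 degC.
#: The alternative value 0.707 is selectable (see ``vapour_coefficients``).
DELTA_AIR_DEFAULT_MG_M_H_PA = 0.72
DELTA_AIR_ALTERNATIVE_MG_M_H_PA = 0.707

DEFAULT_SOLID_DENSITY_KG_M3 = 1450.0


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class StressStrainCurve:
    """Raw force-displacement record of a compression test.

    ``displacement_mm`` and ``force_N`` are parallel sample arrays ordered
    by displacement. ``A0_mm2`` is the initial loaded cross-section and
    ``d0_mm`` the initial specimen height. ``preload_N`` is the machine
    preload; set ``preload_applied=True`` when the displacement origin has
    already been zeroed at the preload crossing.
    """

    displacement_mm: np.ndarray
    force_N: np.ndarray
    A0_mm2: float
    d0_mm: float
    preload_N: float = 20.0
    preload_applied: bool = True
    crosshead_speed_mm_min: float | None = None
    density_kg_m3: float | None = None

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.displacement_mm.shape != self.force_N.shape:
            raise ConfigError("displacement and force arrays must have equal length")
        if self.displacement_mm.ndim != 1:
            raise ConfigError("samples must be 1D arrays")
        if np.any(np.diff(self.displacement_mm) < 0):
            raise ConfigError("samples must be ordered by displacement")
        if not (self.A0_mm2 > 0 and self.d0_mm > 0):
            raise ConfigError("A0_mm2 and d0_mm must be positive")

    @property
    def strain_pct(self) -> np.ndarray:
        """Engineering strain in percent: X / d0 * 100."""
        return self.displacement_mm / self.d0_mm * 100.0

    @property
    def stress_kPa(self) -> np.ndarray:
        """Compressive stress in kPa: 10^3 * F / A0 (F in N, A0 in mm^2)."""
        return 1e3 * self.force_N / self.A0_mm2


@dataclass
class CompressionResult:
    sigma10_kPa: float
    sigma_max_kPa: float
    strain_at_max_pct: float


@dataclass
class BoardGeometry:
    """Specimen geometry for board testing.

    ``t_N`` nominal thickness, ``a``/``b`` specimen length/width, ``t``
    measured thickness, ``l1`` bearing span, ``l2`` specimen length, all mm.
    """

    t_N_mm: float
    a_mm: float
    b_mm: float
    t_mm: float
    l1_mm: float
    l2_mm: float

    def __post_init__(self) -> None:
        for name in ("a_mm", "b_mm", "t_mm", "l1_mm", "l2_mm"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class BendingRecord:
    """Force-deflection record of a three-point bending test."""

    deflection_mm: np.ndarray
    force_N: np.ndarray
    geometry: BoardGeometry

    def __post_init__(self) -> None:
        self.deflection_mm = np.asarray(self.deflection_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.deflection_mm.shape != self.force_N.shape:
            raise ConfigError("deflection and force arrays must have equal length")


@dataclass
class TensileRecord:
    F_max_N: float
    a_mm: float
    b_mm: float


@dataclass
class SoakRecord:
    """Thickness/mass before (1) and after (2) a 24 h water bath."""

    t1_mm: float
    t2_mm: float
    m1_g: float
    m2_g: float


@dataclass
class DensityRecord:
    m_g: float
    a_mm: float
    b_mm: float
    t_mm: float


@dataclass
class VapourSeries:
    """Cup-method mass-gain series: mass of the installation over time.

    ``time_h`` strictly increasing, ``mass_g`` the balance readings.
    ``area_m2`` is the open test surface, ``delta_p_Pa`` the partial
    vapour-pressure difference, ``thickness_m`` the specimen thickness.
    ``condition`` optionally names a standard condition (A/B/C), in which
    case ``delta_p_Pa`` must match the tabulated value.
    """

    time_h: np.ndarray
    mass_g: np.ndarray
    area_m2: float
    delta_p_Pa: float
    thickness_m: float
    condition: str | None = None
    units: tuple[str, str] = ("h", "g")

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if self.units != ("h", "g"):
            raise UnitError(f"VapourSeries requires (h, g) units, got {self.units}")
        if self.time_h.shape != self.mass_g.shape or self.time_h.ndim != 1:
            raise ConfigError("time and mass must be equal-length 1D arrays")
        if np.any(np.diff(self.time_h) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        if not (self.area_m2 > 0 and self.delta_p_Pa > 0 and self.thickness_m > 0):
            raise ConfigError("area, delta_p and thickness must be positive")
        if self.condition is not None:
            expected = STANDARD_VAPOUR_CONDITIONS_PA.get(self.condition)
            if expected is None:
                raise ConfigError(f"unknown standard condition {self.condition!r}")
            if abs(self.delta_p_Pa - expected) > 1e-9:
                raise UnitError(
                    f"condition {self.condition} requires delta_p = {expected} Pa, "
                    f"got {self.delta_p_Pa}"
                )


@dataclass
class VapourCoefficients:
    """Vapour diffusion coefficient chain, unit-tagged in the field names.

    G: periodic mass change (slope of the steady-state fit), g h^-1.
    g: diffusion current density, g (m^2 h)^-1.
    W: diffusion transmittance, mg (m^2 h Pa)^-1.
    delta: diffusion conductivity, mg (m h Pa)^-1.
    mu: dimensionless resistance coefficient, delta_air / delta.
    """

    G_g_per_h: float
    g_g_per_m2_h: float
    W_mg_per_m2_h_Pa: float
    delta_mg_per_m_h_Pa: float
    mu: float
    delta_air_mg_per_m_h_Pa: float
    steady_state_points: int
    r_squared: float


@dataclass
class ConductivityRecord:
    """Guarded two-plate measurement: heat flux, geometry, plate temperatures."""

    phi_W: float
    d_m: float
    A_m2: float
    T1_K: float
    T2_K: float


@dataclass
class FlammabilityObservation:
    """Small-flame test observation used by the rule-based classifier."""

    flame_spread_mm_at_60s: float
    horizontal_spread: bool
    burning_droplets: bool
    smoke_class: str
    flaming_time_s: float

    def __post_init__(self) -> None:
        if self.smoke_class not in ("s1", "s2", "s3"):
            raise ConfigError(f"smoke_class must be s1/s2/s3, got {self.smoke_class!r}")
        if self.flame_spread_mm_at_60s < 0:
            raise ConfigError("flame spread cannot be negative")


@dataclass
class FlammabilityResult:
    label: str
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Calculations
# ---------------------------------------------------------------------------

def compute_compression(
    curve: StressStrainCurve, *, zero_at_preload: bool = False
) -> CompressionResult:
    """Evaluate a compression curve: stress at 10% strain and the maximum.

    Stress is 10^3 * F / A0 [kPa], strain is X / d0 * 100 [%]. sigma10 is
    obtained by linear interpolation between the samples bracketing 10%
    strain. With ``zero_at_preload`` the displacement origin is shifted to
    the point where the force first crosses ``curve.preload_N``.
    """
    disp = curve.displacement_mm.copy()
    force = curve.force_N
    if zero_at_preload:
        if curve.preload_applied:
            warnings.warn("curve flagged preload_applied; zeroing again", stacklevel=2)
        above = np.nonzero(force >= curve.preload_N)[0]
        if above.size == 0:
            raise InsufficientRangeError("curve never reaches the preload")
        i = above[0]
        if i == 0:
            x_p = disp[0]
        else:
            f0, f1 = force[i - 1], force[i]
            x_p = np.interp(curve.preload_N, [f0, f1], [disp[i - 1], disp[i]])
        disp = disp - x_p
    elif not curve.preload_applied:
        warnings.warn(
            "preload offset neither applied nor requested; strains include the toe",
            stacklevel=2,
        )

    strain = disp / curve.d0_mm * 100.0
    stress = 1e3 * force / curve.A0_mm2
    if strain.size == 0 or strain[-1] < 10.0:
        raise InsufficientRangeError(
            f"curve ends at {0.0 if strain.size == 0 else strain[-1]:.2f}% strain, "
            "below the 10% evaluation point"
        )
    sigma10 = float(np.interp(10.0, strain, stress))
    i_max = int(np.argmax(stress))
    return CompressionResult(
        sigma10_kPa=sigma10,
        sigma_max_kPa=float(stress[i_max]),
        strain_at_max_pct=float(strain[i_max]),
    )


def board_geometry(
    t_N_mm: float, *, b_mm: float = 50.0, t_mm: float | None = None
) -> BoardGeometry:
    """Derive board-test specimen geometry from the nominal thickness.

    a = 20 * t_N + 50 and l1 = 20 * t_N (both mm); l2 defaults to a.
    """
    if t_N_mm < 0:
        raise ConfigError("nominal thickness cannot be negative")
    a = 20.0 * t_N_mm + 50.0
    l1 = 20.0 * t_N_mm
    return BoardGeometry(
        t_N_mm=t_N_mm,
        a_mm=a,
        b_mm=b_mm,
        t_mm=t_mm if t_mm is not None else max(t_N_mm, 1e-9),
        l1_mm=l1 if l1 > 0 else 1e-9,
        l2_mm=a,
    )


def flexural_strength(rec: BendingRecord) -> float:
    """f_m = 3 * F_max * l1 / (2 * b * t^2) in N mm^-2."""
    g = rec.geometry
    if not (g.b_mm > 0 and g.t_mm > 0):
        raise ConfigError("width and thickness must be positive")
    f_max = float(np.max(rec.force_N)) if rec.force_N.size else 0.0
    return 3.0 * f_max * g.l1_mm / (2.0 * g.b_mm * g.t_mm**2)


def modulus_of_elasticity(rec: BendingRecord) -> float:
    """E_M = l1^3 * (F2 - F1) / (4 * b * t^3 * (a2 - a1)) in N mm^-2.

    F1/F2 are taken at exactly 10% / 40% of the breaking force F_max, with
    the matching deflections a1/a2 interpolated on the rising branch of the
    force-deflection record.
    """
    g = rec.geometry
    force = rec.force_N
    defl = rec.deflection_mm
    if force.size < 2:
        raise ConfigError("need at least two samples")
    i_max = int(np.argmax(force))
    f_max = float(force[i_max])
    if f_max <= 0:
        return 0.0
    rise_f = force[: i_max + 1]
    rise_a = defl[: i_max + 1]
    # monotone envelope of the rising branch so interpolation is well defined
    env = np.maximum.accumulate(rise_f)
    f1, f2 = 0.1 * f_max, 0.4 * f_max
    a1 = float(np.interp(f1, env, rise_a))
    a2 = float(np.interp(f2, env, rise_a))
    if a2 == a1:
        raise ConfigError("degenerate deflection: a2 equals a1")
    return g.l1_mm**3 * (f2 - f1) / (4.0 * g.b_mm * g.t_mm**3 * (a2 - a1))


def transverse_tensile_strength(rec: TensileRecord) -> float:
    """f_t = F_max / (a * b) in N mm^-2."""
    if not (rec.a_mm > 0 and rec.b_mm > 0):
        raise ConfigError("specimen area must be positive")
    return rec.F_max_N / (rec.a_mm * rec.b_mm)


def raw_density(rec: DensityRecord) -> float:
    """rho = m / (a * b * t) * 10^6 in kg m^-3 (m in g, dimensions in mm)."""
    vol = rec.a_mm * rec.b_mm * rec.t_mm
    if not vol > 0:
        raise ConfigError("specimen volume must be positive")
    return rec.m_g / vol * 1e6


def soak_metrics(rec: SoakRecord) -> tuple[float, float]:
    """Thickness swell G_t and water absorption W_t, both in percent."""
    if not rec.t1_mm > 0:
        raise ConfigError("initial thickness must be positive")
    if not rec.m1_g > 0:
        raise ConfigError("initial mass must be positive")
    g_t = (rec.t2_mm - rec.t1_mm) / rec.t1_mm * 100.0
    w_t = (rec.m2_g - rec.m1_g) / rec.m1_g * 100.0
    return g_t, w_t


def _steady_state_fit(
    time_h: np.ndarray, mass_g: np.ndarray, r2_threshold: float, min_points: int
) -> tuple[float, int, float]:
    """Longest trailing window whose linear fit has R^2 >= threshold.

    Returns (slope g/h, number of points, R^2). Searches from the full
    series down to ``min_points``; a perfectly linear series uses all
    points. Constant-mass series fit with slope 0 and R^2 of 1 by
    convention (zero residuals).
    """
    n = time_h.size
    best = None
    for start in range(0, n - min_points + 1):
        t, m = time_h[start:], mass_g[start:]
        slope, intercept = np.polyfit(t, m, 1)
        resid = m - (slope * t + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((m - m.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if r2 >= r2_threshold:
            best = (float(slope), n - start, r2)
            break  # earliest start => longest trailing window
    if best is None:
        raise NoSteadyStateError(
            f"no trailing window of >= {min_points} points reaches R^2 >= {r2_threshold}"
        )
    return best


def vapour_coefficients(
    series: VapourSeries,
    delta_air_mg_per_m_h_Pa: float = DELTA_AIR_DEFAULT_MG_M_H_PA,
    *,
    r2_threshold: float = 0.999,
    min_points: int = 3,
) -> VapourCoefficients:
    """Cup-method coefficient chain from a mass-gain series.

    G is the slope of the steady-state linear fit of mass vs time; then
    g = G/A, W = G/(A * delta_p), delta = W * d, mu = delta_air / delta.
    """
    if series.time_h.size < min_points:
        raise ConfigError(f"need at least {min_points} mass points")
    slope_g_h, n_pts, r2 = _steady_state_fit(
        series.time_h, series.mass_g, r2_threshold, min_points
    )
    G = slope_g_h                               # g h^-1
    g = G / series.area_m2                      # g m^-2 h^-1
    W = g / series.delta_p_Pa * 1e3             # mg m^-2 h^-1 Pa^-1
    delta = W * series.thickness_m              # mg m^-1 h^-1 Pa^-1
    if delta == 0:
        raise ConfigError("delta is zero; mu undefined")
    mu = delta_air_mg_per_m_h_Pa / delta
    return VapourCoefficients(
        G_g_per_h=G,
        g_g_per_m2_h=g,
        W_mg_per_m2_h_Pa=W,
        delta_mg_per_m_h_Pa=delta,
        mu=mu,
        delta_air_mg_per_m_h_Pa=delta_air_mg_per_m_h_Pa,
        steady_state_points=n_pts,
        r_squared=r2,
    )


def thermal_conductivity(rec: ConductivityRecord) -> float:
    """lambda = phi * d / (A * (T1 - T2)) in W (m K)^-1."""
    if rec.T1_K == rec.T2_K:
        raise ConfigError("zero temperature gradient")
    if not (rec.A_m2 > 0 and rec.d_m > 0):
        raise ConfigError("area and thickness must be positive")
    return rec.phi_W * rec.d_m / (rec.A_m2 * (rec.T1_K - rec.T2_K))


def classify_flammability(obs: FlammabilityObservation) -> FlammabilityResult:
    """Rule-based small-flame classification.

    Horizontal spread, or sustaining flaming only through the 15 s short
    test, yields class "E" (highly flammable). A specimen that sustains the
    30 s flaming, keeps vertical spread <= 150 mm at 60 s after test start
    and sheds no burning droplets is "B1", suffixed with the externally
    measured smoke class and the droplet class (d0 when none fell).
    Anything else is "unclassified" with the failed rules listed.
    """
    if obs.horizontal_spread or obs.flaming_time_s <= 15.0:
        return FlammabilityResult(
            label="E",
            reasons=(
                ["horizontal flame spread observed"]
                if obs.horizontal_spread
                else ["specimen failed within the 15 s flaming test"]
            ),
        )
    reasons: list[str] = []
    if obs.flaming_time_s < 30.0:
        reasons.append("30 s flaming not sustained")
    if obs.flame_spread_mm_at_60s > 150.0:
        reasons.append(
            f"vertical flame spread {obs.flame_spread_mm_at_60s:.0f} mm "
            "exceeds 150 mm at 60 s"
        )
    if obs.burning_droplets:
        reasons.append("burning droplets fell off")
    if reasons:
        return FlammabilityResult(label="unclassified", reasons=reasons)
    droplet_suffix = "d0" if not obs.burning_droplets else "d2"
    return FlammabilityResult(label=f"B1-{obs.smoke_class}-{droplet_suffix}")
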