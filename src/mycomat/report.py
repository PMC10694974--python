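"""Report figures: stress-strain families, property-vs-density scatters,
branching-frequency profiles, and a log-log stiffness/density map."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .morphometry import ShellProfile
from .properties import StressStrainCurve

logger = logging.getLogger(__name__)

DEFAULT_FORMATS = ("svg", "png")


def _save(fig, out_dir: Path, stem: str, formats) -> list[Path]:
    paths = []
    for ext in formats:
        p = out_dir / f"{stem}.{ext}"
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def plot_stress_strain(curves: list[StressStrainCurve], ax=None):
    ax = ax or plt.subplots()[1]
    for i, c in enumerate(curves):
        label = (
            f"{c.density_kg_m3:.0f} kg/m$^3$" if c.density_kg_m3 else f"specimen {i}"
        )
        ax.plot(c.strain_pct, c.stress_kPa, label=label)
    ax.set_xlabel("strain [%]")
    ax.set_ylabel("stress [kPa]")
    ax.legend(fontsize="small")
    return ax


def plot_property_vs_density(df: pd.DataFrame, ycol: str, ax=None):
    ax = ax or plt.subplots()[1]
    ax.scatter(df["density_kg_m3"], df[ycol])
    ax.set_xlabel("density [kg m$^{-3}$]")
    ax.set_ylabel(ycol)
    return ax


def plot_shell_profile(profile: ShellProfile, ax=None, *, relative: bool = True):
    ax = ax or plt.subplots()[1]
    mid = (profile.r_inner_um + profile.r_outer_um) / 2.0
    y = profile.relative_frequency if relative else profile.frequency_per_um
    ax.plot(mid, y, marker="o")
    ax.set_xlabel("distance to substrate [µm]")
    ax.set_ylabel(
        "relative branching frequency" if relative else "branching frequency [µm$^{-1}$]"
    )
    return ax


def plot_stiffness_density_map(
    df: pd.DataFrame, reference_regions: list[dict] | None = None, ax=None
):
    """Log-log modulus-vs-density scatter with optional user-supplied
    reference rectangles ({'density': (lo, hi), 'modulus': (lo, hi),
    'label': str})."""
    ax = ax or plt.subplots()[1]
    ax.scatter(df["density_kg_m3"], df["modulus_N_mm2"], zorder=3)
    for region in reference_regions or []:
        (x0, x1), (y0, y1) = region["density"], region["modulus"]
        ax.fill_betweenx([y0, y1], x0, x1, alpha=0.2, label=region.get("label"))
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("density [kg m$^{-3}$]")
    ax.set_ylabel("modulus of elasticity [N mm$^{-2}$]")
    if reference_regions:
        ax.legend(fontsize="small")
    return ax


def run_report(
    results: dict, out_dir: str | Path, *, formats=DEFAULT_FORMATS
) -> list[Path]:
    """Generate every figure for which data is present; warn and skip the
    rest. Returns the list of written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curves = results.get("compression_curves")
    if curves:
        fig, ax = plt.subplots()
        plot_stress_strain(curves, ax)
        written += _save(fig, out_dir, "stress_strain", formats)

    props = results.get("property_vs_density")
    if props is not None and len(props):
        for ycol in [c for c in props.columns if c != "density_kg_m3"]:
            fig, ax = plt.subplots()
            plot_property_vs_density(props, ycol, ax)
            written += _save(fig, out_dir, f"{ycol}_vs_density", formats)

    profile = results.get("shell_profile")
    if profile is not None and profile.n_shells:
        fig, ax = plt.subplots()
        plot_shell_profile(profile, ax)
        written += _save(fig, out_dir, "branching_frequency", formats)

    ashby = results.get("stiffness_density")
    if ashby is not None and len(ashby):
        fig, ax = plt.subplots()
        plot_stiffness_density_map(ashby, results.get("reference_regions"), ax)
        written += _save(fig, out_dir, "stiffness_density_map", formats)

    if not written:
        logger.warning("no plottable results; no figures generated")
    return written
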