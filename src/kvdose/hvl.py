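"""Spectral half-value layer from air-KERMA attenuation.

The HVL of a beam is the absorber thickness t that halves the air KERMA
computed from the fluence spectrum under narrow-beam (scatter-free)
geometry:

    k(t)/k(0) = [sum_i phi_i E_i (muen/rho)_air(E_i) exp(-mu_abs(E_i) t) dE_i]
                / [sum_i phi_i E_i (muen/rho)_air(E_i) dE_i] = 1/2

For a polyenergetic beam the ratio is a strictly decreasing, continuous
function of t, so the root is found by bracketed root-finding.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .materials import MaterialTable, load_material
from .spectrum import BeamSpectrum

__all__ = ["HVLResult", "kerma_ratio", "hvl"]

RATIO_TOL = 1e-6
BRACKET_MM = (0.0, 20.0)


@dataclass(frozen=True)
class HVLResult:
    thickness_mm: float
    absorber: str
    kerma_ratio_at_solution: float
    solver_iterations: int

    def __post_init__(self):
        if self.thickness_mm < 0:
            raise ValueError("HVL thickness cannot be negative")
        if abs(self.kerma_ratio_at_solution - 0.5) > RATIO_TOL:
            raise ValueError("solver did not reach the half-KERMA ratio")


def kerma_ratio(spectrum: BeamSpectrum, absorber: MaterialTable,
                thickness_cm: float,
                air: MaterialTable | None = None) -> float:
    """Attenuated-to-unattenuated air KERMA ratio k(t)/k(0)."""
    if thickness_cm < 0:
        raise ValueError("thickness must be nonnegative")
    if air is None:
        air = load_material("air")
    flu = np.asarray(spectrum.fluence, float)
    e = spectrum.bin_centers
    w = flu * e * air("energy_absorption", e) * spectrum.bin_widths
    k0 = w.sum()
    if k0 <= 0:
        raise ValueError("spectrum has zero air KERMA")
    kt = np.sum(w * np.exp(-absorber.mu(e) * thickness_cm))
    return float(kt / k0)


def hvl(spectrum: BeamSpectrum, absorber: MaterialTable | None = None,
        air: MaterialTable | None = None) -> HVLResult:
    """Thickness (mm) of ``absorber`` halving the spectral air KERMA."""
    if absorber is None:
        absorber = load_material("aluminum")
    if air is None:
        air = load_material("air")
    iters = 0

    def f(t_mm):
        nonlocal iters
        iters += 1
        return kerma_ratio(spectrum, absorber, t_mm / 10.0, air) - 0.5

    lo, hi = BRACKET_MM
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            f"no half-KERMA root in [{lo}, {hi}] mm of {absorber.name}")
    t = brentq(f, lo, hi, xtol=1e-7, rtol=8.9e-16)
    return HVLResult(
        thickness_mm=float(t),
        absorber=absorber.name,
        kerma_ratio_at_solution=kerma_ratio(spectrum, absorber, t / 10.0, air),
        solver_iterations=iters,
    )


def homogeneity_coefficient(spectrum: BeamSpectrum,
                            absorber: MaterialTable | None = None) -> float:
    """First HVL divided by the second HVL (1 for a monoenergetic beam)."""
    if absorber is None:
        absorber = load_material("aluminum")
    first = hvl(spectrum, absorber).thickness_mm

    def f(t_mm):
        return kerma_ratio(spectrum, absorber, t_mm / 10.0) - 0.25

    quarter = brentq(f, first, 3 * BRACKET_MM[1], xtol=1e-7)
    return first / (quarter - first)
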