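"""Derived dosimetric quantities.

Central-axis percent depth dose (PDD) normalized to the surface voxel,
peak bone-interface dose enhancement, water/bone transmission ratios,
RMSE between PDD curves, and the relative f-factor (ratio of mass
energy-absorption coefficients, the classic exposure-to-dose conversion
contrast between bone and soft tissue).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import MaterialTable
from .spectrum import BeamSpectrum
from .transport import DoseGrid, central_axis

__all__ = ["PDDCurve", "extract_pdd", "interface_enhancement",
           "transmission_ratio", "rmse", "relative_f_factor"]


@dataclass(frozen=True)
class PDDCurve:
    """Central-axis dose versus depth.

    ``normalization`` is ``"raw"`` or ``"percent_of_surface"`` (surface
    voxel scaled to exactly 100).
    """

    depths_cm: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    uncertainty: np.ndarray | None = None  # fractional, per depth

    def __post_init__(self):
        d = np.asarray(self.depths_cm, float)
        v = np.asarray(self.values, float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if len(d) != len(v):
            raise ValueError("depths and values length mismatch")
        if np.any(v < 0):
            raise ValueError("PDD values must be nonnegative")
        if self.normalization == "percent_of_surface" and v[0] != 100.0:
            raise ValueError("percent_of_surface curves start at 100")

    def to_percent_of_surface(self) -> "PDDCurve":
        v = np.asarray(self.values, float)
        if v[0] <= 0:
            raise ZeroDivisionError("zero surface dose; cannot normalize")
        out = 100.0 * v / v[0]
        out[0] = 100.0
        return replace(self, values=out, normalization="percent_of_surface")


def extract_pdd(dose: DoseGrid,
                normalization: str = "percent_of_surface") -> PDDCurve:
    """Central-axis PDD of a dose grid (central 2x2 voxel block)."""
    depths, vals, rel = central_axis(dose)
    curve = PDDCurve(depths_cm=depths, values=vals, normalization="raw",
                     uncertainty=rel)
    if normalization == "percent_of_surface":
        return curve.to_percent_of_surface()
    if normalization != "raw":
        raise ValueError("normalization must be 'raw' or 'percent_of_surface'")
    return curve


def interface_enhancement(pdd: PDDCurve,
                          bone_interval_cm: tuple[float, float]) -> float:
    """Peak PDD value (percent of surface dose) inside the bone slab."""
    if pdd.normalization != "percent_of_surface":
        raise ValueError("enhancement is defined on a percent-of-surface PDD")
    z0, z1 = bone_interval_cm
    d = np.asarray(pdd.depths_cm, float)
    sel = (d >= z0) & (d < z1)
    if not sel.any():
        raise ValueError(f"no depths inside bone interval [{z0}, {z1}) cm")
    return float(np.max(np.asarray(pdd.values, float)[sel]))


def transmission_ratio(dose_water_only: DoseGrid, dose_with_bone: DoseGrid,
                       depth_cm: float) -> float:
    """Central-axis dose ratio water-only / with-bone at one depth.

    Values above 1 quantify how much the upstream bone slab attenuates
    the beam (energy absorbed in bone instead of transmitted).
    """
    pa, pb = dose_water_only.phantom, dose_with_bone.phantom
    if pa.shape != pb.shape or (pa.dx, pa.dy, pa.dz) != (pb.dx, pb.dy, pb.dz):
        raise ValueError("dose grids have mismatched geometry")
    k = int(depth_cm / pa.dz)
    if not 0 <= k < pa.shape[2]:
        raise ValueError(f"depth {depth_cm} cm outside the grids")
    _, da, _ = central_axis(dose_water_only)
    _, db, _ = central_axis(dose_with_bone)
    if db[k] <= 0:
        raise ZeroDivisionError("zero dose in the bone phantom at the "
                                "requested depth")
    return float(da[k] / db[k])


def rmse(pdd_a: PDDCurve, pdd_b: PDDCurve) -> float:
    """Root-mean-square difference of two PDD curves.

    Curves must share normalization; the denser curve is linearly
    interpolated onto the sparser curve's depths over the overlapping
    range.  Units are those of the curve values (percent points for
    percent-of-surface curves).
    """
    if pdd_a.normalization != pdd_b.normalization:
        raise ValueError("curves must share normalization")
    da, db = np.asarray(pdd_a.depths_cm), np.asarray(pdd_b.depths_cm)
    lo, hi = max(da[0], db[0]), min(da[-1], db[-1])
    if lo > hi:
        raise ValueError("curves have no overlapping depth range")
    if len(da) <= len(db):
        sparse, dense = pdd_a, pdd_b
    else:
        sparse, dense = pdd_b, pdd_a
    ds = np.asarray(sparse.depths_cm)
    sel = (ds >= lo) & (ds <= hi)
    if not sel.any():
        raise ValueError("no common depths to compare")
    vs = np.asarray(sparse.values, float)[sel]
    vd = np.interp(ds[sel], np.asarray(dense.depths_cm),
                   np.asarray(dense.values, float))
    return float(np.sqrt(np.mean((vs - vd) ** 2)))


def relative_f_factor(numerator: MaterialTable, denominator: MaterialTable,
                      spectrum_or_energy) -> float:
    """Ratio of mass energy-absorption coefficients.

    For a single energy: (muen/rho)_num / (muen/rho)_den at that energy.
    For a spectrum: ratio of fluence-energy-weighted sums,
    sum phi E (muen/rho)_num dE / sum phi E (muen/rho)_den dE.
    """
    if isinstance(spectrum_or_energy, BeamSpectrum):
        s = spectrum_or_energy
        e = s.bin_centers
        w = np.asarray(s.fluence, float) * e * s.bin_widths
        num = np.sum(w * numerator("energy_absorption", e))
        den = np.sum(w * denominator("energy_absorption", e))
        return float(num / den)
    e = float(spectrum_or_energy)
    return (numerator("energy_absorption", e)
            / denominator("energy_absorption", e))
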