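"""Filtered tungsten-anode photon fluence spectra.

The modeled superficial therapy unit runs three techniques (50, 70 and
100 kVp) behind a 0.8 mm beryllium window plus an automatic aluminum
filter.  The vendor does not publish the aluminum thickness, so the
spectrum model is semi-empirical: a Kramers bremsstrahlung continuum
(intensity proportional to kvp - E, converted to fluence by dividing by
E) plus tungsten K characteristic lines above the 69.5 keV K-edge, both
attenuated through the window and filter; the aluminum thickness is then
*calibrated* so the spectral air-KERMA half-value layer matches the
stated beam quality (0.45 / 1.10 / 2.10 mm Al).  HVL agreement is thus a
consistency check while depth-dose and bone-dose ratios are genuine
predictions of the model.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .materials import MaterialTable, load_material

__all__ = [
    "BeamSpectrum", "tube_spectrum", "attenuate", "air_kerma",
    "calibrate_filtration", "read_spectrum", "write_spectrum",
]

#: tungsten K-edge and K-line energies (keV) with relative intensities
W_K_EDGE = 69.525
W_LINES = (
    (59.32, 1.00),   # K-alpha1
    (57.98, 0.576),  # K-alpha2
    (67.24, 0.231),  # K-beta1 (+beta3)
    (69.07, 0.081),  # K-beta2
)
#: exponent of the K-line production scaling ((kvp/E_K - 1)^p)
K_PRODUCTION_EXPONENT = 1.65
#: K-line share of total filtered fluence at 100 kVp (default yield)
DEFAULT_K_FRACTION = 0.06

MIN_BIN_EDGE = 5.0  # keV; bins below this are truncated after filtration


@dataclass(frozen=True)
class BeamSpectrum:
    """Binned relative photon fluence versus energy.

    ``fluence[i]`` is the number of photons (arbitrary normalization) in
    ``[bin_edges[i], bin_edges[i+1])``; no photons exist above the tube
    potential ``kvp``.
    """

    kvp: float
    bin_edges: np.ndarray
    fluence: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, float)
        flu = np.asarray(self.fluence, float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(flu) != len(edges) - 1:
            raise ValueError("fluence must have len(bin_edges) - 1 entries")
        if np.any(flu < 0) or not np.any(flu > 0):
            raise ValueError("fluence must be nonnegative with at least one "
                             "positive bin")
        if edges[-1] > self.kvp + 1e-9:
            raise ValueError("no photons may exist above the tube potential")

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges, float)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.bin_edges, float))

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy (keV)."""
        f = np.asarray(self.fluence, float)
        return float(np.sum(f * self.bin_centers) / np.sum(f))

    def normalized(self) -> "BeamSpectrum":
        f = np.asarray(self.fluence, float)
        return replace(self, fluence=f / f.sum())


def tube_spectrum(kvp: float, inherent_be_mm: float = 0.8,
                  added_al_mm: float = 0.0, bin_width_keV: float = 1.0,
                  k_fraction: float = DEFAULT_K_FRACTION) -> BeamSpectrum:
    """Semi-empirical filtered tube spectrum, normalized to unit fluence.

    Kramers continuum fluence ``(kvp - E)/E`` per unit energy plus
    tungsten K lines (only when ``kvp`` exceeds the K-edge; their
    filtered fluence share is anchored to ``k_fraction`` at 100 kVp and
    scaled down as ``(kvp/E_K - 1)**1.65`` for lower potentials, which
    makes them negligible at 70 kVp).  Both components are attenuated
    through the beryllium window and the added aluminum.
    """
    if kvp <= 0 or kvp > 150:
        raise ValueError("kvp must be in (0, 150]")
    if inherent_be_mm < 0 or added_al_mm < 0:
        raise ValueError("filtration thicknesses must be nonnegative")
    be = load_material("beryllium")
    al = load_material("aluminum")
    edges = np.arange(MIN_BIN_EDGE, kvp + 0.5 * bin_width_keV, bin_width_keV)
    if edges[-1] < kvp - 1e-9:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    flu = (kvp - centers) / centers * widths
    flu = np.clip(flu, 0.0, None)

    def transmission(e_keV):
        t = np.exp(-be.mu(e_keV) * inherent_be_mm / 10.0)
        t *= np.exp(-al.mu(e_keV) * added_al_mm / 10.0)
        return t

    flu *= transmission(centers)

    if kvp > W_K_EDGE and k_fraction > 0:
        scale = ((kvp / W_K_EDGE - 1.0) / (100.0 / W_K_EDGE - 1.0))
        scale = scale ** K_PRODUCTION_EXPONENT
        line_e = np.array([e for e, _ in W_LINES])
        line_w = np.array([w for _, w in W_LINES])
        line_w = line_w * transmission(line_e)  # filter at the exact line energy
        line_total = k_fraction * scale * flu.sum()
        line_w *= line_total / line_w.sum()
        for e, w in zip(line_e, line_w):
            if e < kvp:
                flu[np.searchsorted(edges, e, side="right") - 1] += w

    return BeamSpectrum(kvp=float(kvp), bin_edges=edges, fluence=flu).normalized()


def attenuate(spectrum: BeamSpectrum, material: MaterialTable,
              thickness_cm: float) -> BeamSpectrum:
    """Exponentially attenuate each bin: phi' = phi * exp(-mu(E_i) t)."""
    if thickness_cm < 0:
        raise ValueError("thickness must be nonnegative")
    mu = material.mu(spectrum.bin_centers)
    return replace(spectrum,
                   fluence=np.asarray(spectrum.fluence, float)
                   * np.exp(-mu * thickness_cm))


def air_kerma(spectrum: BeamSpectrum,
              air: MaterialTable | None = None) -> float:
    """Relative air KERMA: sum_i phi_i E_i (muen/rho)_air(E_i) dE_i."""
    flu = np.asarray(spectrum.fluence, float)
    if not np.any(flu > 0):
        raise ValueError("empty spectrum")
    if air is None:
        air = load_material("air")
    e = spectrum.bin_centers
    return float(np.sum(flu * e * air("energy_absorption", e)
                        * spectrum.bin_widths))


def calibrate_filtration(kvp: float, target_hvl_mm_al: float,
                         inherent_be_mm: float = 0.8,
                         bin_width_keV: float = 1.0,
                         bracket_mm: tuple[float, float] = (0.0, 10.0),
                         tol_mm: float = 0.005) -> float:
    """Added aluminum (mm) whose spectrum has the target air-KERMA HVL.

    HVL increases monotonically with filtration (beam hardening), so a
    bracketing root-finder on the bracket suffices.  Raises if the target
    is unreachable within the bracket.
    """
    from .hvl import hvl  # deferred: hvl depends on this module

    al = load_material("aluminum")

    def f(t_mm):
        s = tube_spectrum(kvp, inherent_be_mm, t_mm, bin_width_keV)
        return hvl(s, al).thickness_mm - target_hvl_mm_al

    lo, hi = bracket_mm
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"target HVL {target_hvl_mm_al} mm Al not reachable for "
            f"{kvp} kVp within added Al in [{lo}, {hi}] mm "
            f"(achievable range [{flo + target_hvl_mm_al:.3f}, "
            f"{fhi + target_hvl_mm_al:.3f}] mm)")
    return float(brentq(f, lo, hi, xtol=tol_mm / 5.0))


def write_spectrum(spectrum: BeamSpectrum, path, comment: str = ""):
    """Two-column text: energy bin center (keV), relative fluence per bin."""
    with open(path, "w") as fh:
        fh.write(f"# kvp {spectrum.kvp:.6g}\n")
        fh.write(f"# bin_width {spectrum.bin_widths[0]:.6g} keV\n")
        if comment:
            fh.write(f"# {comment}\n")
        for e, f in zip(spectrum.bin_centers, spectrum.fluence):
            fh.write(f"{e:.6f} {f:.9e}\n")


def read_spectrum(path) -> BeamSpectrum:
    kvp = None
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                body = ln[1:].split()
                if body and body[0] == "kvp":
                    kvp = float(body[1])
                continue
            e, f = ln.split()
            rows.append((float(e), float(f)))
    if kvp is None:
        raise ValueError("missing '# kvp' header")
    centers = np.array([r[0] for r in rows])
    flu = np.array([r[1] for r in rows])
    widths = np.diff(centers)
    w = widths[0] if len(widths) else 1.0
    edges = np.concatenate([centers - w / 2, [centers[-1] + w / 2]])
    # last bin may have been truncated at the tube potential
    edges[-1] = min(edges[-1], kvp)
    return BeamSpectrum(kvp=kvp, bin_edges=edges, fluence=flu)
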