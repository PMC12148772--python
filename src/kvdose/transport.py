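"""Voxel Monte Carlo photon dose engine (collision-KERMA scoring).

Photons are sampled from a binned beam spectrum at a point source on the
central axis, aimed uniformly into the cone subtending the circular
surface field, and ray-traced voxel-by-voxel with exact boundary
crossing.  Energy transferred to electrons is deposited in the voxel of
the interaction (local-deposition / collision-KERMA approximation): the
CSDA range of the most energetic secondary electron at 100 keV in water
is about 0.014 cm, on the order of the finest voxel used (0.01 cm), so
electron transport is not modeled.  Per-voxel statistical uncertainty is
estimated from batch variance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .materials import MaterialTable
from .phantom import VoxelPhantom
from .spectrum import BeamSpectrum

__all__ = ["BeamSource", "SimulationConfig", "DoseGrid", "simulate",
           "primary_kerma_analytic", "sample_compton", "write_3ddose",
           "central_axis"]

#: dense energy-lookup grid used inside the kernel (keV)
_LUT_E0, _LUT_E1, _LUT_DE = 5.0, 150.0, 0.25


class EnergyConservationError(RuntimeError):
    """The engine's energy audit failed (internal error / test hook)."""


@dataclass(frozen=True)
class BeamSource:
    """Point source at z = -ssd on the central axis, illuminating a
    circular field of the given diameter at the phantom surface."""

    spectrum: BeamSpectrum
    ssd_cm: float = 15.0
    field_diameter_cm: float = 2.0

    def __post_init__(self):
        if self.ssd_cm <= 0 or self.field_diameter_cm <= 0:
            raise ValueError("ssd and field diameter must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    n_histories: int = 1_000_000
    rng_seed: int = 1
    photon_cutoff_keV: float = 10.0
    rayleigh_enabled: bool = True
    scatter_enabled: bool = True
    batches: int = 10

    def __post_init__(self):
        if self.batches < 2 or self.n_histories < self.batches:
            raise ValueError("need n_histories >= batches >= 2")
        if self.photon_cutoff_keV < _LUT_E0:
            raise ValueError(
                f"cutoff below the material-grid minimum ({_LUT_E0} keV)")


@dataclass
class DoseGrid:
    """Per-voxel dose (keV/g per source photon) with batch uncertainty."""

    phantom: VoxelPhantom
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    n_histories: int
    rng_seed: int
    emitted_keV: float = 0.0
    deposited_keV: float = 0.0
    escaped_keV: float = 0.0
    discarded_keV: float = 0.0

    @property
    def energy_balance(self) -> float:
        """Relative energy-audit residual (should be ~0)."""
        return abs(self.deposited_keV + self.escaped_keV + self.discarded_keV
                   - self.emitted_keV) / self.emitted_keV


def _lut(materials, kind_arrays):
    """Material lookup tables on the dense kernel energy grid."""
    egrid = np.arange(_LUT_E0, _LUT_E1 + _LUT_DE / 2, _LUT_DE)
    nmat = len(materials)
    out = [np.empty((nmat, len(egrid))) for _ in kind_arrays]
    for m, mt in enumerate(materials):
        for a, kind in enumerate(kind_arrays):
            out[a][m] = mt(kind, egrid)
    return egrid, out


def _batch_seed(seed: int, batch: int) -> int:
    return (seed * 1_000_003 + 7919 * batch + 1) % (2**31 - 1)


def simulate(source: BeamSource, phantom: VoxelPhantom,
             config: SimulationConfig) -> DoseGrid:
    """Run the Monte Carlo engine and return the scored dose grid."""
    spec = source.spectrum
    flu = np.asarray(spec.fluence, float)
    if not np.any(flu > 0):
        raise ValueError("empty spectrum")
    if config.n_histories <= 0:
        raise ValueError("n_histories must be positive")
    cdf = np.cumsum(flu) / flu.sum()
    edges = np.asarray(spec.bin_edges, float)

    _, (mu_tot, mu_pe, mu_inc, muen) = _lut(
        phantom.materials,
        ("total", "photoelectric", "incoherent", "energy_absorption"))
    f_pe = mu_pe / mu_tot
    f_pe_inc = (mu_pe + mu_inc) / mu_tot
    muen_over_mu = muen / mu_tot

    nx, ny, nz = phantom.shape
    cx = nx * phantom.dx / 2.0
    cy = ny * phantom.dy / 2.0
    mat = np.ascontiguousarray(phantom.material_index, dtype=np.int8)
    den = np.ascontiguousarray(phantom.density, dtype=np.float64)

    B = config.batches
    per = [config.n_histories // B] * B
    per[-1] += config.n_histories - sum(per)
    sum1 = np.zeros(phantom.shape)
    sum2 = np.zeros(phantom.shape)
    emitted = escaped = discarded = 0.0
    for b in range(B):
        edep = np.zeros(phantom.shape)
        em, es, di = _kernels.run_batch(
            _batch_seed(config.rng_seed, b), per[b], cdf, edges,
            source.ssd_cm, source.field_diameter_cm / 2.0, cx, cy,
            mat, den, phantom.dx, phantom.dy, phantom.dz,
            _LUT_E0, _LUT_DE, mu_tot, f_pe, f_pe_inc, muen_over_mu,
            config.photon_cutoff_keV, config.scatter_enabled,
            config.rayleigh_enabled, edep)
        emitted += em
        escaped += es
        discarded += di
        total_edep = total_edep + edep.sum() if b else float(edep.sum())
        rate = edep / per[b]           # keV per voxel per history
        sum1 += rate
        sum2 += rate * rate

    mean = sum1 / B
    var = np.maximum(sum2 / B - mean * mean, 0.0) / max(B - 1, 1)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), 1.0)

    mass = den * phantom.dx * phantom.dy * phantom.dz
    dose = mean / mass  # keV/g per history

    grid = DoseGrid(phantom=phantom, dose=dose, rel_uncertainty=rel,
                    n_histories=config.n_histories, rng_seed=config.rng_seed,
                    emitted_keV=emitted, deposited_keV=total_edep,
                    escaped_keV=escaped, discarded_keV=discarded)
    if grid.energy_balance > 1e-6:
        raise EnergyConservationError(
            f"energy audit residual {grid.energy_balance:.3e} "
            "exceeds 1e-6 of emitted energy")
    return grid


def primary_kerma_analytic(source: BeamSource,
                           phantom: VoxelPhantom) -> DoseGrid:
    """Closed-form primary (unscattered) collision KERMA on the axis.

    For a layered phantom, the central-axis KERMA per source photon at
    voxel-center depth z is

        sum_i phi_i E_i (muen/rho)(E_i, z) exp(-int_0^z mu(E_i) dz')
              * (ssd / (ssd + z))^2 / (pi R_field^2)

    in keV/g, directly comparable to the Monte Carlo dose with scatter
    disabled.  Off-axis voxels are filled with the same depth profile
    (valid on the axis only; use :func:`central_axis`).
    """
    if not phantom.is_layered():
        raise ValueError("analytic primary KERMA supports layered "
                         "(depth-only) phantoms")
    spec = source.spectrum
    flu = np.asarray(spec.fluence, float)
    flu = flu / flu.sum()
    e = spec.bin_centers
    nz = phantom.shape[2]
    zc = phantom.depths_cm
    mats = phantom.material_index[0, 0, :]
    dens = phantom.density[0, 0, :]

    mu = np.empty((nz, len(e)))
    muen_rho = np.empty((nz, len(e)))
    for m in np.unique(mats):
        sel = mats == m
        mt = phantom.materials[m]
        mu[sel] = mt("total", e)[None, :] * dens[sel, None]
        muen_rho[sel] = mt("energy_absorption", e)[None, :]

    od = np.cumsum(mu * phantom.dz, axis=0) - 0.5 * mu * phantom.dz
    geom = (source.ssd_cm / (source.ssd_cm + zc)) ** 2
    area = math.pi * (source.field_diameter_cm / 2.0) ** 2
    kerma_z = (flu[None, :] * e[None, :] * muen_rho
               * np.exp(-od)).sum(axis=1) * geom / area

    dose = np.broadcast_to(kerma_z, phantom.shape).copy()
    return DoseGrid(phantom=phantom, dose=dose,
                    rel_uncertainty=np.zeros(phantom.shape),
                    n_histories=0, rng_seed=0, emitted_keV=1.0)


def sample_compton(energy_keV: float, rng) -> tuple[float, float]:
    """One Klein-Nishina sample: (scattered energy keV, cos_theta).

    ``rng`` is a numpy Generator.  The scattered energy and angle are
    jointly consistent with the Compton relation
    E' = E / (1 + (E/m_e c^2)(1 - cos_theta)).
    """
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    a = energy_keV / _kernels.MEC2
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -math.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = eps0 ** rng.random()
        else:
            eps = math.sqrt(eps0**2 + (1.0 - eps0**2) * rng.random())
        t = (1.0 - eps) / (a * eps)
        sin2 = max(t * (2.0 - t), 0.0)
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if rng.random() <= g:
            return energy_keV * eps, 1.0 - t


def in_field_mask(source: BeamSource, phantom: VoxelPhantom) -> np.ndarray:
    """Voxels whose center lies inside the geometric beam cone."""
    nx, ny, nz = phantom.shape
    cx = nx * phantom.dx / 2.0
    cy = ny * phantom.dy / 2.0
    x = (np.arange(nx) + 0.5) * phantom.dx - cx
    y = (np.arange(ny) + 0.5) * phantom.dy - cy
    z = phantom.depths_cm
    rad = (source.field_diameter_cm / 2.0) * (source.ssd_cm + z) / source.ssd_cm
    r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2
    return r2 <= rad[None, None, :] ** 2


def central_axis(grid: DoseGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(depths, dose, rel_uncertainty) averaged over the central 2x2
    lateral voxel block (improves counting statistics on the axis)."""
    nx, ny, _ = grid.phantom.shape
    i0, j0 = nx // 2 - 1, ny // 2 - 1
    block = grid.dose[i0:i0 + 2, j0:j0 + 2, :]
    rel = grid.rel_uncertainty[i0:i0 + 2, j0:j0 + 2, :]
    dose = block.mean(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        abs_se = np.sqrt(np.sum((rel * block) ** 2, axis=(0, 1))) / 4.0
        rel_out = np.where(dose > 0, abs_se / np.where(dose > 0, dose, 1.0), 1.0)
    return grid.phantom.depths_cm, dose, rel_out


def write_3ddose(grid: DoseGrid, path):
    """Write the dose grid in the plain-text 3ddose layout (voxel counts,
    per-axis boundary coordinates, dose array, relative-error array; x
    index fastest)."""
    nx, ny, nz = grid.phantom.shape
    ph = grid.phantom
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {nz}\n")
        for n, d in ((nx, ph.dx), (ny, ph.dy), (nz, ph.dz)):
            fh.write(" ".join(f"{i * d:.6g}" for i in range(n + 1)) + "\n")
        for arr in (grid.dose, grid.rel_uncertainty):
            vals = arr.transpose(2, 1, 0).ravel()
            for off in range(0, len(vals), 6):
                fh.write(" ".join(f"{v:.6e}" for v in vals[off:off + 6]) + "\n")


def read_3ddose(path, phantom: VoxelPhantom | None = None) -> DoseGrid:
    with open(path) as fh:
        tokens = fh.read().split()
    nx, ny, nz = int(tokens[0]), int(tokens[1]), int(tokens[2])
    p = 3
    bounds = []
    for n in (nx, ny, nz):
        bounds.append(np.array([float(v) for v in tokens[p:p + n + 1]]))
        p += n + 1
    nvox = nx * ny * nz
    dose = np.array([float(v) for v in tokens[p:p + nvox]])
    p += nvox
    rel = np.array([float(v) for v in tokens[p:p + nvox]])
    dose = dose.reshape(nz, ny, nx).transpose(2, 1, 0)
    rel = rel.reshape(nz, ny, nx).transpose(2, 1, 0)
    if phantom is None:
        from .materials import load_material
        water = load_material("water")
        mat = np.zeros((nx, ny, nz), np.int8)
        den = np.full((nx, ny, nz), water.density)
        phantom = VoxelPhantom([water], mat, den,
                               float(bounds[0][1] - bounds[0][0]),
                               float(bounds[1][1] - bounds[1][0]),
                               float(bounds[2][1] - bounds[2][0]))
    return DoseGrid(phantom=phantom, dose=dose, rel_uncertainty=rel,
                    n_histories=0, rng_seed=0, emitted_keV=1.0)
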