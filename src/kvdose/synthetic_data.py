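"""Seed-reproducible fixtures: emulated measured PDDs and toy materials.

The laboratory depth-dose measurements the simulations are compared to
are not distributed with the package, so :func:`synth_measured_pdd`
emulates an ion-chamber depth scan with a near-exponential attenuation
plus inverse-square falloff and multiplicative Gaussian noise.  It
exercises the RMSE comparison plumbing; it does not model scatter
buildup or chamber physics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import PDDCurve
from .materials import MaterialTable

__all__ = ["MeasuredPDDFixture", "synth_measured_pdd", "toy_material"]

#: default measurement depths of the emulated depth scan (mm)
DEFAULT_DEPTHS_MM = (5.0, 10.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class MeasuredPDDFixture:
    depths_mm: np.ndarray
    values: np.ndarray          # percent of the first-depth value
    noise_sigma: float
    rng_seed: int
    mu_eff_cm: float

    def as_curve(self) -> PDDCurve:
        v = np.asarray(self.values, float).copy()
        v[0] = 100.0
        return PDDCurve(depths_cm=np.asarray(self.depths_mm, float) / 10.0,
                        values=v, normalization="percent_of_surface")


def synth_measured_pdd(mu_eff_cm: float, ssd_cm: float = 15.0,
                       noise_sigma: float = 0.01, rng_seed: int = 0,
                       depths_mm=DEFAULT_DEPTHS_MM) -> MeasuredPDDFixture:
    """Emulated measured PDD: 100 exp(-mu_eff z) (ssd/(ssd+z))^2 (1+eps),
    eps ~ N(0, noise_sigma), renormalized to 100 at the first depth."""
    if mu_eff_cm <= 0:
        raise ValueError("mu_eff must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    z = np.asarray(depths_mm, float) / 10.0
    rng = np.random.default_rng(rng_seed)
    vals = 100.0 * np.exp(-mu_eff_cm * z) * (ssd_cm / (ssd_cm + z)) ** 2
    vals = vals * (1.0 + rng.normal(0.0, noise_sigma, size=len(z)))
    vals = 100.0 * vals / vals[0]
    return MeasuredPDDFixture(depths_mm=np.asarray(depths_mm, float),
                              values=vals, noise_sigma=noise_sigma,
                              rng_seed=rng_seed, mu_eff_cm=mu_eff_cm)


def write_fixture_csv(fix: MeasuredPDDFixture, path):
    with open(path, "w") as fh:
        fh.write(f"# seed {fix.rng_seed}\n# sigma {fix.noise_sigma:.6g}\n")
        fh.write(f"# mu_eff {fix.mu_eff_cm:.6g}\n")
        fh.write("depth_mm,pdd_percent\n")
        for d, v in zip(fix.depths_mm, fix.values):
            fh.write(f"{d:.6g},{v:.9g}\n")


def read_fixture_csv(path) -> MeasuredPDDFixture:
    meta = {"seed": 0, "sigma": 0.0, "mu_eff": 1.0}
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln.startswith("#"):
                key, val = ln[1:].split()
                meta[key] = float(val)
            elif ln and not ln.startswith("depth"):
                d, v = ln.split(",")
                rows.append((float(d), float(v)))
    arr = np.array(rows)
    return MeasuredPDDFixture(depths_mm=arr[:, 0], values=arr[:, 1],
                              noise_sigma=meta["sigma"],
                              rng_seed=int(meta["seed"]),
                              mu_eff_cm=meta["mu_eff"])


def toy_material(mu_rho_points, muen_rho_points, partial_split=(1.0, 0.0, 0.0),
                 density: float = 1.0, name: str = "toy") -> MaterialTable:
    """MaterialTable from (energy, value) points and a fixed partial split.

    ``partial_split`` = (photoelectric, incoherent, coherent) fractions,
    summing to 1, applied at every grid point.  Handy for closed-form
    transport and HVL oracles (e.g. flat mu/rho, pure-photoelectric).
    """
    p = np.asarray(partial_split, float)
    if abs(p.sum() - 1.0) > 1e-12 or np.any(p < 0):
        raise ValueError("partial_split must be nonnegative and sum to 1")
    mu = np.array(mu_rho_points, float)
    muen = np.array(muen_rho_points, float)
    if mu.shape != muen.shape or mu.ndim != 2:
        raise ValueError("need matching (energy, value) point arrays")
    floor = 1e-12
    return MaterialTable(
        name=name, density=density,
        energy_grid=mu[:, 0],
        mu_rho_total=mu[:, 1],
        mu_rho_photoelectric=np.maximum(mu[:, 1] * p[0], floor),
        mu_rho_incoherent=np.maximum(mu[:, 1] * p[1], floor),
        mu_rho_coherent=np.maximum(mu[:, 1] * p[2], floor),
        muen_rho=muen[:, 1],
    )
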