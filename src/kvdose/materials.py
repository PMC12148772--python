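"""Photon interaction coefficient tables.

Each packaged material carries mass attenuation coefficients (total and
the photoelectric / incoherent / coherent partials) and the mass
energy-absorption coefficient on a common 5-150 keV grid, interpolated
log-log between grid points -- the standard treatment for photon cross
sections, whose dominant photoelectric component is close to a power law
in energy.  Packaged materials: water, ICRP cortical bone (1.85 g/cm3),
dry air, aluminum, beryllium.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialTable",
    "load_material",
    "available_materials",
    "coefficient",
    "interaction_fractions",
]

#: coefficient-selector names accepted by :func:`coefficient`
KINDS = ("total", "photoelectric", "incoherent", "coherent", "energy_absorption")

_KIND_ATTR = {
    "total": "mu_rho_total",
    "photoelectric": "mu_rho_photoelectric",
    "incoherent": "mu_rho_incoherent",
    "coherent": "mu_rho_coherent",
    "energy_absorption": "muen_rho",
}


@dataclass(frozen=True)
class MaterialTable:
    """Energy-gridded photon coefficients for one material.

    All coefficient arrays are in cm^2/g, indexed parallel to
    ``energy_grid`` (keV, strictly increasing).
    """

    name: str
    density: float
    energy_grid: np.ndarray
    mu_rho_total: np.ndarray
    mu_rho_photoelectric: np.ndarray
    mu_rho_incoherent: np.ndarray
    mu_rho_coherent: np.ndarray
    muen_rho: np.ndarray
    _log_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        e = np.asarray(self.energy_grid, float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy_grid must be 1-D and strictly increasing")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for kind, attr in _KIND_ATTR.items():
            c = np.asarray(getattr(self, attr), float)
            if c.shape != e.shape:
                raise ValueError(f"{attr} shape mismatch")
            if np.any(c <= 0):
                raise ValueError(f"{attr} must be positive everywhere")
        if np.any(self.mu_rho_total < self.muen_rho):
            raise ValueError("mu_rho_total must dominate muen_rho")
        closure = np.abs(
            self.mu_rho_photoelectric + self.mu_rho_incoherent
            + self.mu_rho_coherent - self.mu_rho_total
        ) / self.mu_rho_total
        if np.any(closure > 0.02):
            raise ValueError("partial coefficients do not sum to the total")

    # -- interpolation ------------------------------------------------

    def _logs(self, kind: str):
        if kind not in self._log_cache:
            self._log_cache["_e"] = np.log(np.asarray(self.energy_grid, float))
            self._log_cache[kind] = np.log(
                np.asarray(getattr(self, _KIND_ATTR[kind]), float))
        return self._log_cache["_e"], self._log_cache[kind]

    def __call__(self, kind: str, energy_keV):
        return coefficient(self, kind, energy_keV)

    def mu(self, energy_keV, kind: str = "total"):
        """Linear attenuation coefficient (1/cm) at the material density."""
        return coefficient(self, kind, energy_keV) * self.density


def coefficient(table: MaterialTable, kind: str, energy_keV):
    """Log-log interpolated coefficient (cm^2/g) at ``energy_keV``.

    Exact at grid points; raises on energies outside the grid (no
    extrapolation).
    """
    if kind not in _KIND_ATTR:
        raise ValueError(f"unknown coefficient kind {kind!r}; choose from {KINDS}")
    e = np.asarray(energy_keV, float)
    lo, hi = table.energy_grid[0], table.energy_grid[-1]
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy out of table range [{lo}, {hi}] keV for {table.name}")
    loge, logc = table._logs(kind)
    out = np.exp(np.interp(np.log(e), loge, logc))
    return float(out) if np.isscalar(energy_keV) else out


def interaction_fractions(table: MaterialTable, energy_keV):
    """(p_photoelectric, p_incoherent, p_coherent), renormalized to sum to 1."""
    pe = coefficient(table, "photoelectric", energy_keV)
    inc = coefficient(table, "incoherent", energy_keV)
    coh = coefficient(table, "coherent", energy_keV)
    tot = pe + inc + coh
    return pe / tot, inc / tot, coh / tot


# -- fixture file I/O ---------------------------------------------------

def read_material_file(path_or_lines, name: str | None = None) -> MaterialTable:
    """Parse the plain-text fixture format.

    Header: ``# <name>`` then ``# density <rho> g/cm3``; data rows are six
    whitespace-separated columns (energy_keV, total, pe, incoh, coh, muen).
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = list(path_or_lines)
    else:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    density = None
    parsed_name = name
    rows = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln[1:].strip()
            if body.startswith("density"):
                density = float(body.split()[1])
            elif body.startswith("columns"):
                pass
            elif parsed_name is None and body:
                parsed_name = body.split()[0]
            continue
        rows.append([float(x) for x in ln.split()])
    if density is None:
        raise ValueError("missing '# density' header")
    arr = np.array(rows, float)
    return MaterialTable(
        name=parsed_name or "unnamed",
        density=density,
        energy_grid=arr[:, 0],
        mu_rho_total=arr[:, 1],
        mu_rho_photoelectric=arr[:, 2],
        mu_rho_incoherent=arr[:, 3],
        mu_rho_coherent=arr[:, 4],
        muen_rho=arr[:, 5],
    )


def write_material_file(table: MaterialTable, path):
    lines = [f"# {table.name}", f"# density {table.density:.6g} g/cm3",
             "# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh "
             "mu_rho_coh muen_rho"]
    for i, e in enumerate(table.energy_grid):
        lines.append(
            f"{e:8.2f} {table.mu_rho_total[i]:.6e} "
            f"{table.mu_rho_photoelectric[i]:.6e} "
            f"{table.mu_rho_incoherent[i]:.6e} "
            f"{table.mu_rho_coherent[i]:.6e} {table.muen_rho[i]:.6e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_CACHE: dict[str, MaterialTable] = {}


def available_materials():
    root = importlib.resources.files("kvdose") / "data"
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".txt"))


def load_material(name: str) -> MaterialTable:
    """Load a packaged material table by name (cached)."""
    if name not in _CACHE:
        ref = importlib.resources.files("kvdose") / "data" / f"{name}.txt"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise KeyError(
                f"no packaged material {name!r}; have {available_materials()}")
        _CACHE[name] = read_material_file(text.splitlines(), name=name)
    return _CACHE[name]
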