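"""Voxelized phantom builders for layered water-bone geometries.

Conventions: voxel indices are 0-based; x and y are lateral, z is depth
from the entrance surface; voxel (i, j, k) spans the half-open depth
interval [k*dz, (k+1)*dz).  The beam enters at z = 0.  Slab boundaries
must coincide with voxel boundaries (no partial-volume voxels), matching
common voxel Monte Carlo practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialTable, load_material

__all__ = ["VoxelPhantom", "water_phantom", "slab_phantom",
           "transmission_pair", "preset", "write_phantom", "read_phantom"]

_EPS = 1e-9


@dataclass
class VoxelPhantom:
    """3-D material/density grid with per-axis voxel sizes (cm)."""

    materials: list           # MaterialTable per material index
    material_index: np.ndarray  # int8, shape (nx, ny, nz)
    density: np.ndarray         # g/cm3, shape (nx, ny, nz)
    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if self.material_index.max() >= len(self.materials):
            raise ValueError("material_index refers to an unloaded material")

    @property
    def shape(self):
        return self.material_index.shape

    @property
    def extent_cm(self):
        nx, ny, nz = self.shape
        return nx * self.dx, ny * self.dy, nz * self.dz

    @property
    def depths_cm(self) -> np.ndarray:
        """Voxel-center depths."""
        nz = self.shape[2]
        return (np.arange(nz) + 0.5) * self.dz

    def material_names(self):
        return [m.name for m in self.materials]

    def depth_voxels(self, z0_cm: float, z1_cm: float):
        """Indices k of voxels wholly inside the depth interval [z0, z1)."""
        k0 = int(round(z0_cm / self.dz))
        k1 = int(round(z1_cm / self.dz))
        return np.arange(k0, k1)

    def is_layered(self) -> bool:
        """True when material and density vary only with depth."""
        m0 = self.material_index[:1, :1, :]
        d0 = self.density[:1, :1, :]
        return bool(np.all(self.material_index == m0)
                    and np.all(self.density == d0))


def _uniform(materials, mat_of_k, nx, ny, nz, dx, dy, dz) -> VoxelPhantom:
    mat = np.zeros((nx, ny, nz), np.int8)
    den = np.zeros((nx, ny, nz), float)
    for k in range(nz):
        m = mat_of_k(k)
        mat[:, :, k] = m
        den[:, :, k] = materials[m].density
    return VoxelPhantom(list(materials), mat, den, dx, dy, dz)


def water_phantom(lateral_cm: float = 30.0, total_depth_cm: float = 10.0,
                  dxy_cm: float = 0.5, dz_cm: float = 0.05) -> VoxelPhantom:
    """All-water reference phantom: 30 x 30 x 10 cm3, 0.5 x 0.5 x 0.05 cm3
    voxels (60 x 60 x 200 grid) by default."""
    return slab_phantom(0.0, 0.0, lateral_cm, total_depth_cm, dz_cm, dxy_cm)


def _check_aligned(value, dz, what):
    n = value / dz
    if abs(n - round(n)) > _EPS / dz:
        raise ValueError(
            f"{what} = {value} cm does not fall on a voxel boundary "
            f"(dz = {dz} cm); partial-volume voxels are not supported")


def slab_phantom(bone_depth_cm: float, bone_thickness_cm: float,
                 lateral_cm: float = 10.0, total_depth_cm: float = 6.0,
                 dz_cm: float = 0.05, dxy_cm: float = 0.5) -> VoxelPhantom:
    """Water phantom with a bone slab in [bone_depth, bone_depth+thickness).

    ``bone_thickness_cm = 0`` degenerates to an all-water phantom.
    """
    if bone_depth_cm + bone_thickness_cm > total_depth_cm + _EPS:
        raise ValueError("bone slab extends beyond the phantom")
    _check_aligned(bone_depth_cm, dz_cm, "bone_depth")
    _check_aligned(bone_thickness_cm, dz_cm, "bone_thickness")
    water = load_material("water")
    bone = load_material("bone")
    nx = ny = int(round(lateral_cm / dxy_cm))
    nz = int(round(total_depth_cm / dz_cm))
    k0 = int(round(bone_depth_cm / dz_cm))
    k1 = int(round((bone_depth_cm + bone_thickness_cm) / dz_cm))

    def mat_of_k(k):
        return 1 if k0 <= k < k1 else 0

    return _uniform([water, bone], mat_of_k, nx, ny, nz, dxy_cm, dxy_cm, dz_cm)


def transmission_pair() -> tuple[VoxelPhantom, VoxelPhantom]:
    """The transmission-study pair: two 3 x 3 x 1.28 cm3 phantoms with
    0.5 x 0.5 x 0.01 cm3 voxels (6 x 6 x 128); the first holds a 0.5 cm
    bone slab at 0.3 cm depth, the second is all water."""
    with_bone = slab_phantom(0.3, 0.5, lateral_cm=3.0, total_depth_cm=1.28,
                             dz_cm=0.01)
    water_only = slab_phantom(0.0, 0.0, lateral_cm=3.0, total_depth_cm=1.28,
                              dz_cm=0.01)
    return with_bone, water_only


#: named study geometries: (builder kwargs, bone interval in cm)
PRESETS = {
    "bone03": dict(bone_depth_cm=0.3, bone_thickness_cm=0.5,
                   lateral_cm=3.0, total_depth_cm=1.28, dz_cm=0.01),
    "bone15": dict(bone_depth_cm=1.5, bone_thickness_cm=0.5,
                   lateral_cm=10.0, total_depth_cm=6.0, dz_cm=0.05),
    "bone25": dict(bone_depth_cm=2.5, bone_thickness_cm=0.5,
                   lateral_cm=10.0, total_depth_cm=6.0, dz_cm=0.05),
}


def preset(name: str) -> VoxelPhantom:
    """Build a named study phantom (bone03 / bone15 / bone25)."""
    try:
        kw = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return slab_phantom(**kw)


def bone_interval(name: str) -> tuple[float, float]:
    kw = PRESETS[name]
    return kw["bone_depth_cm"], kw["bone_depth_cm"] + kw["bone_thickness_cm"]


# -- plain-text phantom file (voxel-geometry text format) ---------------

def write_phantom(ph: VoxelPhantom, path):
    """Write the phantom in a DOSXYZnrc-inspired plain-text layout:
    material list, voxel counts, boundary coordinates per axis, then per
    z-slice a material-index map and a density map."""
    nx, ny, nz = ph.shape
    with open(path, "w") as fh:
        fh.write(f"{len(ph.materials)}\n")
        for m in ph.materials:
            fh.write(f"{m.name}\n")
        fh.write(f"{nx} {ny} {nz}\n")
        for n, d in ((nx, ph.dx), (ny, ph.dy), (nz, ph.dz)):
            fh.write(" ".join(f"{i * d:.6g}" for i in range(n + 1)) + "\n")
        for k in range(nz):
            for j in range(ny):
                fh.write("".join(str(int(v))
                                 for v in ph.material_index[:, j, k]) + "\n")
        for k in range(nz):
            for j in range(ny):
                fh.write(" ".join(f"{v:.6g}"
                                  for v in ph.density[:, j, k]) + "\n")


def read_phantom(path) -> VoxelPhantom:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    nmat = int(next(it))
    mats = [load_material(next(it).strip()) for _ in range(nmat)]
    nx, ny, nz = (int(v) for v in next(it).split())
    xb = [float(v) for v in next(it).split()]
    yb = [float(v) for v in next(it).split()]
    zb = [float(v) for v in next(it).split()]
    mat = np.zeros((nx, ny, nz), np.int8)
    for k in range(nz):
        for j in range(ny):
            row = next(it).strip()
            mat[:, j, k] = [int(c) for c in row]
    den = np.zeros((nx, ny, nz), float)
    for k in range(nz):
        for j in range(ny):
            den[:, j, k] = [float(v) for v in next(it).split()]
    return VoxelPhantom(mats, mat, den, xb[1] - xb[0], yb[1] - yb[0],
                        zb[1] - zb[0])
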