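"""Voxel phantoms, HU->material mapping, and exact ray traversal.

Phantoms are regular grids in world coordinates (cm): voxel (i, j, k) spans
``origin + (i, j, k) * spacing`` to ``origin + (i+1, j+1, k+1) * spacing``
with half-open ownership [lower, upper) per axis; a point exactly on the
grid's upper face belongs to no voxel.  Each voxel carries a material index
and a physical density, so one material table serves a density range:
mu_voxel(E) = (mu/rho)_material(E) * rho_voxel.

Ray traversal is Siddon/Amanatides-Woo style incremental stepping: exact
chord lengths whose sum equals the geometric length of the segment clipped
to the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .materials import Material, get_material
from . import _nrrd
from ._kernels import ray_trace_kernel, areal_path_kernel


@dataclass
class VoxelPhantom:
    origin_cm: np.ndarray           # world position of the grid's lower corner
    spacing_cm: np.ndarray          # per-axis voxel size
    material_index: np.ndarray      # (nx, ny, nz) int16
    density: np.ndarray             # (nx, ny, nz) g/cm^3
    materials: list[Material]       # index -> material

    def __post_init__(self) -> None:
        self.origin_cm = np.asarray(self.origin_cm, dtype=np.float64)
        self.spacing_cm = np.asarray(self.spacing_cm, dtype=np.float64)
        if np.any(self.spacing_cm <= 0):
            raise ValueError("spacing must be positive")
        self.material_index = np.ascontiguousarray(self.material_index,
                                                   dtype=np.int16)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.material_index.shape != self.density.shape:
            raise ValueError("material and density grids differ in shape")
        if np.any(self.density < 0):
            raise ValueError("negative density")
        if self.material_index.max() >= len(self.materials):
            raise ValueError("material index outside the material table")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def upper_cm(self) -> np.ndarray:
        return self.origin_cm + self.spacing_cm * np.array(self.dims)

    def voxel_index(self, point_cm) -> tuple[int, int, int]:
        """Voxel owning a world point (half-open convention)."""
        p = np.asarray(point_cm, dtype=float)
        idx = np.floor((p - self.origin_cm) / self.spacing_cm).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.dims)):
            raise ValueError(f"point {p.tolist()} outside the phantom grid")
        return tuple(idx)

    def contains(self, point_cm) -> bool:
        p = np.asarray(point_cm, dtype=float)
        return bool(np.all(p >= self.origin_cm) and np.all(p < self.upper_cm))

    def material_at(self, point_cm) -> Material:
        return self.materials[self.material_index[self.voxel_index(point_cm)]]

    def save(self, basepath: str | Path) -> None:
        """Write ``<base>_density.nrrd``, ``<base>_materials.nrrd``, ``<base>.json``."""
        base = Path(basepath)
        meta = {
            "origin_cm": self.origin_cm.tolist(),
            "spacing_cm": self.spacing_cm.tolist(),
            "materials": [
                {"name": m.name, "density_g_cm3": m.density,
                 "mode": m.mode, "composition": dict(m.composition)}
                for m in self.materials
            ],
        }
        _nrrd.write(base.with_name(base.name + "_density.nrrd"),
                    self.density.astype(np.float32),
                    self.spacing_cm, self.origin_cm)
        _nrrd.write(base.with_name(base.name + "_materials.nrrd"),
                    self.material_index,
                    self.spacing_cm, self.origin_cm)
        base.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, basepath: str | Path) -> "VoxelPhantom":
        base = Path(basepath)
        meta = json.loads(base.with_suffix(".json").read_text())
        dens, spacing, origin = _nrrd.read(base.with_name(base.name + "_density.nrrd"))
        mats, _, _ = _nrrd.read(base.with_name(base.name + "_materials.nrrd"))
        materials = [
            Material(m["name"], m["density_g_cm3"], m["composition"], m["mode"])
            for m in meta["materials"]
        ]
        return cls(origin_cm=np.array(meta["origin_cm"]),
                   spacing_cm=np.array(meta["spacing_cm"]),
                   material_index=mats.astype(np.int16),
                   density=dens.astype(np.float64),
                   materials=materials)


def build_cylinder_phantom(diameter_cm: float, length_cm: float,
                           material: Material, spacing_cm: float = 0.2,
                           margin_cm: float = 1.0) -> VoxelPhantom:
    """Homogeneous cylinder (axis along z, centered on the isocenter) in air.

    Voxels whose *centers* fall inside the cylinder get ``material``; the
    rest are air.  A ``margin_cm`` air shell is kept around the cylinder so
    rays enter the grid before the medium.
    """
    if diameter_cm <= 0 or length_cm <= 0:
        raise ValueError("dimensions must be positive")
    if spacing_cm > diameter_cm:
        raise ValueError("spacing larger than the cylinder diameter")
    air = get_material("air")
    half_xy = diameter_cm / 2 + margin_cm
    half_z = length_cm / 2
    nx = int(np.ceil(2 * half_xy / spacing_cm))
    nz = int(np.ceil(2 * half_z / spacing_cm))
    origin = np.array([-nx / 2 * spacing_cm, -nx / 2 * spacing_cm,
                       -nz / 2 * spacing_cm])
    spacing = np.array([spacing_cm] * 3)
    xc = origin[0] + (np.arange(nx) + 0.5) * spacing_cm
    zc = origin[2] + (np.arange(nz) + 0.5) * spacing_cm
    xx, yy = np.meshgrid(xc, xc, indexing="ij")
    inside_xy = xx**2 + yy**2 <= (diameter_cm / 2) ** 2
    mat = np.zeros((nx, nx, nz), dtype=np.int16)
    mat[inside_xy, :] = 1
    dens = np.where(mat == 1, material.density, air.density)
    return VoxelPhantom(origin_cm=origin, spacing_cm=spacing,
                        material_index=mat, density=dens,
                        materials=[air, material])


@dataclass(frozen=True)
class HUMapping:
    """Ordered half-open HU ranges [hu_min, hu_max) -> (material, density)."""

    rows: Sequence[tuple[float, float, Material, float]]

    def __post_init__(self) -> None:
        rows = sorted(self.rows, key=lambda r: r[0])
        for (a0, b0, *_), (a1, b1, *_) in zip(rows, rows[1:]):
            if b0 > a1:
                raise ValueError("overlapping HU ranges")
        object.__setattr__(self, "rows", rows)

    def lookup(self, hu: float) -> tuple[Material, float]:
        for hu_min, hu_max, mat, dens in self.rows:
            if hu_min <= hu < hu_max:
                return mat, dens
        raise ValueError(f"HU value {hu} not covered by the mapping")


def apply_hu_mapping(hu_grid: np.ndarray, mapping: HUMapping,
                     origin_cm, spacing_cm) -> VoxelPhantom:
    """Segment a HU grid into a material/density phantom by range lookup."""
    hu = np.asarray(hu_grid, dtype=float)
    lo = min(r[0] for r in mapping.rows)
    hi = max(r[1] for r in mapping.rows)
    if hu.min() < lo or hu.max() >= hi:
        bad = hu.min() if hu.min() < lo else hu.max()
        raise ValueError(f"HU value {bad} not covered by the mapping")
    edges = np.array([r[0] for r in mapping.rows] + [hi])
    # searchsorted(right) - 1 gives the half-open range index
    idx = np.searchsorted(edges, hu, side="right") - 1
    # ranges need not be contiguous: verify each voxel's HU is inside its row
    row_lo = edges[:-1][idx]
    row_hi = np.array([r[1] for r in mapping.rows])[idx]
    if np.any(hu < row_lo) or np.any(hu >= row_hi):
        bad = hu[(hu < row_lo) | (hu >= row_hi)].flat[0]
        raise ValueError(f"HU value {bad} not covered by the mapping")
    materials = [r[2] for r in mapping.rows]
    dens_by_row = np.array([r[3] for r in mapping.rows])
    return VoxelPhantom(origin_cm=np.asarray(origin_cm, float),
                        spacing_cm=np.asarray(spacing_cm, float),
                        material_index=idx.astype(np.int16),
                        density=dens_by_row[idx],
                        materials=materials)


def ray_trace(phantom: VoxelPhantom, p_start, p_end) -> list[tuple[tuple, float]]:
    """Exact voxel traversal: ordered [(voxel ijk, chord length cm), ...].

    Chords sum to the length of the segment clipped to the grid bounds; a
    segment missing the grid returns an empty list.
    """
    p0 = np.asarray(p_start, dtype=np.float64)
    p1 = np.asarray(p_end, dtype=np.float64)
    seg = p1 - p0
    length = float(np.linalg.norm(seg))
    if length == 0:
        raise ValueError("degenerate segment")
    d = seg / length
    dims = np.array(phantom.dims, dtype=np.int64)
    nmax = int(dims.sum()) + 4
    idx_buf = np.empty(nmax, dtype=np.int64)
    chord_buf = np.empty(nmax, dtype=np.float64)
    n = ray_trace_kernel(p0, d, length, phantom.origin_cm, phantom.spacing_cm,
                         dims, idx_buf, chord_buf)
    ny, nz = phantom.dims[1], phantom.dims[2]
    out = []
    for t in range(n):
        flat = idx_buf[t]
        i = flat // (ny * nz)
        j = (flat // nz) % ny
        k = flat % nz
        out.append(((int(i), int(j), int(k)), float(chord_buf[t])))
    return out


def radiological_path(phantom: VoxelPhantom, p_start, p_end,
                      energy_kev: float) -> float:
    """Optical depth sum(chord * mu) along the segment (dimensionless).

    mu scales linearly with voxel density relative to the material table:
    per material the traversal accumulates the rho-weighted chord (areal
    density, g/cm^2), which is then multiplied by (mu/rho)(E).
    """
    p0 = np.asarray(p_start, dtype=np.float64)
    p1 = np.asarray(p_end, dtype=np.float64)
    seg = p1 - p0
    length = float(np.linalg.norm(seg))
    if length == 0:
        raise ValueError("degenerate segment")
    d = seg / length
    areal = np.zeros(len(phantom.materials))
    areal_path_kernel(p0, d, length, phantom.origin_cm, phantom.spacing_cm,
                      np.array(phantom.dims, dtype=np.int64),
                      phantom.material_index.ravel(), phantom.density.ravel(),
                      areal)
    return float(sum(
        areal[m] * phantom.materials[m].mass_attenuation(energy_kev)
        for m in range(len(phantom.materials)) if areal[m] > 0
    ))
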