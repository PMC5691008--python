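"""The rotating virtual CT source: spatially varying spectra + 2-D fluence.

The model combines three measured ingredients into a sampleable source:

* a lateral HVL profile, converted per position into a spectrum by matching
  aluminum filtration at the nominal kVp (beam hardening by the bow-tie);
* an in-air lateral dose profile, converted to relative photon fluence by
  dividing out each position's spectrum-dependent kerma integral
  (fluence_rel(x) = [D(x)/D(0)] * [K(0)/K(x)], K = sum counts*E*(mu_en/rho)_air);
* an axial dose profile, which equals the axial fluence directly because the
  spectrum is constant along z.

The two 1-D fluences are normalized to one and multiplied into a separable
2-D grid at the isocenter plane.  Photons are emitted from a point on the
rotation circle (radius SAD in the x-y plane) through a grid cell sampled by
inverse CDF with uniform in-cell jitter, with energy drawn from the spectrum
at the nearest |x| grid position.

Coordinates: isocenter at the origin, x lateral (bow-tie axis), z axial
(couch), y source axis at gantry angle 0; at gantry angle a the source sits
at (SAD sin a, SAD cos a, 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .hvl_measurement import HVLProfile
from .spectrum import Spectrum, air_kerma, fit_filtration, generate_spectrum

FORMAT_VERSION = "1"
PENUMBRA_CM = 0.4  # linear penumbra extension per field edge


@dataclass(frozen=True)
class SpectrumField:
    """One spectrum per |x| position along the bow-tie axis (uniform grid)."""

    x_positions_cm: np.ndarray  # 0, dx, 2dx, ...
    spectra: tuple
    kvp: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_positions_cm, float)
        if x[0] != 0.0 or np.any(np.diff(x) <= 0):
            raise ValueError("x positions must start at 0 and increase")
        dx = np.diff(x)
        if dx.size and not np.allclose(dx, dx[0]):
            raise ValueError("x positions must be uniformly spaced")
        for s in self.spectra:
            if s.kvp != self.kvp:
                raise ValueError("all spectra must share the field kVp")
            if s.energies.shape != self.spectra[0].energies.shape:
                raise ValueError("all spectra must share the energy grid")
        object.__setattr__(self, "x_positions_cm", x)

    @property
    def dx_cm(self) -> float:
        return float(self.x_positions_cm[1] - self.x_positions_cm[0]) \
            if len(self.x_positions_cm) > 1 else 1.0

    @property
    def energies(self) -> np.ndarray:
        return self.spectra[0].energies

    def nearest_index(self, x_cm: float) -> int:
        return min(int(round(abs(x_cm) / self.dx_cm)),
                   len(self.spectra) - 1)

    def spectrum_at(self, x_cm: float) -> Spectrum:
        """Spectrum at the nearest |x| grid position (lateral symmetry)."""
        return self.spectra[self.nearest_index(x_cm)]

    def pdf_matrix(self) -> np.ndarray:
        m = np.array([s.counts for s in self.spectra], dtype=float)
        return m / m.sum(axis=1, keepdims=True)

    def cdf_matrix(self) -> np.ndarray:
        return np.cumsum(self.pdf_matrix(), axis=1)


@dataclass(frozen=True)
class FluenceGrid:
    """Relative 2-D fluence at the isocenter plane (max cell = 1)."""

    x_centers_cm: np.ndarray
    z_centers_cm: np.ndarray
    values: np.ndarray          # (nx, nz)
    lateral: np.ndarray         # 1-D marginal over x (max 1)
    axial: np.ndarray           # 1-D marginal over z (max 1)
    separable: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(v < 0):
            raise ValueError("negative fluence")
        if v.shape != (len(self.x_centers_cm), len(self.z_centers_cm)):
            raise ValueError("grid shape mismatch")
        if not np.allclose(v, v[::-1, :], atol=1e-12):
            raise ValueError("fluence grid must be symmetric in x")

    @staticmethod
    def _edges(centers: np.ndarray) -> np.ndarray:
        d = centers[1] - centers[0] if len(centers) > 1 else 1.0
        return np.concatenate([centers - d / 2, [centers[-1] + d / 2]])

    @property
    def x_edges(self) -> np.ndarray:
        return self._edges(np.asarray(self.x_centers_cm, float))

    @property
    def z_edges(self) -> np.ndarray:
        return self._edges(np.asarray(self.z_centers_cm, float))

    @property
    def norm(self) -> float:
        """sum(values * cell area): converts cell values to a density."""
        dx = self.x_edges[1] - self.x_edges[0]
        dz = self.z_edges[1] - self.z_edges[0]
        return float(self.values.sum() * dx * dz)

    def marginal_cdfs(self) -> tuple[np.ndarray, np.ndarray]:
        lx = self.values.sum(axis=1)
        az = self.values.sum(axis=0)
        return np.cumsum(lx) / lx.sum(), np.cumsum(az) / az.sum()


@dataclass
class SourceModel:
    """Rotating virtual source: SAD circle + spectrum field + fluence grid."""

    sad_cm: float
    kvp: float
    spectrum_field: SpectrumField
    fluence_grid: FluenceGrid
    collimation_z_cm: float
    profile_z_cm: float | None = None
    rotating: bool = True

    def __post_init__(self) -> None:
        if self.sad_cm <= 0:
            raise ValueError("SAD must be positive")
        if self.profile_z_cm is None:
            self.profile_z_cm = float(
                self.fluence_grid.z_edges[-1] - self.fluence_grid.z_edges[0])
        if self.profile_z_cm < self.collimation_z_cm - 1e-9:
            raise ValueError("axial profile narrower than the collimation")


def build_spectrum_field(kvp: float, hvl_profile: HVLProfile,
                         x_grid: Sequence[float]) -> SpectrumField:
    """Per-position spectra by HVL-matched filtration at the nominal kVp."""
    x = np.asarray(x_grid, dtype=float)
    spectra = tuple(
        generate_spectrum(kvp, fit_filtration(kvp, float(hvl_profile(xi))))
        for xi in x
    )
    return SpectrumField(x_positions_cm=x, spectra=spectra, kvp=kvp)


def derive_lateral_fluence(air_dose_x, spectrum_field: SpectrumField):
    """Relative lateral fluence from in-air dose and the local spectra.

    ``air_dose_x`` is an (n, 2) array of (x_cm, relative dose) including
    x = 0.  Returns (x, fluence_rel) with fluence_rel(0) = 1.
    """
    arr = np.asarray(air_dose_x, dtype=float)
    xs, ds = arr[:, 0], arr[:, 1]
    i0 = np.argmin(np.abs(xs))
    if abs(xs[i0]) > 1e-9:
        raise ValueError("lateral dose profile requires a value at x = 0")
    if ds[i0] <= 0:
        raise ValueError("zero dose at x = 0")
    kermas = np.array([
        air_kerma(spectrum_field.spectrum_at(x)) for x in xs
    ])
    if kermas[i0] <= 0:
        raise ValueError("zero kerma integral at x = 0")
    if np.any(kermas <= 0):
        raise ValueError("zero kerma integral off axis")
    fluence = (ds / ds[i0]) * (kermas[i0] / kermas)
    return xs, fluence


def derive_axial_fluence(air_dose_z):
    """Relative axial fluence: the dose ratio to the central axis (z = 0)."""
    arr = np.asarray(air_dose_z, dtype=float)
    zs, ds = arr[:, 0], arr[:, 1]
    i0 = np.argmin(np.abs(zs))
    if abs(zs[i0]) > 1e-9:
        raise ValueError("axial dose profile requires a value at z = 0")
    if ds[i0] <= 0:
        raise ValueError("zero dose on the central axis")
    return zs, ds / ds[i0]


def default_axial_profile(collimation_z_cm: float,
                          penumbra_cm: float = PENUMBRA_CM,
                          dz_cm: float = 0.1):
    """Trapezoidal stand-in axial profile: flat field + linear penumbra.

    Unit fluence inside the nominal field, falling linearly to zero over
    ``penumbra_cm`` beyond each field edge (support = collimation + 2*penumbra).
    """
    zmax = collimation_z_cm / 2 + penumbra_cm
    n = int(round(zmax / dz_cm))
    z = np.linspace(-zmax, zmax, 2 * n + 1)
    v = np.clip((zmax - np.abs(z)) / penumbra_cm, 0.0, 1.0)
    return z, v


def resample_profile(x, v, dx_cm: float, symmetric: bool = False):
    """Cubic-spline resampling of a 1-D profile onto a uniform grid."""
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    if symmetric and x.min() >= 0:
        x = np.concatenate([-x[:0:-1], x])
        v = np.concatenate([v[:0:-1], v])
    order = np.argsort(x)
    spline = CubicSpline(x[order], v[order])
    n = int(np.floor((x.max() - x.min()) / dx_cm))
    xi = x.min() + (np.arange(n) + 0.5) * dx_cm
    return xi, np.clip(spline(xi), 0.0, None)


def build_fluence_grid(lateral, axial) -> FluenceGrid:
    """Outer-product 2-D fluence from two 1-D profiles (each max-normalized).

    ``lateral`` and ``axial`` are (positions, values) pairs; a lateral
    profile given on x >= 0 is mirrored about the isocenter.
    """
    lx, lv = (np.asarray(a, float) for a in lateral)
    az, av = (np.asarray(a, float) for a in axial)
    if lx.min() >= 0:
        lx = np.concatenate([-lx[:0:-1], lx])
        lv = np.concatenate([lv[:0:-1], lv])
    lv = 0.5 * (lv + lv[::-1])  # enforce exact lateral symmetry
    lv = lv / lv.max()
    av = av / av.max()
    values = np.outer(lv, av)
    return FluenceGrid(x_centers_cm=lx, z_centers_cm=az, values=values,
                       lateral=lv, axial=av, separable=True)


def characterize_source(kvp: float, sad_cm: float, measurements,
                        air_dose_x, air_dose_z, collimation_z_cm: float,
                        lateral_dx_cm: float = 0.25,
                        axial_dz_cm: float = 0.1,
                        rotating: bool = True) -> SourceModel:
    """Full characterization: HVL campaign + in-air dose -> SourceModel.

    ``measurements`` are HVLMeasurement objects (or (x, hvl) pairs) on a
    uniform lateral grid; ``air_dose_x``/``air_dose_z`` are (n, 2) arrays of
    (position, relative dose).  The lateral fluence is derived with the
    HVL-matched local spectra, both fluence profiles are spline-resampled
    onto fine uniform grids, and the separable 2-D grid is assembled.
    """
    from .hvl_measurement import build_hvl_profile

    profile = build_hvl_profile(measurements)
    arr = np.asarray(air_dose_x, dtype=float)
    field = build_spectrum_field(kvp, profile, np.sort(np.abs(arr[:, 0])))
    lat_x, lat_f = derive_lateral_fluence(air_dose_x, field)
    lat = resample_profile(lat_x, lat_f, lateral_dx_cm, symmetric=True)
    ax_z, ax_f = derive_axial_fluence(air_dose_z)
    ax = resample_profile(ax_z, ax_f, axial_dz_cm)
    grid = build_fluence_grid(lat, ax)
    return SourceModel(sad_cm=sad_cm, kvp=kvp, spectrum_field=field,
                       fluence_grid=grid, collimation_z_cm=collimation_z_cm,
                       rotating=rotating)


def sample_photons(model: SourceModel, n: int, rng: np.random.Generator):
    """Vectorized photon sampling: (origins, directions, energies, weights).

    Gantry angle uniform on [0, 2pi) (or 0 for a static model); the
    isocenter-plane point by inverse CDF over the fluence grid with uniform
    in-cell jitter; energy from the spectrum at the nearest |x| position.
    The fluence bias is carried by the sampling density, so weights are 1.
    """
    if not isinstance(rng, np.random.Generator):
        raise ValueError("pass a seeded numpy Generator")
    grid = model.fluence_grid
    lat_cdf, ax_cdf = grid.marginal_cdfs()
    xe, ze = grid.x_edges, grid.z_edges
    ix = np.searchsorted(lat_cdf, rng.random(n))
    iz = np.searchsorted(ax_cdf, rng.random(n))
    ix = np.minimum(ix, len(lat_cdf) - 1)
    iz = np.minimum(iz, len(ax_cdf) - 1)
    xs = xe[ix] + rng.random(n) * (xe[ix + 1] - xe[ix])
    zs = ze[iz] + rng.random(n) * (ze[iz + 1] - ze[iz])
    alpha = rng.random(n) * 2 * np.pi if model.rotating else np.zeros(n)
    ca, sa = np.cos(alpha), np.sin(alpha)
    field = model.spectrum_field
    cdfs = field.cdf_matrix()
    ipos = np.minimum(np.round(np.abs(xs) / field.dx_cm).astype(int),
                      len(field.spectra) - 1)
    u = rng.random(n)
    ib = np.empty(n, dtype=int)
    for p in np.unique(ipos):
        sel = ipos == p
        ib[sel] = np.searchsorted(cdfs[p], u[sel])
    ib = np.minimum(ib, cdfs.shape[1] - 1)
    energies = field.energies[ib]
    origins = np.column_stack([model.sad_cm * sa, model.sad_cm * ca,
                               np.zeros(n)])
    plane = np.column_stack([xs * ca, -xs * sa, zs])
    dirs = plane - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return origins, dirs, energies, np.ones(n)


def sample_photon(model: SourceModel, rng: np.random.Generator):
    """Single-photon convenience wrapper around :func:`sample_photons`."""
    o, d, e, w = sample_photons(model, 1, rng)
    return o[0], d[0], float(e[0]), float(w[0])


def save_model(model: SourceModel, path: str | Path) -> None:
    field = model.spectrum_field
    grid = model.fluence_grid
    doc = {
        "version": FORMAT_VERSION,
        "sad_cm": model.sad_cm,
        "kvp": model.kvp,
        "collimation_z_cm": model.collimation_z_cm,
        "profile_z_cm": model.profile_z_cm,
        "rotating": model.rotating,
        "spectrum_field": {
            "x_positions_cm": field.x_positions_cm.tolist(),
            "energies_keV": field.energies.tolist(),
            "counts": [s.counts.tolist() for s in field.spectra],
            "filtration_mm_al": [s.filtration_mm_al for s in field.spectra],
        },
        "fluence_grid": {
            "x_centers_cm": np.asarray(grid.x_centers_cm).tolist(),
            "z_centers_cm": np.asarray(grid.z_centers_cm).tolist(),
            "lateral": np.asarray(grid.lateral).tolist(),
            "axial": np.asarray(grid.axial).tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> SourceModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("version")
    if version != FORMAT_VERSION:
        warnings.warn(
            f"model file version {version!r} != {FORMAT_VERSION!r}; "
            "attempting best-effort load"
        )
    for key in ("sad_cm", "kvp", "collimation_z_cm",
                "spectrum_field", "fluence_grid"):
        if key not in doc:
            raise ValueError(f"model file missing required field: {key}")
    sf = doc["spectrum_field"]
    energies = np.array(sf["energies_keV"])
    spectra = tuple(
        Spectrum(kvp=doc["kvp"], energies=energies, counts=np.array(c),
                 filtration_mm_al=f)
        for c, f in zip(sf["counts"], sf["filtration_mm_al"])
    )
    field = SpectrumField(x_positions_cm=np.array(sf["x_positions_cm"]),
                          spectra=spectra, kvp=doc["kvp"])
    fg = doc["fluence_grid"]
    grid = build_fluence_grid(
        (np.array(fg["x_centers_cm"]), np.array(fg["lateral"])),
        (np.array(fg["z_centers_cm"]), np.array(fg["axial"])),
    )
    return SourceModel(sad_cm=doc["sad_cm"], kvp=doc["kvp"],
                       spectrum_field=field, fluence_grid=grid,
                       collimation_z_cm=doc["collimation_z_cm"],
                       profile_z_cm=doc.get("profile_z_cm"),
                       rotating=doc.get("rotating", True))
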