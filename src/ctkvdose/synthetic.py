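"""Synthetic scanners, measurement campaigns, phantoms and an analog oracle.

Everything the characterization + dose pipeline consumes can be generated
here with known ground truth: a parametric bow-tie scanner (Al-equivalent
filtration rising quadratically off axis), simulated HVL and in-air dose
measurement campaigns with optional multiplicative chamber noise, the
cylindrical PMMA validation fixture with its 13 chamber positions, a
five-material thorax stand-in, and a brute-force analog Monte Carlo oracle
(no forcing, no next-event estimation) for cross-checking the dose engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import HUMapping, VoxelPhantom, build_cylinder_phantom
from .hvl_measurement import HVLMeasurement, oblique_angle
from .materials import get_material
from .source_model import SourceModel, default_axial_profile
from .spectrum import air_kerma, attenuate, compute_hvl, generate_spectrum
from ._kernels import MEC2_KEV, HC_KEV_A, E_CUTOFF_KEV

PMMA_DIAMETER_CM = 15.2
PMMA_DEPTHS_CM = (1.0, 2.5, 4.0)   # alpha, beta, gamma ring depths
PMMA_RING_ANGLES = (0.0, 90.0, 180.0, 270.0)


@dataclass(frozen=True)
class SyntheticScanner:
    """Ground-truth bow-tie scanner used to drive simulated campaigns.

    The bow-tie filter is ``al_mm(x) = bowtie_a_mm + bowtie_b * x^2`` (x in
    cm), an even function producing HVL growth with |x|; the true lateral
    fluence is a smooth bell ``exp(-x^2 / (2 sigma^2))`` and the true axial
    fluence a trapezoid: flat across the collimated field with 0.4 cm linear
    penumbra shoulders per side.
    """

    kvp: float = 120.0
    sad_cm: float = 64.5
    bowtie_a_mm: float = 2.0
    bowtie_b: float = 0.05
    fluence_sigma_cm: float = 12.0
    collimation_z_cm: float = 2.0
    penumbra_cm: float = 0.4

    def bowtie_al_mm(self, x_cm) -> np.ndarray:
        return self.bowtie_a_mm + self.bowtie_b * np.asarray(x_cm, float) ** 2

    def true_fluence_x(self, x_cm):
        x = np.asarray(x_cm, float)
        return np.exp(-(x**2) / (2 * self.fluence_sigma_cm**2))

    def true_fluence_z(self, z_cm):
        z = np.abs(np.asarray(z_cm, float))
        zmax = self.collimation_z_cm / 2 + self.penumbra_cm
        return np.clip((zmax - z) / self.penumbra_cm, 0.0, 1.0)

    def local_spectrum(self, x_cm: float):
        return generate_spectrum(self.kvp, float(self.bowtie_al_mm(x_cm)))


def simulate_hvl_campaign(scanner: SyntheticScanner, x_positions,
                          noise_rel: float = 0.0,
                          seed: int | None = None) -> list[HVLMeasurement]:
    """Simulated two-point HVL measurements along the bow-tie axis.

    For each position the local (bow-tie-hardened) spectrum is generated,
    slab thicknesses bracketing its true HVL are chosen, and the three
    chamber readings are produced by oblique Beer-Lambert attenuation with
    multiplicative Gaussian noise of relative width ``noise_rel``.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    rng = np.random.default_rng(seed)
    al = get_material("aluminum")
    out = []
    for x in x_positions:
        spec = scanner.local_spectrum(x)
        hvl = compute_hvl(spec)
        theta = oblique_angle(x, scanner.sad_cm)
        cos_t = math.cos(theta)
        t1_mm = 0.9 * hvl * cos_t   # nominal thickness: oblique path 0.9 HVL
        t2_mm = 1.1 * hvl * cos_t   # close bracketing keeps the two-point
        # interpolation error well below the chamber noise
        d0 = air_kerma(spec)
        d1 = air_kerma(attenuate(spec, al, t1_mm / cos_t / 10.0))
        d2 = air_kerma(attenuate(spec, al, t2_mm / cos_t / 10.0))
        if noise_rel > 0:
            d0, d1, d2 = (d * (1.0 + noise_rel * rng.standard_normal())
                          for d in (d0, d1, d2))
        out.append(HVLMeasurement(x_cm=float(x), T1_mm=t1_mm, T2_mm=t2_mm,
                                  D0=d0, D1=d1, D2=d2, theta_rad=theta))
    return out


def simulate_air_dose_profiles(scanner: SyntheticScanner, x_positions,
                               z_positions):
    """In-air dose profiles D(x, z=0) and D(x=0, z), center-normalized.

    The lateral profile is the true fluence times the local kerma integral
    (the spectrum varies with x); along z the spectrum is constant so the
    dose profile is the axial fluence itself.
    """
    xs = np.asarray(x_positions, float)
    zs = np.asarray(z_positions, float)
    if not np.any(np.isclose(xs, 0.0)) or not np.any(np.isclose(zs, 0.0)):
        raise ValueError("profiles must include the isocenter (0)")
    kermas = np.array([air_kerma(scanner.local_spectrum(x)) for x in xs])
    dx = scanner.true_fluence_x(xs) * kermas
    i0 = int(np.argmin(np.abs(xs)))
    dx = dx / dx[i0]
    dz = scanner.true_fluence_z(zs)
    j0 = int(np.argmin(np.abs(zs)))
    dz = dz / dz[j0]
    return np.column_stack([xs, dx]), np.column_stack([zs, dz])


def make_pmma_cylinder_fixture(spacing_cm: float = 0.2,
                               length_cm: float = 15.0):
    """The 15.2 cm PMMA validation cylinder and its 13 chamber positions.

    Rings at depths 1, 2.5 and 4 cm below the surface (radii 6.6, 5.1 and
    3.6 cm) at four 90-degree-spaced angles, plus the center; all at z = 0.
    Returns (phantom, pois (13, 3), names).
    """
    phantom = build_cylinder_phantom(PMMA_DIAMETER_CM, length_cm,
                                     get_material("pmma"),
                                     spacing_cm=spacing_cm)
    radius = PMMA_DIAMETER_CM / 2
    pois = [(0.0, 0.0, 0.0)]
    names = ["C"]
    ring_names = ("alpha", "beta", "gamma")
    for depth, ring in zip(PMMA_DEPTHS_CM, ring_names):
        r = radius - depth
        for ang in PMMA_RING_ANGLES:
            a = math.radians(ang)
            # round away trig residue so axis points are exactly on-axis
            pois.append((round(r * math.cos(a), 12),
                         round(r * math.sin(a), 12), 0.0))
            names.append(f"{ring}_{int(ang)}")
    return phantom, np.array(pois), names


# --- thorax stand-in ------------------------------------------------------

_THORAX_HU = {"air": -1000.0, "lung": -750.0, "soft": 0.0,
              "tumor": 20.0, "cancellous": 300.0, "cortical": 800.0}


def thorax_hu_mapping() -> HUMapping:
    """Documented HU breakpoints for the five-material segmentation."""
    return HUMapping(rows=[
        (-1100.0, -900.0, get_material("air"), 0.0012047),
        (-900.0, -400.0, get_material("lung"), 0.26),
        (-400.0, 150.0, get_material("soft_tissue"), 1.06),
        (150.0, 500.0, get_material("cancellous_bone"), 1.18),
        (500.0, 2000.0, get_material("cortical_bone"), 1.92),
    ])


@dataclass(frozen=True)
class ThoraxFixture:
    hu_grid: np.ndarray
    origin_cm: np.ndarray
    spacing_cm: np.ndarray
    mapping: HUMapping
    pois: np.ndarray
    poi_names: tuple
    material_counts: dict


def make_thorax_fixture(spacing_cm: float = 0.25) -> ThoraxFixture:
    """Synthetic thorax: elliptical body, two lungs with tumors, vertebra.

    An elliptical soft-tissue body holds two low-density lung volumes (each
    containing a soft-tissue "tumor" sphere), a vertebra with a cortical
    shell and cancellous core, on an air background.  Six named POIs mirror
    a thorax measurement layout, two of them (1 and 4) off the nominal
    axial field edge.
    """
    hx, hy, hz = 16.0, 10.0, 5.0
    nx = int(2 * hx / spacing_cm)
    ny = int(2 * hy / spacing_cm)
    nz = int(2 * hz / spacing_cm)
    origin = np.array([-hx, -hy, -hz])
    spacing = np.array([spacing_cm] * 3)
    x = origin[0] + (np.arange(nx) + 0.5) * spacing_cm
    y = origin[1] + (np.arange(ny) + 0.5) * spacing_cm
    z = origin[2] + (np.arange(nz) + 0.5) * spacing_cm
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    hu = np.full((nx, ny, nz), _THORAX_HU["air"])
    body = (xx / 14.0) ** 2 + (yy / 8.0) ** 2 <= 1.0
    hu[body] = _THORAX_HU["soft"]
    for cx in (-6.5, 6.5):
        lung = ((xx - cx) / 4.5) ** 2 + ((yy - 1.0) / 3.5) ** 2 <= 1.0
        hu[lung & body] = _THORAX_HU["lung"]
    tum_l = (xx - 6.5) ** 2 + (yy - 1.0) ** 2 + zz**2 <= 1.5**2
    tum_s = (xx + 6.5) ** 2 + (yy - 1.0) ** 2 + (zz - 3.0) ** 2 <= 0.75**2
    hu[tum_l | tum_s] = _THORAX_HU["tumor"]
    vert = (xx**2 + (yy + 5.0) ** 2) <= 1.8**2
    core = (xx**2 + (yy + 5.0) ** 2) <= 1.1**2
    hu[vert & body] = _THORAX_HU["cortical"]
    hu[core & body] = _THORAX_HU["cancellous"]

    mapping = thorax_hu_mapping()
    counts = {}
    for lo_hu, hi_hu, mat, _ in mapping.rows:
        counts[mat.name] = int(np.sum((hu >= lo_hu) & (hu < hi_hu)))

    pois = np.array([
        (10.0, 0.0, 3.0),    # 1: soft tissue, off the axial field edge
        (-6.5, 2.5, 0.0),    # 2: lung
        (6.5, 1.0, 0.0),     # 3: large tumor
        (-6.5, 1.0, 3.0),    # 4: small tumor, off the axial field edge
        (0.0, -5.0, 0.0),    # 5: vertebra (cancellous core)
        (0.0, -3.2, 0.0),    # 6: cord region (normalization point)
    ])
    names = ("soft_offfield", "lung", "tumor_large", "tumor_small_offfield",
             "vertebra", "cord")
    return ThoraxFixture(hu_grid=hu, origin_cm=origin, spacing_cm=spacing,
                         mapping=mapping, pois=pois, poi_names=names,
                         material_counts=counts)


# --- analog Monte Carlo oracle -------------------------------------------

@dataclass(frozen=True)
class OracleResult:
    primary: float
    first_scatter: float
    multi_scatter: float
    sigma_primary: float
    sigma_first: float
    sigma_multi: float

    @property
    def total(self) -> float:
        return self.primary + self.first_scatter + self.multi_scatter


def analog_mc_oracle(model: SourceModel, phantom: VoxelPhantom, poi,
                     n_histories: int, seed: int,
                     tally_radius_cm: float = 0.5,
                     n_batches: int = 10,
                     max_generations: int = 40) -> OracleResult:
    """Brute-force analog transport with a track-length sphere tally.

    Unbiased reference for the dose engine: photons are sampled from the
    same source model, free paths are sampled analog (no forcing), angles
    from the same Klein-Nishina / form-factor laws, and collision kerma is
    tallied by track length through a small sphere around the POI.  The
    phantom must be homogeneous (one material, uniform density); segments
    by generation give the primary (unscattered), first-scatter and
    multiscatter components per emitted photon.
    """
    from .source_model import sample_photons

    mat_idx = np.unique(phantom.material_index)
    dens = np.unique(phantom.density)
    if len(mat_idx) != 1 or len(dens) != 1:
        raise ValueError("the analog oracle requires a homogeneous phantom")
    material = phantom.materials[int(mat_idx[0])].with_density(float(dens[0]))
    lo = phantom.origin_cm
    hi = phantom.upper_cm
    center = np.asarray(poi, float)
    vol = 4.0 / 3.0 * np.pi * tally_radius_cm**3

    e_grid = np.arange(1.0, 150.5, 0.5)
    mu_tot_t = material.linear_attenuation(e_grid)
    mu_pe_t = material.linear_attenuation(e_grid, "pe")
    mu_coh_t = material.linear_attenuation(e_grid, "coh")
    mu_en_t = material.mass_energy_absorption(e_grid)

    def look(table, e):
        return np.interp(e, e_grid, table)

    x0 = 0.43 * material.effective_z() ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    per_batch = n_histories // n_batches
    tallies = np.zeros((n_batches, 3))
    for b in range(n_batches):
        tallies[b] = _oracle_batch(model, per_batch, rng, lo, hi, center,
                                   tally_radius_cm, vol, look, mu_tot_t,
                                   mu_pe_t, mu_coh_t, mu_en_t, x0,
                                   max_generations)
    per = tallies / per_batch
    mean = per.mean(axis=0)
    sig = per.std(axis=0, ddof=1) / np.sqrt(n_batches)
    if np.all(mean == 0):
        raise ValueError("zero tally; increase n_histories or the tally radius")
    return OracleResult(primary=mean[0], first_scatter=mean[1],
                        multi_scatter=mean[2], sigma_primary=sig[0],
                        sigma_first=sig[1], sigma_multi=sig[2])


def _box_clip(p, d, lo, hi):
    t0 = np.zeros(len(p))
    t1 = np.full(len(p), np.inf)
    for ax in range(3):
        da = d[:, ax]
        pa = p[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[ax] - pa) / da
            tb = (hi[ax] - pa) / da
        swap = ta > tb
        ta[swap], tb[swap] = tb[swap], ta[swap]
        par = np.abs(da) < 1e-300
        inside = (pa >= lo[ax]) & (pa < hi[ax])
        ta[par] = np.where(inside[par], -np.inf, np.inf)
        tb[par] = np.where(inside[par], np.inf, -np.inf)
        t0 = np.maximum(t0, ta)
        t1 = np.minimum(t1, tb)
    return t0, t1


def _sphere_chord(p, d, t_start, t_end, center, radius):
    rel = p - center
    bq = np.einsum("ij,ij->i", rel, d)
    cq = np.einsum("ij,ij->i", rel, rel) - radius**2
    disc = bq**2 - cq
    hit = disc > 0
    chord = np.zeros(len(p))
    if np.any(hit):
        sq = np.sqrt(disc[hit])
        ta = np.maximum(-bq[hit] - sq, t_start[hit])
        tb = np.minimum(-bq[hit] + sq, t_end[hit])
        chord[hit] = np.maximum(tb - ta, 0.0)
    return chord


def _sample_kn_vec(e, rng):
    """Vectorized Kahn sampling of the Klein-Nishina angle."""
    k = e / MEC2_KEV
    cos_t = np.empty_like(e)
    todo = np.arange(len(e))
    while len(todo):
        kk = k[todo]
        r1, r2, r3 = rng.random((3, len(todo)))
        branch = r1 <= (1 + 2 * kk) / (9 + 2 * kk)
        x = np.where(branch, 1 + 2 * kk * r2, (1 + 2 * kk) / (1 + 2 * kk * r2))
        ct = 1 - (x - 1) / kk
        acc = np.where(branch, r3 <= 4 * (1 / x - 1 / x**2),
                       r3 <= 0.5 * (ct**2 + 1 / x))
        cos_t[todo[acc]] = ct[acc]
        todo = todo[~acc]
    return cos_t


def _sample_coh_vec(e, x0, rng):
    xmax2 = (e / HC_KEV_A) ** 2
    a = x0 * x0
    big_a = 1.0 - (1.0 + xmax2 / a) ** (-3.0)
    cos_t = np.empty_like(e)
    todo = np.arange(len(e))
    while len(todo):
        r1, r2 = rng.random((2, len(todo)))
        u = a * ((1.0 - big_a[todo] * r1) ** (-1.0 / 3.0) - 1.0)
        ct = 1.0 - 2.0 * u / xmax2[todo]
        acc = r2 <= 0.5 * (1.0 + ct**2)
        cos_t[todo[acc]] = ct[acc]
        todo = todo[~acc]
    return cos_t


def _rotate_vec(d, cos_t, phi):
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, None))
    u = np.zeros_like(d)
    steep = np.abs(d[:, 2]) >= 0.99999
    u[~steep, 0] = -d[~steep, 1]
    u[~steep, 1] = d[~steep, 0]
    u[steep, 0] = 1.0
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (sin_t * (np.cos(phi) * u.T + np.sin(phi) * v.T)
            + cos_t * d.T).T


def _oracle_batch(model, n, rng, lo, hi, center, radius, vol, look,
                  mu_tot_t, mu_pe_t, mu_coh_t, mu_en_t, x0, max_gen):
    from .source_model import sample_photons

    p, d, e, _ = sample_photons(model, n, rng)
    tally = np.zeros(3)
    generation = 0
    while len(e) and generation <= max_gen:
        t0, t1 = _box_clip(p, d, lo, hi)
        valid = t1 > np.maximum(t0, 0.0)
        p, d, e, t0, t1 = p[valid], d[valid], e[valid], t0[valid], t1[valid]
        if not len(e):
            break
        t0 = np.maximum(t0, 0.0)
        mu = look(mu_tot_t, e)
        with np.errstate(divide="ignore"):
            s_col = t0 - np.log(1.0 - rng.random(len(e))) / mu
        seg_end = np.minimum(s_col, t1)
        chord = _sphere_chord(p, d, t0, seg_end, center, radius)
        comp = min(generation, 2)
        tally[comp] += np.sum(chord * e * look(mu_en_t, e)) / vol
        collided = s_col < t1
        p = p[collided] + d[collided] * s_col[collided, None]
        d, e = d[collided], e[collided]
        if not len(e):
            break
        # channel selection
        u = rng.random(len(e)) * look(mu_tot_t, e)
        pe_cut = look(mu_pe_t, e)
        coh_cut = pe_cut + look(mu_coh_t, e)
        alive = u >= pe_cut
        p, d, e, u, coh_cut = p[alive], d[alive], e[alive], u[alive], \
            coh_cut[alive]
        if not len(e):
            break
        is_coh = u < coh_cut
        cos_t = np.empty(len(e))
        if np.any(is_coh):
            cos_t[is_coh] = _sample_coh_vec(e[is_coh], x0, rng)
        if np.any(~is_coh):
            cos_t[~is_coh] = _sample_kn_vec(e[~is_coh], rng)
            k = e[~is_coh] / MEC2_KEV
            e[~is_coh] = e[~is_coh] / (1 + k * (1 - cos_t[~is_coh]))
        d = _rotate_vec(d, cos_t, rng.random(len(e)) * 2 * np.pi)
        keep = e >= E_CUTOFF_KEV
        p, d, e = p[keep], d[keep], e[keep]
        generation += 1
    return tally


def write_campaign(scanner: SyntheticScanner, outdir: str | Path,
                   noise_rel: float = 0.005, seed: int = 0,
                   x_step_cm: float = 2.0, x_max_cm: float = 18.0) -> Path:
    """Emit a complete synthetic campaign directory.

    Writes hvl.csv, airdose_x.csv, airdose_z.csv, the PMMA fixture phantom
    (NRRD + JSON), pois.csv and truth.json (the generating parameters).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    xs = np.arange(0.0, x_max_cm + x_step_cm / 2, x_step_cm)
    meas = simulate_hvl_campaign(scanner, xs, noise_rel=noise_rel, seed=seed)
    with open(outdir / "hvl.csv", "w") as fh:
        fh.write("x_cm,T1_mm,T2_mm,D0,D1,D2\n")
        for m in meas:
            fh.write(f"{m.x_cm:g},{m.T1_mm:.6f},{m.T2_mm:.6f},"
                     f"{m.D0:.8e},{m.D1:.8e},{m.D2:.8e}\n")
    zs = default_axial_profile(scanner.collimation_z_cm,
                               scanner.penumbra_cm)[0]
    ax_x, ax_z = simulate_air_dose_profiles(scanner, xs, zs)
    np.savetxt(outdir / "airdose_x.csv", ax_x, delimiter=",",
               header="x_cm,dose_rel", comments="")
    np.savetxt(outdir / "airdose_z.csv", ax_z, delimiter=",",
               header="z_cm,dose_rel", comments="")
    phantom, pois, names = make_pmma_cylinder_fixture()
    phantom.save(outdir / "phantom")
    with open(outdir / "pois.csv", "w") as fh:
        fh.write("name,x_cm,y_cm,z_cm\n")
        for nm, p in zip(names, pois):
            fh.write(f"{nm},{p[0]:.4f},{p[1]:.4f},{p[2]:.4f}\n")
    truth = {
        "kvp": scanner.kvp, "sad_cm": scanner.sad_cm,
        "bowtie_a_mm": scanner.bowtie_a_mm, "bowtie_b": scanner.bowtie_b,
        "fluence_sigma_cm": scanner.fluence_sigma_cm,
        "collimation_z_cm": scanner.collimation_z_cm,
        "penumbra_cm": scanner.penumbra_cm,
        "noise_rel": noise_rel, "seed": seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
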