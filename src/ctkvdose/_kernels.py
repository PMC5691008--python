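"""Numba kernels: voxel ray traversal and photon transport.

Energy-dependent coefficients enter as per-material rows tabulated on a fine
grid (1 to 150 keV in 0.5 keV steps, linear interpolation).  Mass (not
linear) coefficients are used throughout: traversals accumulate per-material
rho-weighted chords (areal densities, g/cm^2), so voxel densities scale the
attenuation without per-voxel tables.

The scatter kernel implements the biased-MC contract: photons are sampled
from the rotating-source distributions (with importance tilts carried as
weights), every flight's collision is forced inside the grid, the first
collision is additionally stratified in optical depth, and every
scattering vertex scores a channel-expected next-event estimate to each
point of interest.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEC2_KEV = 510.99895
R_E2_BARN = 0.07940775  # classical electron radius squared (barns/sr scale)
HC_KEV_A = 12.39842     # keV * Angstrom; x = sin(theta/2) * E / hc in 1/A

EF0 = 1.0    # fine energy grid start, keV
DEF = 0.5    # fine grid step
NEF = 299    # grid points: 1.0 .. 150.0

E_CUTOFF_KEV = 5.0
W_CUTOFF = 1e-4
RR_THRESHOLD = 0.05
RR_SURVIVE = 0.25
MAX_VERTICES = 1000
FC_STRATA = 6  # equal-probability optical-depth strata for the first collision
# Bounded point-detector radius: inside this sphere the 1/r^2 kernel is
# replaced by its volume average (standard next-event-estimator treatment;
# tames the otherwise infinite variance of vertices adjacent to a POI).
NEE_R0_CM = 0.8


@njit(cache=True, inline="always")
def _vdc(n, base):
    """Van der Corput radical inverse of n in the given base."""
    v = 0.0
    denom = 1.0
    while n > 0:
        denom *= base
        v += (n % base) / denom
        n //= base
    return v


def fine_energy_grid() -> np.ndarray:
    return EF0 + DEF * np.arange(NEF)


@njit(cache=True, inline="always")
def _interp_row(row, e):
    t = (e - EF0) / DEF
    i = int(t)
    if i < 0:
        return row[0]
    if i >= NEF - 1:
        return row[NEF - 1]
    f = t - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(cache=True, inline="always")
def _clip_box(px, py, pz, dx, dy, dz, ox, oy, oz, ux, uy, uz, tmax):
    """Intersection [t0, t1] of ray p + t*d, t in [0, tmax], with the box."""
    t0 = 0.0
    t1 = tmax
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = px, dx, ox, ux
        elif axis == 1:
            p, d, lo, hi = py, dy, oy, uy
        else:
            p, d, lo, hi = pz, dz, oz, uz
        if abs(d) < 1e-300:
            if p < lo or p >= hi:
                return 1.0, 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def ray_trace_kernel(p0, d, length, origin, spacing, dims, idx_buf, chord_buf):
    """Amanatides-Woo traversal; fills flat voxel indices and chords."""
    ox, oy, oz = origin[0], origin[1], origin[2]
    ux = ox + spacing[0] * dims[0]
    uy = oy + spacing[1] * dims[1]
    uz = oz + spacing[2] * dims[2]
    t0, t1 = _clip_box(p0[0], p0[1], p0[2], d[0], d[1], d[2],
                       ox, oy, oz, ux, uy, uz, length)
    if t1 <= t0 + 1e-14:
        return 0
    eps = 1e-10 * max(spacing[0], max(spacing[1], spacing[2]))
    sx = p0[0] + d[0] * (t0 + eps)
    sy = p0[1] + d[1] * (t0 + eps)
    sz = p0[2] + d[2] * (t0 + eps)
    i = int((sx - ox) / spacing[0])
    j = int((sy - oy) / spacing[1])
    k = int((sz - oz) / spacing[2])
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i >= dims[0]:
        i = dims[0] - 1
    if j >= dims[1]:
        j = dims[1] - 1
    if k >= dims[2]:
        k = dims[2] - 1
    big = 1e300
    step_i = 1 if d[0] > 0 else -1
    step_j = 1 if d[1] > 0 else -1
    step_k = 1 if d[2] > 0 else -1
    tdx = spacing[0] / abs(d[0]) if d[0] != 0 else big
    tdy = spacing[1] / abs(d[1]) if d[1] != 0 else big
    tdz = spacing[2] / abs(d[2]) if d[2] != 0 else big
    if d[0] > 0:
        tmx = (ox + (i + 1) * spacing[0] - p0[0]) / d[0]
    elif d[0] < 0:
        tmx = (ox + i * spacing[0] - p0[0]) / d[0]
    else:
        tmx = big
    if d[1] > 0:
        tmy = (oy + (j + 1) * spacing[1] - p0[1]) / d[1]
    elif d[1] < 0:
        tmy = (oy + j * spacing[1] - p0[1]) / d[1]
    else:
        tmy = big
    if d[2] > 0:
        tmz = (oz + (k + 1) * spacing[2] - p0[2]) / d[2]
    elif d[2] < 0:
        tmz = (oz + k * spacing[2] - p0[2]) / d[2]
    else:
        tmz = big
    t = t0
    n = 0
    nynz = dims[1] * dims[2]
    while t < t1 - 1e-14:
        if tmx <= tmy and tmx <= tmz:
            tn = tmx
        elif tmy <= tmz:
            tn = tmy
        else:
            tn = tmz
        te = tn if tn < t1 else t1
        chord = te - t
        if chord > 0:
            idx_buf[n] = i * nynz + j * dims[2] + k
            chord_buf[n] = chord
            n += 1
        if te >= t1 - 1e-14:
            break
        if tmx <= tmy and tmx <= tmz:
            i += step_i
            tmx += tdx
            if i < 0 or i >= dims[0]:
                break
        elif tmy <= tmz:
            j += step_j
            tmy += tdy
            if j < 0 or j >= dims[1]:
                break
        else:
            k += step_k
            tmz += tdz
            if k < 0 or k >= dims[2]:
                break
        t = tn
    return n


@njit(cache=True)
def areal_path_kernel(p0, d, length, origin, spacing, dims, mat, rho, areal):
    """Accumulate per-material rho-weighted chords (g/cm^2) along a segment."""
    ox, oy, oz = origin[0], origin[1], origin[2]
    ux = ox + spacing[0] * dims[0]
    uy = oy + spacing[1] * dims[1]
    uz = oz + spacing[2] * dims[2]
    t0, t1 = _clip_box(p0[0], p0[1], p0[2], d[0], d[1], d[2],
                       ox, oy, oz, ux, uy, uz, length)
    if t1 <= t0 + 1e-14:
        return
    eps = 1e-10 * max(spacing[0], max(spacing[1], spacing[2]))
    sx = p0[0] + d[0] * (t0 + eps)
    sy = p0[1] + d[1] * (t0 + eps)
    sz = p0[2] + d[2] * (t0 + eps)
    i = min(max(int((sx - ox) / spacing[0]), 0), dims[0] - 1)
    j = min(max(int((sy - oy) / spacing[1]), 0), dims[1] - 1)
    k = min(max(int((sz - oz) / spacing[2]), 0), dims[2] - 1)
    big = 1e300
    step_i = 1 if d[0] > 0 else -1
    step_j = 1 if d[1] > 0 else -1
    step_k = 1 if d[2] > 0 else -1
    tdx = spacing[0] / abs(d[0]) if d[0] != 0 else big
    tdy = spacing[1] / abs(d[1]) if d[1] != 0 else big
    tdz = spacing[2] / abs(d[2]) if d[2] != 0 else big
    if d[0] > 0:
        tmx = (ox + (i + 1) * spacing[0] - p0[0]) / d[0]
    elif d[0] < 0:
        tmx = (ox + i * spacing[0] - p0[0]) / d[0]
    else:
        tmx = big
    if d[1] > 0:
        tmy = (oy + (j + 1) * spacing[1] - p0[1]) / d[1]
    elif d[1] < 0:
        tmy = (oy + j * spacing[1] - p0[1]) / d[1]
    else:
        tmy = big
    if d[2] > 0:
        tmz = (oz + (k + 1) * spacing[2] - p0[2]) / d[2]
    elif d[2] < 0:
        tmz = (oz + k * spacing[2] - p0[2]) / d[2]
    else:
        tmz = big
    t = t0
    nynz = dims[1] * dims[2]
    while t < t1 - 1e-14:
        if tmx <= tmy and tmx <= tmz:
            tn = tmx
        elif tmy <= tmz:
            tn = tmy
        else:
            tn = tmz
        te = tn if tn < t1 else t1
        chord = te - t
        if chord > 0:
            flat = i * nynz + j * dims[2] + k
            areal[mat[flat]] += chord * rho[flat]
        if te >= t1 - 1e-14:
            break
        if tmx <= tmy and tmx <= tmz:
            i += step_i
            tmx += tdx
            if i < 0 or i >= dims[0]:
                break
        elif tmy <= tmz:
            j += step_j
            tmy += tdy
            if j < 0 or j >= dims[1]:
                break
        else:
            k += step_k
            tmz += tdz
            if k < 0 or k >= dims[2]:
                break
        t = tn
    return


@njit(cache=True)
def _tau_and_collision(p0, d, origin, spacing, dims, mat, rho, mu_at_e,
                       tau_target):
    """One traversal to grid exit returning (tau_total, s_collision, flat_idx).

    If ``tau_target`` < 0 only tau_total is computed (s = -1).  Otherwise s is
    the distance at which the cumulative optical depth reaches tau_target and
    flat_idx the voxel containing that point.
    """
    ox, oy, oz = origin[0], origin[1], origin[2]
    ux = ox + spacing[0] * dims[0]
    uy = oy + spacing[1] * dims[1]
    uz = oz + spacing[2] * dims[2]
    t0, t1 = _clip_box(p0[0], p0[1], p0[2], d[0], d[1], d[2],
                       ox, oy, oz, ux, uy, uz, 1e30)
    if t1 <= t0 + 1e-14 or t1 <= 0.0:
        return 0.0, -1.0, -1
    if t0 < 0.0:
        t0 = 0.0
    eps = 1e-10 * max(spacing[0], max(spacing[1], spacing[2]))
    sx = p0[0] + d[0] * (t0 + eps)
    sy = p0[1] + d[1] * (t0 + eps)
    sz = p0[2] + d[2] * (t0 + eps)
    i = min(max(int((sx - ox) / spacing[0]), 0), dims[0] - 1)
    j = min(max(int((sy - oy) / spacing[1]), 0), dims[1] - 1)
    k = min(max(int((sz - oz) / spacing[2]), 0), dims[2] - 1)
    big = 1e300
    step_i = 1 if d[0] > 0 else -1
    step_j = 1 if d[1] > 0 else -1
    step_k = 1 if d[2] > 0 else -1
    tdx = spacing[0] / abs(d[0]) if d[0] != 0 else big
    tdy = spacing[1] / abs(d[1]) if d[1] != 0 else big
    tdz = spacing[2] / abs(d[2]) if d[2] != 0 else big
    if d[0] > 0:
        tmx = (ox + (i + 1) * spacing[0] - p0[0]) / d[0]
    elif d[0] < 0:
        tmx = (ox + i * spacing[0] - p0[0]) / d[0]
    else:
        tmx = big
    if d[1] > 0:
        tmy = (oy + (j + 1) * spacing[1] - p0[1]) / d[1]
    elif d[1] < 0:
        tmy = (oy + j * spacing[1] - p0[1]) / d[1]
    else:
        tmy = big
    if d[2] > 0:
        tmz = (oz + (k + 1) * spacing[2] - p0[2]) / d[2]
    elif d[2] < 0:
        tmz = (oz + k * spacing[2] - p0[2]) / d[2]
    else:
        tmz = big
    t = t0
    tau = 0.0
    s_hit = -1.0
    flat_hit = -1
    nynz = dims[1] * dims[2]
    while t < t1 - 1e-14:
        if tmx <= tmy and tmx <= tmz:
            tn = tmx
        elif tmy <= tmz:
            tn = tmy
        else:
            tn = tmz
        te = tn if tn < t1 else t1
        chord = te - t
        if chord > 0:
            flat = i * nynz + j * dims[2] + k
            mu = mu_at_e[mat[flat]] * rho[flat]
            dtau = chord * mu
            if s_hit < 0.0 and tau_target >= 0.0 and tau + dtau >= tau_target:
                frac = (tau_target - tau) / dtau if dtau > 0 else 0.0
                s_hit = t + chord * frac
                flat_hit = flat
            tau += dtau
        if te >= t1 - 1e-14:
            break
        if tmx <= tmy and tmx <= tmz:
            i += step_i
            tmx += tdx
            if i < 0 or i >= dims[0]:
                break
        elif tmy <= tmz:
            j += step_j
            tmy += tdy
            if j < 0 or j >= dims[1]:
                break
        else:
            k += step_k
            tmz += tdz
            if k < 0 or k >= dims[2]:
                break
        t = tn
    return tau, s_hit, flat_hit


@njit(cache=True, inline="always")
def _kn_diff(e_kev, cos_t):
    """Klein-Nishina differential cross section, barns/sr per electron."""
    k = e_kev / MEC2_KEV
    ratio = 1.0 / (1.0 + k * (1.0 - cos_t))  # E'/E
    return 0.5 * R_E2_BARN * ratio * ratio * (
        ratio + 1.0 / ratio - (1.0 - cos_t * cos_t)
    )


@njit(cache=True)
def _sample_kn(e_kev):
    """Kahn's method for the Klein-Nishina angle; returns cos(theta)."""
    k = e_kev / MEC2_KEV
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return 1.0 - (x - 1.0) / k if k > 0 else 1.0
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cos_t = 1.0 - (x - 1.0) / k if k > 0 else 1.0
            if r3 <= 0.5 * (cos_t * cos_t + 1.0 / x):
                return cos_t


@njit(cache=True)
def _sample_coherent(e_kev, x0):
    """Thomson x screened-form-factor angle sampling; returns cos(theta)."""
    xmax2 = (e_kev / HC_KEV_A) ** 2
    a = x0 * x0
    big_a = 1.0 - (1.0 + xmax2 / a) ** (-3.0)
    while True:
        r1 = np.random.random()
        u = a * ((1.0 - big_a * r1) ** (-1.0 / 3.0) - 1.0)
        cos_t = 1.0 - 2.0 * u / xmax2
        if np.random.random() <= 0.5 * (1.0 + cos_t * cos_t):
            return cos_t


@njit(cache=True, inline="always")
def _rotate_direction(dx, dy, dz, cos_t, phi):
    """New unit vector at polar angle theta from (dx,dy,dz), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    # Build an orthonormal frame around the incident direction.
    if abs(dz) < 0.99999:
        ux = -dy
        uy = dx
        uz = 0.0
    else:
        ux = 1.0
        uy = 0.0
        uz = 0.0
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= norm
    uy /= norm
    uz /= norm
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    nx = sin_t * (cp * ux + sp * vx) + cos_t * dx
    ny = sin_t * (cp * uy + sp * vy) + cos_t * dy
    nz = sin_t * (cp * uz + sp * vz) + cos_t * dz
    return nx, ny, nz


@njit(cache=True)
def primary_kernel(pois, poi_mat, n_angles, sad, rotating,
                   x_edges, z_edges, values2d, fluence_norm,
                   spec_pdf, spec_dx, energies,
                   origin, spacing, dims, mat, rho, nmat,
                   mu_tot_bins, mu_en_bins, out):
    """Deterministic primary collision kerma per emitted photon, per POI."""
    npoi = pois.shape[0]
    nbins = energies.shape[0]
    nx = x_edges.shape[0] - 1
    nz = z_edges.shape[0] - 1
    dxc = x_edges[1] - x_edges[0]
    dzc = z_edges[1] - z_edges[0]
    npos = spec_pdf.shape[0]
    areal = np.zeros(nmat)
    nang = n_angles if rotating else 1
    for p in range(npoi):
        qx = pois[p, 0]
        qy = pois[p, 1]
        qz = pois[p, 2]
        acc = 0.0
        for ia in range(nang):
            alpha = 2.0 * np.pi * ia / nang if rotating else 0.0
            ca = np.cos(alpha)
            sa = np.sin(alpha)
            # POI in the gantry frame
            gx = qx * ca - qy * sa
            gy = qx * sa + qy * ca
            if gy >= sad:
                continue
            scale = sad / (sad - gy)
            xp = gx * scale
            zp = qz * scale
            ix = int((xp - x_edges[0]) / dxc)
            iz = int((zp - z_edges[0]) / dzc)
            if ix < 0 or ix >= nx or iz < 0 or iz >= nz:
                continue
            val = values2d[ix, iz]
            if val <= 0.0:
                continue
            ipos = int(np.round(abs(xp) / spec_dx))
            if ipos >= npos:
                ipos = npos - 1
            # source position in world coordinates
            swx = sad * sa
            swy = sad * ca
            rq2 = (qx - swx) ** 2 + (qy - swy) ** 2 + qz * qz
            rp2 = xp * xp + sad * sad + zp * zp
            dist = np.sqrt(rq2)
            ddx = (qx - swx) / dist
            ddy = (qy - swy) / dist
            ddz = qz / dist
            for m in range(nmat):
                areal[m] = 0.0
            p0 = np.empty(3)
            p0[0] = swx
            p0[1] = swy
            p0[2] = 0.0
            dvec = np.empty(3)
            dvec[0] = ddx
            dvec[1] = ddy
            dvec[2] = ddz
            areal_path_kernel(p0, dvec, dist, origin, spacing, dims, mat,
                              rho, areal)
            pm = poi_mat[p]
            w_geom = (val / fluence_norm) * (rp2 / rq2)
            for b in range(nbins):
                pdf = spec_pdf[ipos, b]
                if pdf <= 0.0:
                    continue
                tau = 0.0
                for m in range(nmat):
                    if areal[m] > 0.0:
                        tau += areal[m] * mu_tot_bins[m, b]
                acc += pdf * w_geom * np.exp(-tau) * energies[b] \
                    * mu_en_bins[pm, b]
        out[p] = acc / nang


@njit(cache=True, inline="always")
def _nee_kernel_factor(tau_p, r, r2):
    """exp(-tau)/r^2, volume-averaged over a small sphere near a POI."""
    if r < NEE_R0_CM:
        mu_bar = tau_p / r if r > 1e-12 else 0.0
        x = mu_bar * NEE_R0_CM
        if x > 1e-12:
            return 3.0 * (-np.expm1(-x)) / (mu_bar * NEE_R0_CM**3)
        return 3.0 / (NEE_R0_CM * NEE_R0_CM)
    return np.exp(-tau_p) / r2


@njit(cache=True)
def _score_nee(vx, vy, vz, ddx, ddy, ddz, e, w_inc, w_coh, mv,
               origin, spacing, dims, mat, rho, nmat,
               mu_tot, mu_en, kn_sigma, coh_x0, coh_norm,
               pois, poi_mat, out, areal, p0, dvec):
    """Channel-expected next-event estimate from one vertex to every POI.

    Scores both scatter channels (incoherent with weight ``w_inc``,
    coherent with ``w_coh``) sharing a single geometric traversal per POI:
    the per-material areal densities are energy-independent, so the optical
    depths at the Compton-shifted and elastic energies reuse one trace.
    ``out`` accumulates collision kerma; ``areal``/``p0``/``dvec`` are
    caller-provided scratch arrays.  Within NEE_R0_CM of a POI the 1/r^2
    transport kernel is replaced by its volume average over that sphere.
    """
    npoi = pois.shape[0]
    k = e / MEC2_KEV
    sig_kn = _interp_row(kn_sigma, e)
    x0sq = coh_x0[mv] * coh_x0[mv]
    norm_coh = _interp_row(coh_norm[mv], e)
    for p in range(npoi):
        tx = pois[p, 0] - vx
        ty = pois[p, 1] - vy
        tz = pois[p, 2] - vz
        r2 = tx * tx + ty * ty + tz * tz
        if r2 < 1e-12:
            continue
        r = np.sqrt(r2)
        cos_t = (ddx * tx + ddy * ty + ddz * tz) / r
        p0[0] = vx
        p0[1] = vy
        p0[2] = vz
        dvec[0] = tx / r
        dvec[1] = ty / r
        dvec[2] = tz / r
        for m in range(nmat):
            areal[m] = 0.0
        areal_path_kernel(p0, dvec, r, origin, spacing, dims, mat, rho, areal)
        pm = poi_mat[p]
        score = 0.0
        if w_inc > 0.0:
            ratio = 1.0 / (1.0 + k * (1.0 - cos_t))
            ep = e * ratio
            if ep >= EF0:
                pdf = _kn_diff(e, cos_t) / sig_kn
                tau_p = 0.0
                for m in range(nmat):
                    if areal[m] > 0.0:
                        tau_p += areal[m] * _interp_row(mu_tot[m], ep)
                score += w_inc * pdf * _nee_kernel_factor(tau_p, r, r2) \
                    * ep * _interp_row(mu_en[pm], ep)
        if w_coh > 0.0:
            u2 = (1.0 - cos_t) * 0.5 * (e / HC_KEV_A) ** 2
            ff = (1.0 + u2 / x0sq) ** (-2.0)
            pdf = (1.0 + cos_t * cos_t) * ff * ff / norm_coh
            tau_p = 0.0
            for m in range(nmat):
                if areal[m] > 0.0:
                    tau_p += areal[m] * _interp_row(mu_tot[m], e)
            score += w_coh * pdf * _nee_kernel_factor(tau_p, r, r2) \
                * e * _interp_row(mu_en[pm], e)
        out[p] += score


@njit(cache=True)
def _walk(vx, vy, vz, ddx, ddy, ddz, e, w, mv, incoherent,
          origin, spacing, dims, mat, rho, nmat,
          mu_tot, mu_pe, mu_coh, mu_incoh, mu_en,
          kn_sigma, coh_x0, coh_norm, pois, poi_mat, multi_out,
          mu_arr, areal, p0, dvec, sp0, sdvec):
    """Continue a photon walk from a scattering vertex, scoring multiscatter.

    Every flight is forced (the escaping fraction is removed from the
    weight); each scattering vertex scores the channel-expected next-event
    estimate to every POI; Russian roulette terminates low weights.
    """
    nvert = 1
    while nvert < MAX_VERTICES:
        nvert += 1
        if incoherent:
            cos_t = _sample_kn(e)
            k = e / MEC2_KEV
            e = e / (1.0 + k * (1.0 - cos_t))
        else:
            cos_t = _sample_coherent(e, coh_x0[mv])
        if e < E_CUTOFF_KEV:
            break
        phi = 2.0 * np.pi * np.random.random()
        ddx, ddy, ddz = _rotate_direction(ddx, ddy, ddz, cos_t, phi)
        if w < RR_THRESHOLD:
            if np.random.random() > RR_SURVIVE:
                break
            w /= RR_SURVIVE
        for m in range(nmat):
            mu_arr[m] = _interp_row(mu_tot[m], e)
        p0[0] = vx
        p0[1] = vy
        p0[2] = vz
        dvec[0] = ddx
        dvec[1] = ddy
        dvec[2] = ddz
        tau_rem, _, _ = _tau_and_collision(
            p0, dvec, origin, spacing, dims, mat, rho, mu_arr, -1.0)
        p_col = -np.expm1(-tau_rem)
        if p_col < 1e-9 or w * p_col < W_CUTOFF:
            break
        w *= p_col
        tau_c = -np.log(1.0 - np.random.random() * p_col)
        _, s_hit, flat_hit = _tau_and_collision(
            p0, dvec, origin, spacing, dims, mat, rho, mu_arr, tau_c)
        if s_hit < 0.0:
            break
        vx = p0[0] + ddx * s_hit
        vy = p0[1] + ddy * s_hit
        vz = p0[2] + ddz * s_hit
        mv = mat[flat_hit]
        m_pe = _interp_row(mu_pe[mv], e)
        m_coh = _interp_row(mu_coh[mv], e)
        m_inc = _interp_row(mu_incoh[mv], e)
        m_tot = m_pe + m_coh + m_inc
        # channel-expected scoring: both scatter channels share the trace
        _score_nee(vx, vy, vz, ddx, ddy, ddz, e, w * m_inc / m_tot,
                   w * m_coh / m_tot, mv, origin, spacing, dims, mat, rho,
                   nmat, mu_tot, mu_en, kn_sigma, coh_x0, coh_norm,
                   pois, poi_mat, multi_out, areal, sp0, sdvec)
        # channel selection for the continuation
        u = np.random.random() * m_tot
        if u < m_pe:
            break
        incoherent = u < m_pe + m_inc


@njit(cache=True)
def scatter_kernel(n_photons, seed, sad, rotating,
                   x_edges, lat_cdf, lat_w, z_edges, ax_cdf,
                   spec_cdf, spec_w, spec_dx, energies,
                   origin, spacing, dims, mat, rho, nmat,
                   mu_tot, mu_pe, mu_coh, mu_incoh, mu_en,
                   kn_sigma, coh_x0, coh_norm,
                   pois, poi_mat, first_out, multi_out):
    """Biased MC scatter: importance-sampled emission, forced collisions,
    stratified first-collision depth, next-event estimation to each POI.

    The lateral cell and energy bin are drawn from importance-tilted CDFs
    (``lat_cdf``/``spec_cdf``) with the true-to-sampling probability ratio
    carried as the photon weight (``lat_w``/``spec_w``).  The gantry angle
    is stratified over the batch, and the lateral/axial/energy CDF inputs
    are randomized low-discrepancy points (Halton bases 3/5/2 with a random
    Cranley-Patterson shift per batch), so each batch remains an
    independent unbiased estimate.  The first collision is forced inside
    the grid and its optical depth is sampled in FC_STRATA
    equal-probability strata; every stratum scores a channel-expected
    next-event estimate to every POI with weight w/FC_STRATA
    (first-scatter component) and launches an independent continuation
    walk with the same weight that scores the multiscatter component.

    Scores are summed collision kerma per component; divide by n_photons
    for the per-emitted-photon estimate.  Coefficient rows live on the fine
    energy grid; kn_sigma is the Klein-Nishina total cross section per
    electron (barns); coh_norm is the per-material angular normalization of
    (1 + cos^2) F^2 over solid angle.
    """
    np.random.seed(seed)
    nx = x_edges.shape[0] - 1
    nz = z_edges.shape[0] - 1
    nbins = energies.shape[0]
    npos = spec_cdf.shape[0]
    mu_arr = np.empty(nmat)
    areal = np.empty(nmat)
    p0 = np.empty(3)
    dvec = np.empty(3)
    sp0 = np.empty(3)
    sdvec = np.empty(3)
    sh_x = np.random.random()
    sh_z = np.random.random()
    sh_e = np.random.random()
    for ph in range(n_photons):
        # --- emission: stratified angle, shifted-Halton cell and energy ---
        alpha = 2.0 * np.pi * (ph + np.random.random()) / n_photons \
            if rotating else 0.0
        ca = np.cos(alpha)
        sa = np.sin(alpha)
        u = _vdc(ph, 3) + sh_x
        u -= int(u)
        ix = np.searchsorted(lat_cdf, u)
        if ix >= nx:
            ix = nx - 1
        xs = x_edges[ix] + np.random.random() * (x_edges[ix + 1] - x_edges[ix])
        u = _vdc(ph, 5) + sh_z
        u -= int(u)
        iz = np.searchsorted(ax_cdf, u)
        if iz >= nz:
            iz = nz - 1
        zs = z_edges[iz] + np.random.random() * (z_edges[iz + 1] - z_edges[iz])
        ipos = int(np.round(abs(xs) / spec_dx))
        if ipos >= npos:
            ipos = npos - 1
        u = _vdc(ph, 2) + sh_e
        u -= int(u)
        ib = np.searchsorted(spec_cdf[ipos], u)
        if ib >= nbins:
            ib = nbins - 1
        e = energies[ib]
        w0 = lat_w[ix] * spec_w[ipos, ib]
        if w0 <= 0.0:
            continue
        # world-frame origin and direction
        swx = sad * sa
        swy = sad * ca
        px = xs * ca
        py = -xs * sa
        pz = zs
        ddx = px - swx
        ddy = py - swy
        ddz = pz
        dist = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        ddx /= dist
        ddy /= dist
        ddz /= dist
        p0[0] = swx
        p0[1] = swy
        p0[2] = 0.0
        dvec[0] = ddx
        dvec[1] = ddy
        dvec[2] = ddz
        # --- forced first collision, stratified in optical depth ---
        for m in range(nmat):
            mu_arr[m] = _interp_row(mu_tot[m], e)
        tau_tot, _, _ = _tau_and_collision(p0, dvec, origin, spacing, dims,
                                           mat, rho, mu_arr, -1.0)
        if tau_tot < 1e-12:
            continue
        p_col = -np.expm1(-tau_tot)
        w = w0 * p_col
        ws = w / FC_STRATA
        for j in range(FC_STRATA):
            uj = (j + np.random.random()) / FC_STRATA
            tau_c = -np.log(1.0 - uj * p_col)
            _, s_hit, flat_hit = _tau_and_collision(
                p0, dvec, origin, spacing, dims, mat, rho, mu_arr, tau_c)
            if s_hit < 0.0:
                continue
            vx = p0[0] + ddx * s_hit
            vy = p0[1] + ddy * s_hit
            vz = p0[2] + ddz * s_hit
            mv = mat[flat_hit]
            m_pe = _interp_row(mu_pe[mv], e)
            m_coh = _interp_row(mu_coh[mv], e)
            m_inc = _interp_row(mu_incoh[mv], e)
            m_tot = m_pe + m_coh + m_inc
            # channel-expected first-scatter score for this stratum
            _score_nee(vx, vy, vz, ddx, ddy, ddz, e, ws * m_inc / m_tot,
                       ws * m_coh / m_tot, mv, origin, spacing, dims, mat,
                       rho, nmat, mu_tot, mu_en, kn_sigma, coh_x0, coh_norm,
                       pois, poi_mat, first_out, areal, sp0, sdvec)
            # every stratum launches a continuation walk (channel-sampled)
            u = np.random.random() * m_tot
            if u < m_pe:
                continue  # photoelectric at this stratum: absorbed locally
            _walk(vx, vy, vz, ddx, ddy, ddz, e, ws, mv, u < m_pe + m_inc,
                  origin, spacing, dims, mat, rho, nmat,
                  mu_tot, mu_pe, mu_coh, mu_incoh, mu_en,
                  kn_sigma, coh_x0, coh_norm, pois, poi_mat, multi_out,
                  mu_arr, areal, p0, dvec, sp0, sdvec)
            # _walk clobbers the shared scratch; restore the emission ray
            p0[0] = swx
            p0[1] = swy
            p0[2] = 0.0
            dvec[0] = ddx
            dvec[1] = ddy
            dvec[2] = ddz
            for m in range(nmat):
                mu_arr[m] = _interp_row(mu_tot[m], e)
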