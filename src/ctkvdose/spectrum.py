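"""kV X-ray spectra: generation, filtration, air kerma, HVL and its inverse.

The generator is a self-contained semi-empirical model: Kramers-form
bremsstrahlung, N(E) ∝ (kVp − E)/E, with tungsten K characteristic lines
added when the tube potential exceeds the W K-edge, then Beer-Lambert
attenuation through the stated aluminum filtration.  The method this package
implements constrains the spectrum by its measured half-value layer (HVL),
which makes downstream dose only weakly sensitive to the generator's fine
shape; the generator sits behind this module's interface so a table-driven
model can be slotted in.

All spectra live on a fixed 1 keV grid starting at 1 keV and are normalized
to unit sum.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .materials import Material, get_material

KVP_MIN = 40.0
KVP_MAX = 150.0

# Tungsten K characteristic lines: (energy keV, relative intensity).
_W_K_EDGE_KEV = 69.525
_W_K_LINES = ((58.0, 0.58), (59.3, 1.0), (67.2, 0.33), (69.1, 0.08))
# Fraction of total output in characteristic lines at kVp well above the edge.
_W_K_YIELD = 0.08

_HVL_BRACKET_MM = 30.0
_HVL_TOL_MM = 1e-3
_FILTRATION_TOL_MM = 1e-2


@dataclass(frozen=True)
class Spectrum:
    """Relative photon counts in 1 keV bins from 1 keV up to the kVp."""

    kvp: float
    energies: np.ndarray  # bin centers, keV
    counts: np.ndarray    # relative photons per bin
    filtration_mm_al: float = 0.0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, float)
        c = np.asarray(self.counts, float)
        if e.shape != c.shape:
            raise ValueError("energies and counts shapes differ")
        if np.any(c < 0):
            raise ValueError("negative counts")
        if np.any(c[e > self.kvp] > 0):
            raise ValueError("counts above the kVp endpoint")
        if not np.any(c > 0):
            raise ValueError("spectrum has no positive bin")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.counts) / self.total)

    def normalized(self) -> "Spectrum":
        return replace(self, counts=self.counts / self.total)

    def save(self, path: str | Path) -> None:
        """CSV (`energy_keV,relative_counts`) plus a JSON metadata sidecar."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["energy_keV", "relative_counts"])
            for e, c in zip(self.energies, self.counts):
                w.writerow([f"{e:g}", f"{c:.12e}"])
        meta = {"kvp": self.kvp, "filtration_mm_al": self.filtration_mm_al}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Spectrum":
        path = Path(path)
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(kvp=meta["kvp"], energies=rows[:, 0], counts=rows[:, 1],
                   filtration_mm_al=meta["filtration_mm_al"])


def energy_grid(kvp: float) -> np.ndarray:
    """1 keV bin centers from 1 keV to the kVp (inclusive endpoint bin)."""
    return np.arange(1.0, np.floor(kvp) + 0.5, 1.0)


def generate_spectrum(kvp: float, filtration_mm_al: float) -> Spectrum:
    """Semi-empirical tube spectrum at ``kvp`` behind Al filtration.

    Kramers bremsstrahlung plus W K lines (above the K edge), attenuated
    through ``filtration_mm_al`` of aluminum and normalized to unit sum.
    """
    if not (KVP_MIN <= kvp <= KVP_MAX):
        raise ValueError(f"kvp {kvp} outside supported range [{KVP_MIN}, {KVP_MAX}]")
    if filtration_mm_al < 0:
        raise ValueError("negative filtration")
    e = energy_grid(kvp)
    counts = np.maximum(kvp - e, 0.0) / e
    if kvp > _W_K_EDGE_KEV:
        # Line strength grows with overvoltage above the K edge.
        strength = _W_K_YIELD * counts.sum() * (kvp / _W_K_EDGE_KEV - 1.0) ** 1.65
        weights = np.array([w for _, w in _W_K_LINES])
        for (line_e, w) in _W_K_LINES:
            if line_e < kvp:
                idx = int(np.argmin(np.abs(e - line_e)))
                counts[idx] += strength * w / weights.sum()
    spec = Spectrum(kvp=kvp, energies=e, counts=counts, filtration_mm_al=0.0)
    if filtration_mm_al > 0:
        spec = attenuate(spec, get_material("aluminum"), filtration_mm_al / 10.0)
    spec = replace(spec, filtration_mm_al=filtration_mm_al)
    return spec.normalized()


def attenuate(spectrum: Spectrum, material: Material,
              thickness_cm: float) -> Spectrum:
    """Beer-Lambert attenuation per bin; the result is *not* renormalized."""
    if thickness_cm < 0:
        raise ValueError("negative thickness")
    mu = material.linear_attenuation(spectrum.energies)
    return replace(spectrum, counts=spectrum.counts * np.exp(-mu * thickness_cm))


def air_kerma(spectrum: Spectrum) -> float:
    """Relative air kerma: sum over bins of counts * E * (mu_en/rho)_air."""
    air = get_material("air")
    return float(np.sum(
        spectrum.counts * spectrum.energies
        * air.mass_energy_absorption(spectrum.energies)
    ))


def compute_hvl(spectrum: Spectrum) -> float:
    """Half-value layer in mm Al: the Al thickness halving the air kerma.

    Narrow-beam geometry (no scatter to the detector); bracketed root search
    to 1e-3 mm.
    """
    k0 = air_kerma(spectrum)
    if k0 <= 0:
        raise ValueError("spectrum has zero air kerma")
    al = get_material("aluminum")

    def f(t_mm: float) -> float:
        return air_kerma(attenuate(spectrum, al, t_mm / 10.0)) - 0.5 * k0

    if f(_HVL_BRACKET_MM) > 0:
        raise ValueError(f"HVL exceeds the {_HVL_BRACKET_MM} mm search bracket")
    return float(brentq(f, 0.0, _HVL_BRACKET_MM, xtol=_HVL_TOL_MM / 10))


def fit_filtration(kvp: float, target_hvl_mm: float) -> float:
    """Invert the spectral model: Al filtration whose spectrum has the HVL.

    Deterministic bisection on filtration in [0, 30] mm; the returned value
    reproduces ``target_hvl_mm`` within 0.01 mm.
    """
    lo, hi = 0.0, _HVL_BRACKET_MM
    hvl_lo = compute_hvl(generate_spectrum(kvp, lo))
    hvl_hi = compute_hvl(generate_spectrum(kvp, hi))
    if not (hvl_lo - 1e-9 <= target_hvl_mm <= hvl_hi + 1e-9):
        raise ValueError(
            f"target HVL {target_hvl_mm:.3f} mm not achievable at {kvp:g} kVp; "
            f"achievable range is [{hvl_lo:.3f}, {hvl_hi:.3f}] mm"
        )
    while hi - lo > _FILTRATION_TOL_MM / 4:
        mid = 0.5 * (lo + hi)
        if compute_hvl(generate_spectrum(kvp, mid)) < target_hvl_mm:
            lo = mid
        else:
            hi = mid
    t_hat = 0.5 * (lo + hi)
    if abs(compute_hvl(generate_spectrum(kvp, t_hat)) - target_hvl_mm) > 0.01:
        raise RuntimeError("filtration search failed to meet the 0.01 mm tolerance")
    return t_hat
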