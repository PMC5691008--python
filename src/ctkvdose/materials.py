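"""Elemental and composite material data for kV photon transport.

Bundled per-element tables give photoelectric, coherent and incoherent cross
sections (barns/atom) and the mass-energy absorption coefficient (cm^2/g) on
a sparse 1-150 keV grid; everything is interpolated log-log in energy, the
standard choice for photon coefficient tables (positive, no overshoot).

A :class:`Material` is a named density plus a composition given either as
atoms per molecule (``molecular`` mode) or as fractions by weight (``weight``
mode).  Atomic number densities follow

    n_x = rho * N_A * (atoms of x per molecule) / A_molecule        (molecular)
    n_x = rho * N_A * w_x / A_x                                     (weight)

with rho in g/cm^3 and A in g/mol, so n_x is in atoms/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

AVOGADRO = 6.02214076e23
ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 150.0

_CHANNELS = ("pe", "coh", "incoh")


@dataclass(frozen=True)
class ElementData:
    """Tabulated photon-interaction data for one element."""

    symbol: str
    Z: int
    A: float  # g/mol
    energy_kev: np.ndarray
    sigma_pe: np.ndarray     # barns/atom
    sigma_coh: np.ndarray    # barns/atom
    sigma_incoh: np.ndarray  # barns/atom
    mu_en_over_rho: np.ndarray  # cm^2/g

    def __post_init__(self) -> None:
        e = self.energy_kev
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"{self.symbol}: energy grid not increasing")
        for name in ("sigma_pe", "sigma_coh", "sigma_incoh", "mu_en_over_rho"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{self.symbol}: negative values in {name}")

    @property
    def sigma_total(self) -> np.ndarray:
        return self.sigma_pe + self.sigma_coh + self.sigma_incoh

    def mass_attenuation(self, energy_kev, channel: str | None = None):
        """Elemental mu/rho (cm^2/g) at ``energy_kev``, log-log interpolated.

        ``channel`` selects one of ``pe``/``coh``/``incoh``; default total.
        """
        sigma = {
            None: self.sigma_total,
            "pe": self.sigma_pe,
            "coh": self.sigma_coh,
            "incoh": self.sigma_incoh,
        }[channel]
        barns = _loglog_interp(energy_kev, self.energy_kev, sigma)
        return barns * 1e-24 * AVOGADRO / self.A

    def mass_energy_absorption(self, energy_kev):
        return _loglog_interp(energy_kev, self.energy_kev, self.mu_en_over_rho)


def _loglog_interp(x, xp, fp):
    x = np.asarray(x, dtype=float)
    if np.any(x < ENERGY_MIN_KEV - 1e-12) or np.any(x > ENERGY_MAX_KEV + 1e-12):
        raise ValueError(
            f"energy outside table support [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV"
        )
    out = np.exp(np.interp(np.log(x), np.log(xp), np.log(np.maximum(fp, 1e-300))))
    return out if out.ndim else float(out)


def _load_elements() -> dict[str, ElementData]:
    text = resources.files("ctkvdose.data").joinpath("elements.csv").read_text()
    rows = [line.split(",") for line in text.strip().splitlines()[1:]]
    table: dict[str, list] = {}
    for sym, z, a, e, pe, coh, incoh, muen in rows:
        table.setdefault(sym, []).append(
            (int(z), float(a), float(e), float(pe), float(coh), float(incoh), float(muen))
        )
    out = {}
    for sym, recs in table.items():
        recs.sort(key=lambda r: r[2])
        arr = np.array([r[2:] for r in recs], dtype=float)
        out[sym] = ElementData(
            symbol=sym, Z=recs[0][0], A=recs[0][1],
            energy_kev=arr[:, 0], sigma_pe=arr[:, 1], sigma_coh=arr[:, 2],
            sigma_incoh=arr[:, 3], mu_en_over_rho=arr[:, 4],
        )
    return out


_ELEMENTS: dict[str, ElementData] | None = None


def get_element(symbol: str) -> ElementData:
    global _ELEMENTS
    if _ELEMENTS is None:
        _ELEMENTS = _load_elements()
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None


@dataclass
class Material:
    """A composite medium: density plus elemental composition.

    ``mode`` is an explicit flag, never auto-detected: ``"molecular"`` maps
    element -> atoms per molecule, ``"weight"`` maps element -> fraction by
    weight (must sum to 1 within 1e-6).
    """

    name: str
    density: float  # g/cm^3
    composition: Mapping[str, float] = field(default_factory=dict)
    mode: str = "molecular"

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"{self.name}: negative density {self.density}")
        if self.mode not in ("molecular", "weight"):
            raise ValueError(f"{self.name}: mode must be 'molecular' or 'weight'")
        if not self.composition:
            raise ValueError(f"{self.name}: empty composition")
        for sym in self.composition:
            get_element(sym)  # raises on unknown symbol
        if self.mode == "weight":
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.name}: weight fractions sum to {total}, expected 1"
                )

    @property
    def molecular_weight(self) -> float:
        if self.mode != "molecular":
            raise ValueError("molecular weight defined only in molecular mode")
        return sum(n * get_element(s).A for s, n in self.composition.items())

    @property
    def weight_fractions(self) -> dict[str, float]:
        if self.mode == "weight":
            return dict(self.composition)
        mw = self.molecular_weight
        return {s: n * get_element(s).A / mw for s, n in self.composition.items()}

    @property
    def number_densities(self) -> dict[str, float]:
        return atomic_number_density(self)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, dict(self.composition), self.mode)

    def mass_attenuation(self, energy_kev, channel: str | None = None):
        """mu/rho of the mixture (cm^2/g) by the weight-fraction mixture rule."""
        w = self.weight_fractions
        return sum(
            frac * get_element(sym).mass_attenuation(energy_kev, channel)
            for sym, frac in w.items()
        )

    def linear_attenuation(self, energy_kev, channel: str | None = None):
        """mu (1/cm): mass attenuation times density."""
        return self.mass_attenuation(energy_kev, channel) * self.density

    def mass_energy_absorption(self, energy_kev):
        w = self.weight_fractions
        return sum(
            frac * get_element(sym).mass_energy_absorption(energy_kev)
            for sym, frac in w.items()
        )

    def effective_z(self, power: float = 2.94) -> float:
        """Electron-fraction-weighted effective atomic number."""
        w = self.weight_fractions
        elec = {s: f * get_element(s).Z / get_element(s).A for s, f in w.items()}
        tot = sum(elec.values())
        return (
            sum(v / tot * get_element(s).Z ** power for s, v in elec.items())
        ) ** (1.0 / power)


def atomic_number_density(material: Material) -> dict[str, float]:
    """Per-element atomic number densities n_x in atoms/cm^3."""
    rho = material.density
    if rho < 0:
        raise ValueError("negative density")
    out = {}
    if material.mode == "molecular":
        mw = material.molecular_weight
        for sym, n in material.composition.items():
            out[sym] = rho * AVOGADRO * n / mw
    else:
        for sym, w in material.composition.items():
            out[sym] = rho * AVOGADRO * w / get_element(sym).A
    return out


def mass_attenuation(material: Material, energy_kev, channel: str | None = None):
    return material.mass_attenuation(energy_kev, channel)


def linear_attenuation(material: Material, energy_kev, channel: str | None = None):
    return material.linear_attenuation(energy_kev, channel)


def medium_conversion_ratio(spectrum, medium: Material,
                            reference_medium: Material) -> float:
    """Spectrum-averaged mass-energy-absorption ratio medium/reference.

    ratio = sum_E phi(E) E (mu_en/rho)_m / sum_E phi(E) E (mu_en/rho)_ref,
    the kerma-weighted conversion factor used to translate dose between media
    (e.g. the TG-61-style medium-to-water ratios).
    """
    e = np.asarray(spectrum.energies, dtype=float)
    c = np.asarray(spectrum.counts, dtype=float)
    if c.size == 0 or not np.any(c > 0):
        raise ValueError("spectrum has no positive bins")
    num = float(np.sum(c * e * medium.mass_energy_absorption(e)))
    den = float(np.sum(c * e * reference_medium.mass_energy_absorption(e)))
    if den == 0:
        raise ValueError("zero total kerma in reference medium")
    return num / den


def _load_material_registry() -> dict[str, Material]:
    text = resources.files("ctkvdose.data").joinpath("materials.json").read_text()
    raw = json.loads(text)
    out = {}
    for name, spec in raw.items():
        out[name] = Material(
            name=name,
            density=spec["density_g_cm3"],
            composition=spec["composition"],
            mode=spec["mode"],
        )
    return out


_MATERIALS: dict[str, Material] | None = None


def get_material(name: str, density: float | None = None) -> Material:
    """Look up a bundled material, optionally overriding its density."""
    global _MATERIALS
    if _MATERIALS is None:
        _MATERIALS = _load_material_registry()
    try:
        mat = _MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(_MATERIALS)}"
        ) from None
    return mat if density is None else mat.with_density(density)


def material_from_config(spec: Mapping) -> Material:
    """Build a Material from a JSON-style config mapping."""
    return Material(
        name=spec["name"],
        density=spec["density_g_cm3"],
        composition=spec["composition"],
        mode=spec.get("mode", "molecular"),
    )
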