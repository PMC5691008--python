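"""Two-point HVL estimation from exposure readings and lateral HVL profiles.

A half-value-layer measurement at lateral position x records an open-beam
reading D0 and two filtered readings D1, D2 behind aluminum slabs of nominal
thickness T1 < T2 chosen to bracket the expected HVL.  Because the ray to an
off-axis chamber crosses the slabs obliquely, the effective path through a
slab is T/cos(theta) with theta = arctan(x / SAD).

The two-point estimator interpolates log-attenuation between the two slab
thicknesses:

    HVL = [T2θ ln(2 D1/D0) − T1θ ln(2 D2/D0)] / ln(D1/D2)

which is exact for a single-exponential (monoenergetic) beam and a good
approximation for a bracketed polyenergetic one.

Profiles along the bow-tie axis are measured at discrete positions, mirrored
about x = 0 (the source is laterally symmetric), and interpolated with a
natural cubic spline; beyond the last measured position the profile clamps
to its endpoint value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class HVLMeasurement:
    """One two-point HVL measurement at lateral position x."""

    x_cm: float
    T1_mm: float   # nominal slab thickness, slightly below the expected HVL
    T2_mm: float   # nominal slab thickness, slightly above the expected HVL
    D0: float      # open-beam reading
    D1: float      # reading behind T1
    D2: float      # reading behind T2
    theta_rad: float = 0.0  # obliquity of the ray to the slab normal

    def __post_init__(self) -> None:
        if not (0 < self.D2 < self.D1 < self.D0):
            raise ValueError(
                f"readings must satisfy 0 < D2 < D1 < D0, got "
                f"D0={self.D0}, D1={self.D1}, D2={self.D2}"
            )
        if not (0 <= self.T1_mm < self.T2_mm):
            raise ValueError("slab thicknesses must satisfy 0 <= T1 < T2")
        if not (0 <= self.theta_rad < math.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")


def oblique_angle(x_cm: float, sad_cm: float) -> float:
    """Angle between the central ray and the ray to a chamber at (x, 0, 0)."""
    if sad_cm <= 0:
        raise ValueError("SAD must be positive")
    return math.atan2(abs(x_cm), sad_cm)


def hvl_two_point(m: HVLMeasurement) -> float:
    """Two-point HVL (mm Al, along the oblique path) from one measurement."""
    if m.D1 == m.D2:
        raise ValueError("D1 == D2: zero denominator in the two-point formula")
    sec = 1.0 / math.cos(m.theta_rad)
    t1, t2 = m.T1_mm * sec, m.T2_mm * sec
    num = t2 * math.log(2 * m.D1 / m.D0) - t1 * math.log(2 * m.D2 / m.D0)
    return num / math.log(m.D1 / m.D2)


@dataclass(frozen=True)
class HVLProfile:
    """Symmetric lateral HVL profile with a cubic-spline interpolant."""

    positions_cm: np.ndarray  # measured positions, 0 .. x_max
    hvl_mm: np.ndarray
    _spline: CubicSpline

    @property
    def x_max_cm(self) -> float:
        return float(self.positions_cm[-1])

    def __call__(self, x_cm):
        """HVL at |x|; clamps to the endpoint value beyond x_max."""
        x = np.minimum(np.abs(np.asarray(x_cm, float)), self.x_max_cm)
        out = self._spline(x)
        return float(out) if out.ndim == 0 else out

    def save(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x_cm", "hvl_mm"])
            for x, h in zip(self.positions_cm, self.hvl_mm):
                w.writerow([f"{x:g}", f"{h:.6f}"])


def build_hvl_profile(measurements: Sequence[HVLMeasurement] | Sequence[tuple],
                      x_max_cm: float | None = None) -> HVLProfile:
    """Fit the symmetric lateral HVL profile from per-position measurements.

    Accepts HVLMeasurement objects (converted via :func:`hvl_two_point`) or
    pre-computed ``(x_cm, hvl_mm)`` pairs.  Data are mirrored about x = 0
    before fitting a natural cubic spline, which forces zero odd-order terms
    at the isocenter and hence an even (symmetric) profile.
    """
    pairs = []
    for m in measurements:
        if isinstance(m, HVLMeasurement):
            pairs.append((abs(m.x_cm), hvl_two_point(m)))
        else:
            x, h = m
            pairs.append((abs(float(x)), float(h)))
    pairs.sort()
    xs, hs = {}, []
    for x, h in pairs:
        if x in xs and abs(xs[x] - h) > 1e-9:
            raise ValueError(f"conflicting HVL values at x = {x} cm")
        xs[x] = h
    positions = np.array(sorted(xs))
    hvls = np.array([xs[x] for x in positions])
    if positions.size < 3:
        raise ValueError("need at least 3 distinct positions")
    if positions[0] != 0.0:
        raise ValueError("profile requires a measurement at x = 0")
    if np.any(hvls <= 0):
        raise ValueError("non-positive HVL value")
    if x_max_cm is None:
        x_max_cm = float(positions[-1])
    # Mirror about x = 0 (skip the duplicate origin knot).
    full_x = np.concatenate([-positions[:0:-1], positions])
    full_h = np.concatenate([hvls[:0:-1], hvls])
    spline = CubicSpline(full_x, full_h, bc_type="natural")
    keep = positions <= x_max_cm + 1e-12
    return HVLProfile(positions_cm=positions[keep], hvl_mm=hvls[keep],
                      _spline=spline)


def load_hvl_csv(path, sad_cm: float) -> list[HVLMeasurement]:
    """Read a measurement campaign CSV: ``x_cm,T1_mm,T2_mm,D0,D1,D2``."""
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    out = []
    for x, t1, t2, d0, d1, d2 in rows:
        out.append(HVLMeasurement(
            x_cm=x, T1_mm=t1, T2_mm=t2, D0=d0, D1=d1, D2=d2,
            theta_rad=oblique_angle(x, sad_cm),
        ))
    return out
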