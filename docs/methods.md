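# Methods

This note records the models, numerical choices and limitations behind
`ctkvdose`, in the order data flows through the package.

## Photon interaction data

Transport uses per-element tables (H, C, N, O, Al, P, Ar, Ca) of
photoelectric, coherent and incoherent cross sections (barns/atom) and
mass-energy absorption coefficients (cm²/g) on a sparse 1–150 keV grid,
interpolated log-log (positive, no overshoot — the standard choice for
photon coefficients). The tables are bundled as package data and
regenerated by `scripts/make_element_tables.py`:

* total mass attenuation for H, C, N, O and Al is anchored to standard
  published grid values;
* the incoherent part is Z·σ_KN(E) with the closed-form Klein–Nishina
  cross section and a smooth binding-suppression factor
  E²/(E² + 10·Z^⅔) (E in keV);
* the coherent part is a screened-form-factor power law 2.31·Z^2.4/E^1.9
  barns;
* the photoelectric part is the remainder (floored at zero); for P, Ar
  and Ca it is scaled from aluminum by (Z/13)^4.5, which ignores their
  K edges (3–4 keV, below the transport cutoff);
* μ_en/ρ = (σ_pe + σ_incoh·f_tr(E))·N_A/A, with f_tr the Klein–Nishina
  mean energy-transfer fraction computed by quadrature. Coherent events
  transfer no energy; fluorescence is neglected (low-Z media).

Everything downstream (HVL matching, kerma weighting, transport,
oracles) is self-consistent against these tables. Their absolute
accuracy against reference compilations is at the few-percent level for
the partition into channels and for μ_en/ρ; this cancels in the relative,
center-normalized doses the package reports, and in the HVL-matched
characterization, which constrains the spectrum by the same tables used
to compute kerma.

Mixtures use the weight-fraction mixture rule. Compositions for air,
water, PMMA (C₅O₂H₈, 1.18 g/cm³), aluminum and the ICRU-44 tissues
(soft tissue, lung, cortical and cancellous bone) are bundled; trace
elements not in the table set (Na, Mg, S, Cl, K, Fe, ≤1% by weight) are
folded into oxygen, as noted per material in `data/materials.json`.

## Spectrum model

Spectra live in 1 keV bins from 1 keV to the kVp and are normalized to
unit sum; only relative shapes matter (the absolute fluence scale cancels
in every reported quantity). The generator is semi-empirical: Kramers
bremsstrahlung N(E) ∝ (kVp−E)/E plus tungsten K lines (58.0, 59.3, 67.2,
69.1 keV) above the 69.5 keV K edge, their summed intensity a fixed
fraction of the continuum scaled by (kVp/E_K − 1)^1.65, then Beer–Lambert
attenuation through the stated aluminum filtration. Because the
characterization pins the spectrum to a *measured* HVL at the nominal
kVp, downstream dose is only weakly sensitive to the generator's fine
shape; the generator sits behind `generate_spectrum` so a table-driven
model can replace it without touching anything else.

HVL is computed in ideal narrow-beam geometry by bracketed root search
on the air-kerma ratio (tolerance 10⁻³ mm on [0, 30] mm); the inverse
problem — filtration matching a target HVL — is plain bisection with a
0.01 mm acceptance on the reproduced HVL. Both are deterministic.

## Characterization pipeline

The two-point HVL estimator is exact for monoenergetic beams and, with
slabs bracketing the HVL at ±10–15%, carries a polyenergetic
interpolation error well under 1%. Measured profiles are mirrored about
x = 0 before fitting a *natural* cubic spline (mirroring forces zero
odd-order terms at the isocenter, so the profile is even by
construction); beyond the last measured position (18 cm by default) the
profile clamps to its endpoint rather than extrapolating — sufficient
for the phantom sizes the package targets. Each grid position gets a
spectrum by HVL-matched filtration; lateral fluence follows from the
in-air dose by dividing out the local kerma integral; axial fluence is
the axial dose ratio. Both 1-D profiles are spline-resampled onto fine
uniform grids (0.25 cm lateral, 0.1 cm axial) and multiplied into the
separable fluence grid (max cell = 1). When no measured axial profile
exists, a trapezoid is used: flat across the nominal collimation with
0.4 cm linear penumbra shoulders per side.

## Source sampling and coordinates

Isocenter at the origin; x is the lateral (bow-tie) axis, z the axial
(couch) axis; at gantry angle α the point source sits at
(SAD·sin α, SAD·cos α, 0), and a full rotation is modeled by uniform α.
A photon's isocenter-plane position is drawn by inverse CDF over the
grid cells with uniform in-cell jitter; its energy comes from the
spectrum at the nearest |x| grid position (no spectral interpolation —
the error is bounded by the 2 cm measurement spacing). `sample_photon`
emits exactly this distribution with unit weights.

## Dose engine

Dose is collision kerma at the POI, per emitted photon, using the local
voxel's material μ_en/ρ (point tallies; `volume_effect_uncertainty`
exposes the chamber-volume alternative by sampling the dose spread over
four points on a 0.32 cm-radius circle, half the 6.4 mm active diameter
of a Farmer-type chamber).

**Primary** is deterministic: for each of 360 equally spaced gantry
angles (configurable) the POI is back-projected onto the isocenter-plane
grid (piecewise-constant cell lookup, matching the sampling density);
the contribution is the local spectrum's kerma-weighted sum attenuated
by the radiological path and scaled by (r_plane/r_POI)² — the
geometrically consistent form of the inverse-square law for a fluence
defined on the isocenter plane. Using the plane-referred solid-angle
factor (rather than a bare 1/r²) keeps the deterministic primary and
the Monte Carlo scatter on one normalization; any global constant
cancels in the center-normalized relative doses.

**Scatter** is a biased Monte Carlo with next-event estimation:

* emission is importance-sampled — lateral cells whose rays miss the
  phantom's bounding box are down-weighted (Gaussian tilt, floor 0.05),
  and energy bins are tilted by a fixed tissue-equivalent transmission
  factor exp(−(μ/ρ)_water·3 g/cm²) — with the true-to-sampling ratio
  carried as the photon weight, so all estimates remain unbiased;
* the gantry angle is stratified over each batch, and the lateral,
  axial and energy CDF inputs are randomized Halton points (bases 3, 5,
  2) with a fresh Cranley–Patterson shift per batch;
* the first collision is forced inside the grid (weight 1 − e^(−τ)) and
  its optical depth is sampled in four equal-probability strata; every
  stratum scores a channel-expected NEE to each POI (first-scatter
  component, weight w/4) and launches an independent continuation walk;
* walks force every subsequent flight (the escaping fraction is removed
  from the weight), score channel-expected NEE at each vertex
  (multiscatter component), and terminate on photoelectric absorption,
  the 5 keV energy cutoff (kV photons below it have sub-mm range in
  tissue), a 10⁻⁴ weight floor, or Russian roulette below weight 0.02
  with survival probability 0.25;
* NEE transport to a POI reuses one geometric traversal for both
  channels (per-material areal densities are energy-independent), and
  within 0.8 cm of a POI the 1/r² kernel is replaced by its volume
  average over that sphere — the standard bounded point-detector
  treatment, without which the estimator has unbounded variance from
  vertices adjacent to a POI.

Angular laws: incoherent scattering uses the free-electron
Klein–Nishina distribution (Kahn's rejection method) with the Compton
energy shift; the binding suppression applied to the *total* incoherent
cross section is not propagated to the angular shape — a deliberate
simplification, consistent between the engine, its estimators and the
analog oracle. Coherent scattering uses the Thomson law modulated by a
one-parameter screened form factor F(x) = (1 + x²/x₀²)⁻² with
x₀ = 0.43·Z_eff^⅓ Å⁻¹ (Z_eff from electron-fraction-weighted Z^2.94),
sampled by inverse CDF in x² with a (1+cos²θ)/2 rejection and
normalized numerically per material and energy for the NEE pdf.

Uncertainties come from ten independently seeded batches (standard
error of the batch means); the seed fully determines every stream, so
runs are bit-reproducible and per-POI results are independent of the
POI list order (all POIs are scored from the same walks).

## Ray tracing and phantoms

Voxel traversal is exact Amanatides–Woo stepping with half-open voxel
ownership [lower, upper) to resolve boundary ties; chord sums equal the
clipped segment length to 10⁻⁹ relative. Traversals accumulate
per-material ρ-weighted chords (areal densities), so one material table
serves any density range: μ_voxel(E) = (μ/ρ)_material(E)·ρ_voxel,
mirroring the HU→(material, density) mapping, which assigns half-open HU
ranges to (material, density) pairs. Phantom I/O uses NRRD (raw
little-endian encoding, written by a minimal reader/writer inside the
package) plus a JSON sidecar for the material table.

## Synthetic study conditions

The synthetic scanner stands in for the physical machines: a quadratic
bow-tie a + b·x² mm Al (defaults a = 2, b = 0.05, x in cm — produces
HVL roughly doubling from isocenter to x = 18 cm, qualitatively like a
clinical bow-tie; the exact coefficients are arbitrary and documented as
such), a Gaussian lateral fluence (σ = 12 cm, peak 1 at the isocenter)
and a trapezoidal axial fluence (2.0 cm collimation + 0.4 cm penumbra
shoulders). Measurement campaigns sample HVL at 2 cm intervals to
x = 18 cm with slabs at 0.9/1.1 of the local true HVL and multiplicative
Gaussian chamber noise (default 0.5%, the ion-chamber repeatability
regime; tests of recovery accuracy use 0%). The validation fixture is
the 15.2 cm-diameter PMMA cylinder (15 cm long, 2 mm voxels, air margin)
with 13 POIs: rings at 1, 2.5 and 4 cm depth (radii 6.6, 5.1, 3.6 cm) at
four 90°-spaced angles, plus the center. A five-material thorax stand-in
(elliptical body, two lungs with tumor spheres, cortical/cancellous
vertebra, documented HU breakpoints at −900/−400/150/500) exercises the
HU-mapping path with six named POIs, two off the axial field edge.

What the generator does *not* emulate: tube output (mAs) variation,
focal-spot size and heel effect, collimator scatter and leakage,
detector/electrometer behavior, helical or multi-slice acquisition.
Passing tests therefore demonstrate the internal consistency and
convergence of the characterization-plus-transport chain under ideal
measurement geometry, not agreement with any physical scanner.

## Verification strategy and problem sizes

The scatter engine is cross-checked against `analog_mc_oracle`, an
independent vectorized analog transport (free-path sampling, no
forcing, no NEE, track-length kerma tally in a small sphere) sharing
only the physics data and angular laws; agreement is asserted within
combined statistical uncertainty on a 10 cm water cube with a static
60 keV beam. The deterministic primary additionally matches closed-form
attenuation and inverse-square ratios to 10⁻⁶ or better.

The convergence study runs at its stated scale: 2×10⁵ seeded photons
against a 2×10⁶-photon reference over the 13 PMMA POIs (about five
minutes on one CPU); the seeding-ladder and uncertainty-scaling checks
use 10⁴–6.4×10⁵ photons. Characterization accuracy is bounded
end-to-end by comparing doses from the measurement-derived model with
doses from the ground-truth source on identical seeds.

## Known limitations

* Cross-section tables are compact semi-empirical compilations, not a
  live XCOM extraction; absolute (non-relative) dosimetry is out of
  scope, as are chamber calibration factors and Gy-scale output.
* Incoherent angular sampling ignores the scattering function; coherent
  scattering uses a one-parameter form factor. Both matter mostly below
  ~30 keV, where the photon weight in CT spectra behind a bow-tie is
  small.
* The bounded NEE kernel reports, within 0.8 cm of a POI, a
  sphere-averaged rather than point contribution from nearby vertices —
  of the same order as (and smaller than) a Farmer chamber's own volume
  averaging.
* No electron transport (kerma ≈ dose assumed, valid at kV energies),
  no fluorescence, no helical scanning or automatic exposure control.
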