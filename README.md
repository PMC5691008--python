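# ctkvdose

Machine- and patient-specific CT dose estimation starts from a problem of
characterization: the X-ray source of a clinical CT scanner is not directly
observable, but its two practical beam-quality descriptors — the nominal
tube potential (kVp) and the half-value layer (HVL) measured at points
along the bow-tie filter axis — are. `ctkvdose` turns those measurements
into a rotating virtual source model (spatially varying energy spectra plus
a relative 2-D fluence grid at the isocenter plane) and computes relative
absorbed dose at points of interest (POIs) inside voxel phantoms with a
deterministic primary component and a variance-reduced Monte Carlo scatter
component. It is aimed at medical-physics researchers who want
patient-specific CT dose beyond the fixed-phantom CTDI metrics.

## Method

**Source characterization.** At each lateral position *x* the HVL is
obtained from an open reading D0 and two filtered readings D1, D2 behind
aluminum slabs T1 < T2 bracketing the expected HVL, using the two-point
estimator (exact for a single exponential; `Tθ = T / cos θ` accounts for
the oblique ray to an off-axis chamber, `θ = arctan(x/SAD)`):

    HVL = [T2θ ln(2 D1/D0) − T1θ ln(2 D2/D0)] / ln(D1/D2)

The lateral HVL profile is mirrored about the isocenter and interpolated
with a natural cubic spline. For each position a spectrum is generated
from a semi-empirical tube model (Kramers bremsstrahlung + W K lines in
1 keV bins) by bisecting the aluminum filtration until the computed HVL
matches the measurement. The relative lateral fluence then follows from
in-air dose D(x) by dividing out each position's kerma integral,

    φ(x)/φ(0) = [D(x)/D(0)] · [Σ U′(0,E) (μ_en/ρ)_air E] /
                              [Σ U′(x,E) (μ_en/ρ)_air E],

while the axial fluence equals the axial dose profile directly (the
spectrum is constant along z). The two 1-D profiles, each normalized to
one, multiply into a separable 2-D fluence grid; the nominal collimation
is extended by a 0.4 cm linear penumbra per field edge.

**Dose computation.** Dose at a POI is collision kerma per emitted photon
(secondary electrons absorbed locally; fluorescence neglected). The
primary is a deterministic average over equally spaced gantry angles of
the attenuated, inverse-square-weighted kerma along the source–POI ray.
Scatter is Monte Carlo with forced collisions and next-event estimation
(NEE) at every scattering vertex — photoelectric, coherent
(Thomson × screened form factor) and incoherent (Klein–Nishina) channels —
split into first-scatter and multiscatter components, with batch-based
1-σ uncertainties.

## Worked example

```python
import numpy as np
from ctkvdose.synthetic import (SyntheticScanner, simulate_hvl_campaign,
                                simulate_air_dose_profiles,
                                make_pmma_cylinder_fixture)
from ctkvdose.source_model import characterize_source, default_axial_profile
from ctkvdose.dose_engine import compute_dose

scanner = SyntheticScanner(kvp=120, sad_cm=64.5)      # ground-truth bow-tie
x = np.arange(0, 18.1, 2.0)                           # 2 cm HVL spacing
meas = simulate_hvl_campaign(scanner, x, noise_rel=0.0)
z = default_axial_profile(scanner.collimation_z_cm)[0]
air_x, air_z = simulate_air_dose_profiles(scanner, x, z)
model = characterize_source(120, 64.5, meas, air_x, air_z,
                            collimation_z_cm=2.0)

phantom, pois, names = make_pmma_cylinder_fixture()   # 15.2 cm PMMA, 13 POIs
results = compute_dose(model, phantom, pois, n_photons=200_000, seed=1,
                       names=names, normalize_to="C")
for r in results[:3]:
    print(f"{r.name:8s} total={r.total:.4e}  scatter_frac="
          f"{r.scatter_fraction:.3f}  norm={r.normalized:.3f}")
```

prints (dose in relative units per emitted photon):

```
C        total=1.0954e-02  scatter_frac=0.578  norm=1.000
alpha_0  total=2.1796e-02  scatter_frac=0.367  norm=1.990
alpha_90 total=2.1871e-02  scatter_frac=0.369  norm=1.997
```

The center receives about half the dose of the 1 cm-deep ring positions,
and the scatter fraction rises from ~0.37 at the surface ring to ~0.58 at
the center — the attenuation-driven redistribution the rotating-source
model is built to capture.

The same pipeline is available from a shell:

```
ctkvdose synth --out campaign --noise 0 --seed 3
ctkvdose characterize --hvl campaign/hvl.csv --airdose-x campaign/airdose_x.csv \
    --airdose-z campaign/airdose_z.csv --kvp 120 --sad 64.5 \
    --collimation 2.0 --out model.json
ctkvdose dose --model model.json --phantom campaign/phantom \
    --pois campaign/pois.csv --photons 200000 --seed 1 --normalize C \
    --out dose.csv
```

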