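# carofret

Quantitative analysis of carotenoid delivery into fluorescently labelled
lipid membranes, built around two time-resolved fluorescence techniques:

1. **Polarized TCSPC anisotropy → membrane microviscosity.** Polarized
   decay histograms (VV, VH, HV, HH) are combined into the time-resolved
   anisotropy
   `r(t) = (I_VV − G·I_VH) / (I_VV + 2G·I_VH)` with the detector
   sensitivity ratio `G = I_HV / I_HH`. A multiexponential fit of r(t)
   gives the rotational correlation time θ (amplitude-weighted mean
   `θ = ΣÃ_j θ_j / ΣÃ_j`), which converts to the microviscosity of the
   probe's lipid environment via the Stokes–Einstein–Debye relation
   `θ = 4πηR³ / (3k_B T)`.

2. **FRET quantification of delivery.** The spectral overlap
   `J = ∫F_D(λ)ε_A(λ)λ⁴dλ / ∫F_D(λ)dλ` and the photophysical constants
   (donor quantum yield Φ_D, refractive index n, orientation factor κ²)
   give the Förster distance `R0 = 0.211(κ² n⁻⁴ Φ_D J)^{1/6}` Å. Transfer
   efficiency follows from donor lifetime quenching `W = 1 − τ_DA/τ_D`,
   the mean donor–acceptor distance from `R = R0(1/W − 1)^{1/6}`, and the
   amplitude share of the fast (quenched) donor component times the probe
   concentration bounds the concentration of acceptors actually delivered
   into the membrane. κ² itself can be computed from molecular-axis time
   series (`κ = d·a − 3(d·r)(a·r)`, time-averaged per frame), alongside
   tilt-angle and bilayer-depth densities that characterize carotenoid
   pose in the membrane.

A synthetic-data module emulates the whole measurement chain —
multiexponential decays convolved with a Gaussian IRF under Poisson
counting statistics, detector polarization bias, Gaussian-band spectra and
isotropic/cone-restricted orientation ensembles — so every stage is
testable against known ground truth without instrument data.

Intended users: fluorescence spectroscopists analysing polarized TCSPC
measurements of membrane probes, and anyone quantifying chromophore
delivery by lifetime-based FRET.

## Worked example

Simulate a labelled-liposome measurement (donor population 82% quenched at
1.45 ns, 18% unquenched at 5.601 ns; rotational correlation time 2 ns;
detector bias G = 1.2; 5×10⁶ photons per geometry), then run the full
analysis:

```python
import carofret as cf

truth = cf.GroundTruth(
    intensity_components=[(0.82, 1.45), (0.18, 5.601)],
    anisotropy_r0=0.35, anisotropy_components=[(1.0, 2.0)],
    g_true=1.2, total_counts=5e6, irf_fwhm=0.1, seed=7,
)
h = cf.simulate_polarized_decays(truth, cf.TimeGrid(0.0, 30.0, 4096))

G = cf.compute_g_factor(h["HV"], h["HH"])
aniso, total = cf.build_anisotropy(h["VV"], h["VH"], G)
rfit, theta = cf.fit_rotational_correlation(aniso, 1)
eta = cf.microviscosity(theta, temperature_K=293.15, probe_radius_nm=0.5)

ifit = cf.fit_multiexp(total, 2)          # lifetimes from the total intensity
frac = cf.fast_component_fraction(ifit)   # share of donors engaged in FRET

W = cf.efficiency_from_lifetimes(5.601, 4.971)
R = cf.distance_from_efficiency(59.0, 0.310)
```

Output:

```
G factor            : 1.2000
theta (ns)          : 1.992
eta (mPa s)         : 15.40
lifetimes (ns)      : [1.445 5.576]
amplitudes (%)      : [81.07 18.93]
fast fraction       : 0.8107
W(5.601, 4.971)     : 0.1125
R_DA(59 A, W=0.310) : 67.4 A
```

The estimated G factor, lifetimes and correlation time recover the
generator's ground truth to well under a percent at this photon budget; η
is the microviscosity a 0.5 nm probe with θ ≈ 2 ns reports at 20 °C; the
last two lines are the efficiency of donor quenching for the measured
lifetime pair and the mean donor–acceptor distance for a 59 Å Förster
distance at 31% efficiency.

The same chain is available from the shell:

```bash
carofret simulate --config sim.yaml --seed 7 --out decays.tsv
carofret gfactor decays.tsv
carofret anisotropy decays.tsv
carofret viscosity --theta-ns 2.0 --temperature-c 20 --probe-radius-nm 0.5
carofret fret --donor donor.tsv --acceptor acceptor.tsv --tau-d 4.51 --tau-da 3.1
carofret kappa2 trajectory.tsv
carofret run --config run.yaml --histograms decays.tsv --out result.json
```

All file formats are `#`-commented delimited text; see `docs/methods.md`
for the model details and conventions.

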