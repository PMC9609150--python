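# Methods

## Measurement model

A polarized TCSPC experiment records photon-arrival histograms in four
polarizer geometries (excitation/emission): VV, VH, HV, HH. The package
models the underlying physics as

* an isotropic intensity decay `I(t) = Σ_i A_i exp(−t/τ_i)` with
  amplitude fractions summing to 1,
* an anisotropy decay `r(t) = r0 Σ_j f_j exp(−t/θ_j)` with
  `0 ≤ r0 ≤ 0.4` (the one-photon photoselection limit),
* emission components `I_∥ = I(1+2r)/3` and `I_⊥ = I(1−r)/3`; with
  horizontal excitation both analyzer positions see the unpolarized
  component, so HV and HH share one expectation,
* a single wavelength-independent detector sensitivity ratio g applied as
  a factor 1/g on the horizontal-analyzer channels (VH, HH). This is
  deliberately minimal: a ratio is all the G-factor measurement
  `G = I_HV/I_HH` can identify,
* a Gaussian instrument response of configurable FWHM (default 0.1 ns, a
  convention for a picosecond-pulsed diode system; the true IRF of any
  given instrument should be measured) applied by discrete convolution,
* independent per-channel Poisson noise on the expected counts plus a
  uniform background rate. Pile-up, afterpulsing and dead-time are not
  modelled.

The default time grid is 0–25 ns in 4096 channels, matching a high-rate
TCSPC window; the grid must span at least five times the longest lifetime
so that tail fits are well posed, and must contain the ±5σ support of the
IRF. The photon budget `total_counts` is the expected magic-angle count
per geometry, so the total-intensity reconstruction `VV + 2g·VH` sums to
three times it. Identical seeds give bit-identical histograms.

What the generator does **not** emulate: liposome size heterogeneity,
probe partitioning kinetics, homo-FRET/aggregation, detector nonlinearity,
and wavelength-dependent polarization bias. Passing the recovery tests
therefore demonstrates correctness of the analysis chain under ideal
counting statistics, not robustness to every instrumental artifact of
real data.

## Decay fitting

Multiexponential fits (1–4 components) minimize weighted least squares
with lmfit's Levenberg–Marquardt. Poisson weighting uses
`var = max(counts, 1)`; uniform weighting is available for noise-free
model curves. Without an IRF the fit is a tail fit starting at the
histogram maximum (the default start policy; an explicit fit range can
override it); with an IRF the multiexponential is reconvolved with the
unit-normalized response and fitted over the full range.

Initialization and determinism: relaxation-time guesses are log-spaced
around the signal's 1/e time; amplitudes come from (non-negative) linear
least squares given those guesses; a fixed schedule of at most five
restarts rescales the guesses by {1, 0.3, 3, 0.1, 10} and the best
converged result is kept, so results are deterministic given data and
options. A free non-negative baseline absorbs dark counts. Non-convergence
is flagged (`success=False`) rather than silently returned, and a
component whose relative standard error exceeds 100% raises a
model-order warning.

Numerical note: on noise-free data the optimizer stops at its tolerance
floor rather than at the exact minimum, so adding a redundant component
can change χ² within that floor (bounded by the 1e-8-of-peak residual
invariant) without ever meaningfully increasing it.

Amplitudes are reported both on the data scale and as percentages of the
total amplitude. The amplitude-weighted mean `Στ_iA_i/ΣA_i` summarizes a
fit; the amplitude share of the fastest component is the fraction of
donors engaged in energy transfer in a quenching experiment.

Lifetimes must be fitted on the anisotropy-free total intensity
`I = VV + 2G·VH`, not on a single polarized channel: the VV channel decays
faster than the true lifetime by the rotational depolarization term.

## Anisotropy and microviscosity

G is estimated from integrated window counts `ΣHV/ΣHH` (optionally
baseline-subtracted) rather than a channel-wise ratio, which is unstable
at low counts; the window must hold at least 100 counts in each
histogram. r(t) is formed channel-wise; channels whose denominator
`VV + 2G·VH` falls below 30 counts are masked (keeping the per-channel
standard error of r below ≈0.03), never clamped. The per-channel variance
of r is propagated from Poisson counts of VV and VH and weights the
multiexponential fit of r(t). By default no r_∞ offset (hindered-rotor
plateau) is fitted; a flag enables it.

The Stokes–Einstein–Debye conversion `η = 3k_BTθ/(4πR³)` reports η in
mPa·s (≡ cP) — note η is proportional to T at fixed θ, while θ at fixed η
scales as 1/T. The probe's hydrodynamic radius R is a required user
input; no literature default is assumed, since reported probe radii vary
with the embedding medium. The inverse `theta_from_viscosity` round-trips
to 1e-12 relative.

## Förster analysis

The overlap integral is trapezoidal on the union of the two wavelength
grids with linear interpolation, zero outside each spectrum's support; it
is invariant to rescaling of the donor emission and carries units
M⁻¹cm⁻¹nm⁴ for λ in nm. The Förster-distance prefactor is pinned to the
0.211 Å convention for those units. Acceptor spectra supplied in arbitrary
units are rescaled so their maximum equals a user-supplied peak molar
extinction; defaults are 75,300 M⁻¹cm⁻¹ (echinenone) and
125,300 M⁻¹cm⁻¹ (β-carotene), with Φ_D = 0.95 and n = 1.4251 as the
default donor quantum yield and membrane refractive index.

Efficiency uses amplitude-weighted mean lifetimes by default, matching
how τ_av characterizes multiexponential donor decays. `W = 1 − τ_DA/τ_D`
rejects τ_DA > τ_D (a negative efficiency signals swapped inputs).
`R = R0(1/W−1)^{1/6}` is undefined at W ∈ {0,1} and errors there. The
delivered-concentration estimate assumes one acceptor per quenched donor
by default; the stoichiometry is an explicit parameter.

## Orientation statistics

κ² uses the dynamic-averaging regime: the per-frame
`κ = d·a − 3(d·r)(a·r)` is squared and time-averaged, appropriate when
reorientation is fast relative to the transfer time; the alternative
(κ of time-averaged vectors) is not computed. Molecular axes are treated
as headless — transition dipoles and polyene long axes have no
directionality — so tilt angles fold into [0°, 90°] via
`φ = arccos|axis·n̂|`. Tilt densities are raw histogram densities by
default (no solid-angle correction); a `sin_corrected` flag divides by
sin φ and renormalizes, under which an isotropic axis yields a flat
density. Depth densities clip out-of-bilayer values into the edge bins
and report the clip count. Two-state occupancy is simply the fraction of
frames beyond a user-chosen tilt boundary; no boundary is hard-coded
because the split between membrane-spanning and membrane-parallel states
is system-dependent.

Trajectory input is a plain delimited table of per-frame unit vectors
(normalized on read), not a binary MD format: any simulation engine can
export to it, and running MD is out of scope.

## Test problem sizes

Monte-Carlo checks use 10⁶ frames for sphere-moment and κ² convergence
(standard error ≈ 8×10⁻⁴ on κ²) and 10⁵ frames for the sin-law χ²
goodness-of-fit. Parameter-recovery suites use the packaged two-component
fixture — 82% at 1.45 ns plus 18% at 5.601 ns, θ = 2 ns, g = 1.2,
5×10⁶ counts per geometry, 0.1 ns IRF on a 30 ns / 4096-channel grid —
over 20 fixed seeds; the full suite runs in a few seconds on one core.

## Known limitations

* Weighted least squares, not Poisson maximum likelihood: at very low
  counts per channel the fitted lifetimes acquire the usual WLS bias.
* Tail fitting discards the rise; with broad IRFs relative to the fastest
  lifetime, use reconvolution mode.
* No global (linked multi-curve) analysis and no associated-anisotropy or
  wobble-in-cone models.
* The anisotropy fit assumes the same r(t) for every intensity component
  (one rotating species).
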