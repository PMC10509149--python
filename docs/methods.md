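# Methods

`braggfricke` models a track-end radiolysis measurement: a proton or
carbon-ion beam stops inside a 10-mm cuvette of super-Fricke solution while a
linear bundle of 20 optical fibres images the growth of the Fe³⁺ absorbance
at 304 nm along the last millimetres of the track. The forward model predicts
the per-fibre absorbance time series from a known yield profile; the inverse
pipeline turns measured (or simulated) time series into track-segment yields
G(Fe³⁺)(x). This note records the model, its assumptions, the defaults, and
the choices made where the design was open.

## Charged-particle transport

Stopping power is the relativistic Bethe formula with Bragg additivity over
the material composition and a material-level mean excitation energy
(I = 75 eV water and super-Fricke, 74 eV PMMA, 85.7 eV air — standard ICRU
values). No shell, Barkas/Bloch or density-effect corrections are applied:
in the 1–100 MeV/u window that dominates these beams they shift the stopping
power by a few percent, below the accuracy claimed for the dose-rate model.
The super-Fricke solution is treated as water at the measured solution
density of 1.024 g/cm³ (the solutes are ≤ 10 mM).

The Bethe evaluation stops at 0.5 MeV/u. Energy still carried there (about
0.5 MeV for a proton) is deposited in the bin where the ion crosses the
cutoff; the straggling convolution dominates the curve shape in that region
anyway. Energy–range tables are built once per (material, projectile) on a
4000-point log grid up to 2 GeV/u and inverted with monotone (PCHIP)
interpolation; degrader transport is range subtraction on these tables, so
`degrade_energy` is exact within the CSDA and composes over a material
stack.

### Straggled ELF curve

The depth profile of energy loss per ion (ELF, MeV/mm) inside the sample is
the CSDA curve of the mean-energy ion convolved with a single Gaussian in
depth. Its width combines, in quadrature:

* range straggling, σ_R = 0.012 R^0.951 (R in cm), an empirical power law
  for protons in water-like media, reduced by √(M/Mₚ) for heavier ions. R is
  the CSDA range of the **initial** beam energy expressed in the sample
  material: straggling accumulates over the whole path, degrader included,
  which is why the degraded 25-MeV proton peak is several times broader than
  a pristine 25-MeV beam would suggest, while the carbon peak stays narrow;
* the initial energy spread mapped through dR/dE at the initial energy
  (0.3 MeV for the proton beamline; the carbon beamline's spread is not
  specified and defaults to 0).

The convolution is evaluated on an extended grid and cropped, so the depth
integral of the ELF equals the energy entering the sample to better than 1%
(re-normalised within that margin; a warning is raised if the peak leaks out
of the sample window). The depth grid is uniform (10 µm default, ≤ 50 µm
required to resolve the fibre pitch) with half-open bins, depth 0 at the
sample entrance. Angular/lateral straggling and nuclear fragmentation are
out of scope.

### Dose rate

Under the constant-volume assumption (the collimated 8-mm beam defines a
cylinder), dD/dt(x) = ELF(x) · N_ions / (ρ A_beam), with the particle rate
N_ions = I/(z·e). Dividing the electrical current by the full ion charge is
a deliberate choice: a 0.1 nA C⁶⁺ current is ~1×10⁸ ions/s, not 6×10⁸. A
`single_charge` switch reproduces the single-elementary-charge convention for
comparison. Dose rate is exactly linear in the current.

## Super-Fricke chemistry

The dosimeter response is the five-reaction oxidation scheme (rate constants
k₁ = 2.3×10¹⁰, k₂ = 2.1×10¹⁰, k₃ = 4.3×10⁸, k₄ = 42, k₅ = 2.1×10⁶ M⁻¹s⁻¹).
Reaction 5 is implemented with the H₂O₂-regenerating stoichiometry
(Fe²⁺ + HO₂˙ → Fe³⁺ + H₂O₂ + OH⁻); conventional acid-solution chemistry
writes this step differently, but this stoichiometry is exactly what makes
the observed ferric yield the linear combination

    G(Fe³⁺) = G(˙OH) + 2 G(H₂O₂) + 3 (G(e⁻aq) + G(˙H) + G(HO₂˙)),

which the stiff-ODE simulation (`simulate_mechanism`, LSODA) reproduces to
better than 0.1% once the slow Fe²⁺ + H₂O₂ step (τ ≈ 2.4 s at 10 mM Fe²⁺)
reaches steady state. Unit conversion uses the exact factor 1 molecule/100 eV
= 1.036×10⁻⁷ mol/J. No individual primary yields are hard-coded as truth;
`LOW_LET_PRESET` is a labelled literature-style fixture whose combination
gives the conventional low-LET limit of 15.6 molecules/100 eV.

Defaults for quantities the recipe implies but does not number: [H₃O⁺] =
0.4 M (first proton of H₂SO₄ fully dissociated, second ignored) and [O₂] =
1.3 mM (O₂-saturated water at 1 atm, 25 °C); both config-overridable.

The dose response C(D) = G·ρ·D_eff uses the saturation mapping
D_eff = D_sat (1 − e^(−D/D_sat)) with D_sat set so that the departure from
linearity reaches 5% at the variant's dose limit (500 Gy classic Fricke,
10³ Gy super-Fricke). This reproduces the observed gradual onset of
sub-linearity without claiming mechanistic detail; the ODE model is
available when fidelity matters. The *visible* saturation of a simulated
trace is keyed to the 500 Gy classic limit, which is the dose scale where
the measured traces bend.

## Synthetic data generator

The generator's defaults are the measurement conditions: 20 fibres of
250 µm diameter at magnification 8/9, each observing a contiguous half-open
281.25-µm interval (fibre 20 shallowest); 100-ms frames for 60 s; beam on at
2 s; 8-mm beam; 0.8-cm optical path. The depth offset of the fibre window in
the cuvette is not a published quantity; the default (3.0 mm) puts the
25-MeV proton peak on fibre 10, and it is config-exposed.

The concentration field evolves per frame: linear-regime production
G(x)·ρ·dD/dt(x)·dt attenuated by the saturation slope; 1-D axial diffusion
(D = 6.07×10⁻¹⁰ m²/s for Fe³⁺ at 25 °C) applied as a Gaussian kernel with
reflecting walls, which conserves mass to machine precision; and radial
escape from the beam cylinder as a deterministic dilution
(d/(d+2√(4Dt/π)))², calibrated against the ~28 µm/s boundary-blur estimate —
diffusion is a perturbation here, not a full 3-D solve. Detector noise is
applied in transmitted-intensity space (relative σ 0.5% per frame, plus
optional common-mode flicker), so the absorbance noise is heteroscedastic as
in real transmission data. What the generator does **not** emulate: beam
current drift, spectral response, stray light, cuvette-to-cuvette thickness
variation, stirring. A passing recovery test therefore demonstrates the
inverse pipeline's correctness under the stated statistical structure, not
robustness to every real-beamline systematic.

## Inverse pipeline

Beam-on detection thresholds the summed cross-fibre absorbance increment at
5× the baseline noise sustained for 3 frames (≥ 1 s of baseline required).
Initial slopes are unweighted OLS over the first 10 frames (protons) or 15
frames (carbon) after onset; an optional scan rule picks the smallest
n ∈ [5, 30] with r² ≥ 0.95 instead. The Bragg peak is the fibre of steepest
slope, refined to sub-fibre precision by parabolic interpolation through its
two neighbours; exact ties resolve to the deepest fibre with a warning.

ELF alignment translates the computed curve so its maximum falls on the
located peak. The model curve's position is measured with the *same*
fibre-binned parabolic estimator as the data, so the estimator's shape bias
cancels and a deliberate 1-mm misalignment is corrected to < 0.05 mm on
synthetic runs. A caveat discovered while validating: when the true yield
varies with depth, the slope profile peaks where G(x)·ELF(x) is maximal,
not where ELF is, so peak-matching alignment is *intrinsically* biased (up
to ~2 mm for a yield varying 15 → 5 across the peak) and inflates
steep-gradient distal yields. `align="none"` keeps the ELF's absolute depth
registration instead, which is exact for synthetic data and appropriate
whenever the ELF was computed from the actual run geometry; `align="peak"`
remains the default because a real measurement has no absolute registration.

Yields follow G = (dA/dt)₀ / (ρ·ε·l·dD/dt) with ε = 2212 M⁻¹cm⁻¹ and
l = 0.8 cm. Fibres whose aligned ELF falls below 1% of the maximum are
reported as undefined (NaN): nonzero growth there is the post-range
diffusion signature, and dividing by a vanishing ELF would fabricate huge
yields. Uncertainty bands are the min/max envelope over ELF alignment
shifts of ±1 fibre, widened by twice the propagated OLS slope standard
error (the envelope alone collapses to zero width at shift-insensitive
fibres); they are an envelope, not a parametric confidence interval, and
replicate runs are averaged when supplied.

## Problem sizes and numerical settings

Depth grid 10 µm over the 10-mm sample (1000 bins); energy–range tables
4000 points; ODE tolerances rtol 1e-8 / atol 1e-15; simulated acquisitions
in the test-suite run 6–12 s of beam time at 10 Hz, which brackets the
initial-slope window and the saturation onset. Reported dose-rate maxima are
averaged over 281.25-µm fibre bins to match what the imager can resolve; the
unbinned profile maximum is used when the point dose rate at the peak is the
quantity of interest (e.g. dose accumulated at the peak in a few seconds).

## Known limitations

* Bethe without low-energy corrections overestimates the stopping power
  below ~1 MeV/u; the cutoff-plus-convolution treatment hides this in the
  peak bin but the pristine (unstraggled) peak height is not trustworthy.
* The empirical straggling power law carries ~10–20% uncertainty in σ, which
  propagates directly into the binned peak dose rate (the ±25% band on the
  dose-rate checks reflects this).
* The radial-escape dilution is a calibrated first-order surrogate, accurate
  only while diffusion remains a small perturbation (tens of seconds).
* Peak-matching ELF alignment is biased for depth-varying yields (above);
  real-data distal yields inherit that bias exactly as the measurement
  procedure does.
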