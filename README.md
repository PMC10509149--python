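# braggfricke

Track-end radiolysis of the super-Fricke dosimeter: a forward model of Fe³⁺
formation along a stopping proton or carbon-ion track read out by a 20-fibre
absorbance imager, and the inverse pipeline that converts the absorbance
time series into sub-millimetre **track-segment yields** G(Fe³⁺)(x).

## The problem

Near the Bragg peak (BP) of a therapeutic ion beam the linear energy
transfer (LET = −dE/dx) rises steeply and the radiation chemistry of water
changes: the dense ionization track suppresses the escape of radicals, so
the radiolytic yield (G-value) of Fe³⁺ in a Fricke dosimeter drops. Mapping
G(Fe³⁺) along the last millimetres of the track at sub-millimetre resolution
probes exactly the region that matters for proton and carbon-ion therapy.
The measurement this package models: a collimated 8-mm beam stops inside a
10-mm cuvette of super-Fricke solution (10 mM Fe²⁺, 0.4 M H₂SO₄, 1 mM NaCl,
O₂-saturated) while 20 optical fibres, each imaging a 281.25-µm depth
interval, record the 304-nm absorbance A(t, x) of the Fe³⁺ being produced.

## The model

Per fibre, the early-time absorbance grows linearly and the track-segment
yield follows from Beer–Lambert plus the local dose rate:

    G(Fe³⁺)_x = (dA/dt)₀ / (ρ · ε · l · (dD/dt)_x),
    (dD/dt)_x = ELF(x) · I / (z·e · ρ · A_beam),

with ε = 2212 M⁻¹cm⁻¹ (304 nm, 25 °C), l = 0.8 cm, ρ = 1.024 kg/dm³, I the
beam current and ELF(x) the energy loss per ion per unit depth. The ELF is
computed analytically: Bethe stopping power with Bragg additivity, CSDA
range tables, degrader transport, and a Gaussian depth convolution that
combines empirical range straggling (σ_R = 0.012 R^0.951, R in cm, reduced
by √(M/Mₚ) for heavier ions) with the initial energy spread. The observed
ferric yield is the linear combination of the water-radiolysis primary
yields, G(Fe³⁺) = G(OH) + 2 G(H₂O₂) + 3 (G(e⁻aq) + G(H) + G(HO₂)), and the
full five-reaction oxidation mechanism is available as a stiff-ODE
simulation. See `docs/methods.md` for assumptions and defaults.

## Worked example

Simulate the degraded proton beamline (64 MeV → 23.57 mm PMMA → 10-mm
cuvette, 1 nA) with a flat truth of 15 molecules/100 eV, then invert:

```python
import numpy as np
from braggfricke import (BeamSpec, MaterialStack, PROTON, PMMA, SUPER_FRICKE,
                         GroundTruth, AcquisitionSpec, MOL_PER_J_PER_MOLEC100EV,
                         bragg_elf_curve, simulate_run, analyze_records)

beam = BeamSpec(PROTON, 64.0, 0.3, 1e-9, 8.0)        # 0.3 MeV spread, 1 nA
stack = MaterialStack(((PMMA, 23.57), (SUPER_FRICKE, 10.0)), sample_index=1)
profile = bragg_elf_curve(beam, stack)
print(profile.metadata)   # energy at sample 27.18 MeV, peak at 6.775 mm,
                          # straggling sigma 0.478 mm

truth = np.full_like(profile.depth_grid, 15 * MOL_PER_J_PER_MOLEC100EV)
gt = GroundTruth(truth, profile, beam)
records = simulate_run(gt, acq=AcquisitionSpec(duration=10.0, beam_on_time=2.0),
                       rng=np.random.default_rng(7))
yields = analyze_records(records, profile, beam)
print(yields.metadata["bp_fibre"])                   # 7
print(yields.to_frame().head(3))
```

which prints (fibre 20 is the shallowest):

```
fibre  depth_mm  elf_MeV_per_mm  dose_rate_Gy_s  G_molec_per_100eV
   20  3.140625        2.717756       52.800820          14.774183
   19  3.421875        2.809398       54.581248          14.893507
   18  3.703125        2.912054       56.575658          14.648749
```

The recovered yields sit within ~2% of the 15 molecules/100 eV truth at this
noise level; the BP lands on fibre 7 where the dose rate peaks at ~131 Gy/s
for 1 nA. Fibres beyond the distal falloff are reported as NaN — their
absorbance growth comes from Fe³⁺ diffusion, not local dose.

The same workflow is available from the shell:

```
braggfricke simulate --config sim.yaml --out runs/demo/
braggfricke analyze  --traces runs/demo/traces.csv --elf runs/demo/elf.tsv \
                     --beam sim.yaml --out yields.tsv
braggfricke recover  --config sim.yaml --out runs/recovery/
braggfricke stopping --beam sim.yaml --out elf.tsv
```

Every run writes a `manifest.json` (config snapshot, seed, digests); the
same config and seed reproduce byte-identical tables.

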