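# magrheo

Magnetic-tweezer microrheology of living cells and extracellular-matrix
networks: force calibration, sub-pixel bead tracking, creep-compliance
analysis, population statistics and 3D pore-size determination — with a
virtual instrument that generates every input with known ground truth, so
the entire measurement chain can be exercised and validated without
hardware.

## Who this is for

A single-pole electromagnetic tweezer pulls a fibronectin-coated 4.5 µm
superparamagnetic bead that is bound to a cell or embedded in a collagen
gel. The bead's displacement under nanonewton force steps, imaged in
brightfield at up to 40 Hz, reports the local viscoelasticity of the
material. This package implements the software side of such an instrument:
the calibration and feedback mathematics, the image analysis, the
rheological model fitting and the downstream statistics — plus a simulator
standing in for the hardware.

## The models

**Force calibration.** The force on the bead depends on coil current *I*
and bead–needle distance *d* through an empirical power law with a
current-dependent exponent:

```
F(I, d) = F0 · d^c(I),        c(I) = c1 / (1 + c2 · exp(c3 · I))
```

The parameters are fitted from viscous-drag measurements in PDMS of known
viscosity (drift-corrected bead velocity → Stokes force `F = 6πηRv`, then
a per-current log–log fit of F vs d, then a nonlinear fit of the exponents
vs current). The constant-force feedback loop uses the exact algebraic
inverse `I(F, d)` to adapt the current as the bead approaches the needle.

**Creep compliance.** With the bead cross-section `A = πr²` as the contact
area, a force step ΔF applies the stress `σ = ΔF/(πr²)`; the strain is
`ε = d(t)/r`, so the compliance is the displacement curve scaled by
`πr/ΔF`:

```
J(t) = ε/σ = d(t) · πr / ΔF            [1/Pa]
```

Two models are fitted: the weak power law `J(t) = J0 (t/t0)^β` (with
t0 = 1 s; 1/J0 is the stiffness in Pa and β the fluidity, 0 = elastic,
1 = viscous) and the Kelvin–Voigt form `J(t) = J0 (1 − e^(−t/τ))`.
Multi-step protocols (pulse trains, staircases) and the relaxation after
force-off are analyzed by Boltzmann superposition of the responses to
every force-change event.

**Populations and pores.** Stiffness is log-normally distributed across
cells, so populations are summarized by the geometric mean and compared by
Welch's t-test on log values with explicit Bonferroni correction; fluidity
is normal and uses the arithmetic mean. Collagen-network architecture is
quantified by segmenting the fibril phase of a confocal volume and
greedily packing maximal inscribed spheres into the fluid phase of its
Euclidean distance transform ("pore sizes").

## Worked example

```python
import numpy as np
import magrheo as m
from magrheo.simulate import simulate_calibration_table

# 1. calibrate the (virtual) instrument by viscous drag in 5000 cSt PDMS
truth = m.CalibrationModel(F0=700.0, c1=-4.0, c2=1.0, c3=1.0,
                           current_range=(0.2, 1.0), distance_range=(40, 160))
cfg = m.SimulationConfig(drift_velocity_um_s=0.1)
table = simulate_calibration_table(truth, [0.2, 0.35, 0.5, 0.65, 0.8, 1.0],
                                   [70, 80, 90, 100, 110, 120],
                                   viscosity_pa_s=4.85, bead_radius_um=2.25, cfg=cfg)
cal = m.fit_calibration(table, 4.85, 2.25)
print(f"fitted law: F(I,d) = {cal.F0:.1f} * d^c(I),  "
      f"c(I) = {cal.c1:.3f}/(1 + {cal.c2:.3f} e^({cal.c3:.3f} I))")
print(f"force at 0.8 A, 80 um: {m.force_at(cal, 0.8, 80.0):.3f} nN")
print(f"current to hold 2 nN at 80 um: {m.current_for_force(cal, 2.0, 80.0):.4f} A")

# 2. a single 1 nN / 2 s pulse on a soft cell (300 Pa, fluidity 0.45)
mat = m.MaterialModel("power_law", J0=1/300, beta=0.45)
prot = m.ForceProtocol.single_pulse(1.0, 2.0, t_start=0.5)
traj = m.simulate_creep_displacement(
    mat, prot, 2.25, m.SimulationConfig(noise_sd_position_um=0.005, seed=1))
disp = traj.displacement_um()
on = (traj.time_s > 0.5) & (traj.time_s <= 2.5)
curve = m.displacement_to_compliance(traj.time_s[on] - 0.5, disp[on], 1.0, 2.25)
pl, kv = m.fit_power_law(curve), m.fit_kelvin_voigt(curve)
print(f"power law:    J0 = {pl.J0:.3e} 1/Pa  (stiffness {pl.stiffness_pa:.0f} Pa), "
      f"beta = {pl.beta:.3f}, R^2 = {pl.r_squared:.4f}")
print(f"Kelvin-Voigt: J0 = {kv.J0:.3e} 1/Pa, tau = {kv.tau:.2f} s, R^2 = {kv.r_squared:.4f}")

# 3. population statistics over two simulated groups
a = m.sample_population(np.log(277), 0.5, 0.46, 0.1, n=100, seed=2)
b = m.sample_population(np.log(600), 0.5, 0.36, 0.1, n=100, seed=3)
sa = m.summarize_stiffness(a.stiffness_pa)
print(f"group A stiffness: GM {sa.geometric_mean_pa:.0f} +/- {sa.error_pa:.0f} Pa (n = {sa.n})")
r = m.compare_groups(a.stiffness_pa, b.stiffness_pa, "stiffness", n_comparisons=6)
print(f"Welch on log-stiffness: p_bonf = {r.p_bonferroni:.2e}  {r.stars}")
```

prints

```
fitted law: F(I,d) = 700.1 * d^c(I),  c(I) = -4.007/(1 + 1.003 e^(0.999 I))
force at 0.8 A, 80 um: 3.055 nN
current to hold 2 nN at 80 um: 0.6892 A
power law:    J0 = 3.425e-03 1/Pa  (stiffness 292 Pa), beta = 0.435, R^2 = 0.9991
Kelvin-Voigt: J0 = 4.488e-03 1/Pa, tau = 0.61 s, R^2 = 0.9427
group A stiffness: GM 276 +/- 13 Pa (n = 100)
Welch on log-stiffness: p_bonf = 1.22e-19  ***
```

The calibration recovers the injected law to a fraction of a percent, the
creep fit recovers the 300 Pa / β = 0.45 material from a noisy record (and
prefers the power law over Kelvin–Voigt, R² 0.999 vs 0.943), and the two
populations — a factor ~2 apart in stiffness — separate at p ≪ 0.001.

## Command line

Each analysis stage is also a CLI subcommand driven by a JSON/YAML config
(`magrheo simulate|calibrate|track|analyze|pores|stats --config c.json
--out outdir`). Every run writes its resolved configuration (with hash and
version) next to its CSV/JSON outputs; a single seed governs all
stochastic stages, and reruns are byte-identical.

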