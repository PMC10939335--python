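# Methods

This note records the models behind `thermoseed`, the defaults and why
they were chosen, and what the package's tests do and do not demonstrate
about real benches.

## Scene and coordinates

Right-handed Cartesian coordinates, z along the coil axis, origin at the
coil's geometric centre. The reference scene is a homogeneous
ferromagnetic scaffold cylinder (⌀20 mm × 20 mm, iron-loaded PLA) centred
in an agar phantom cylinder (⌀25 mm × 40 mm), both concentric with an
8-turn single-layer solenoid. The bench this emulates does not publish
the coil bore or height, so the defaults — inner radius 25 mm, 8 turns
evenly spaced over 48 mm (pitch 48/7 mm), wire radius 2 mm — are typical
of commercial 8-turn induction heads and fully configurable. In
misplacement sweeps the scaffold and phantom move **rigidly together**
(the gel holds the embedded sample); probes are drilled into the scaffold
and move with it.

Material properties (relative permittivity, conductivity S/m, thermal
conductivity W/(m K), specific heat J/(g K), density g/cm³):

| material  | ε_r | σ      | k    | C_p  | ρ    |
|-----------|-----|--------|------|------|------|
| agar      | 70  | 0.2    | 0.48 | 4.2  | 1.0  |
| iron-PLA  | 3   | 1e-5   | 0.47 | 1.2  | 2.7  |
| PLA       | 2.5 | 1e-6   | 0.29 | 1.8  | 0.9  |
| water     | 78  | 5.5e-6 | 0.60 | 4.186| 0.998|

Non-SI table units are converted to SI exactly once, at the
`MaterialProps.from_table` boundary. The iron-PLA density of 2.7 g/cm³ is
taken as tabulated for the 40 wt% iron composite. The water row uses
standard distilled-water values near room temperature (the in-water setup
is a comparison case, not a tabulated one).

## Field solver

At 400 kHz over centimetres the problem is deeply quasi-static, and the
dilute composite perturbs the applied field weakly, so the field is
computed in free space: each turn is a circular filament with the exact
elliptic-integral closed form, and the solenoid is their superposition.
The scaffold's magnetic nonlinearity enters only through the loss model,
never the field map. This replaces a full vector-potential FEM solve with
something closed-form verifiable; the trade-off is that scaffold-induced
field distortion (a few percent at these filling fractions) is ignored.

Conventions: all field "amplitudes" are sinusoid peaks, not RMS;
H = B/μ₀. The drive current is calibrated by linearity so |B| at the coil
centre equals the 30 mT target. The homogeneity statistic ξ uses the
magnitude |H| and the sample (n−1) standard deviation over grid nodes in
the scaffold; a perfectly uniform field reports ξ = +∞ with a flag.

The induced azimuthal field uses Faraday's law on the axisymmetric
geometry: |E_φ(r,z)| = ω|Φ(r,z)|/(2πr), with Φ the trapezoidal flux
integral of B_z over the disc of radius r. E_φ → 0 on the axis.

The pickup-coil conversion is the single-flux-linkage Faraday formula
H = V_pp / (2 n ω μ₀ π (d/2)²); the probe's physical height is metadata
only.

## Hysteresis loss model

The per-cycle volumetric loss is the BH loop area, `P_m = f·A_hyst`.
Measured loops load from CSV (columns `H_A_per_m, B_T, branch`); the
synthetic generator uses sigmoid branches `B = B_s tanh((H ± H_c)/w)`.

Where the local drive amplitude H_a is below the loop span, the loop is
**truncated** to ±H_a: branches clipped and closed by vertical switching
segments, giving a per-cycle area `A(H_a) = ∫_{−H_a}^{H_a} ΔB(H) dH` that
is continuous, zero at zero drive, non-decreasing, and exactly the full
loop area at full drive. This rule is deterministic and oracle-checkable,
and it reduces to the plain loop-area formula under a uniform field. Its
notable consequence: because the branch gap ΔB is largest at H = 0, the
truncated area grows at most linearly with amplitude, so deposited power
never rises faster than the local field. Real minor loops (Rayleigh
regime) can be steeper than linear; this is the model's main known bias
and is discussed under Limitations.

**Default loop calibration.** The default synthetic loop puts the
23.9 kA/m operating amplitude below the coercivity (H_c = 30 kA/m,
w = 5 kA/m, H_max = 800 kA/m — the constant-gap regime where power tracks
the local field), and sets the B-scale so that the adiabatic centre-probe
slope maps through the agar-C_p SAR definition to exactly 1.0 W/g, the
scale reported for scaffolds of this class. The resulting saturation
induction (≈ 2×10⁻⁵ T) is an *effective* calibration constant — it
absorbs the narrowing of real minor loops relative to the truncated major
loop — and must not be read as the composite's physical magnetization.
Superparamagnetic loss laws can be substituted by supplying a per-node
mass-power function in place of the loop.

Eddy/dielectric background heating is `P_e = ½σ|E_φ|²` with the local
conductivity (agar 0.2 S/m dominates; the scaffold's 10⁻⁵ S/m is
negligible). For the calibrated scene the magnetic term exceeds the
background by well over an order of magnitude, but the agar term is kept
because it heats the O-probe region.

## Heat solver

Finite-volume conduction on a uniform voxel grid (region labels by
voxel-centre membership), harmonic-mean interface conductivities, and a
Robin condition on every solid face exposed to ambient air — flux
= h_a(T_surf − T_a) with the half-cell conduction resistance in series.
Ambient air is never meshed. h_a defaults to 10 W/(m² K) (free convection
in air); T_a = 19 °C is also the uniform initial condition. Sources are
on for t < t_off (default 600 s) and zero after; the default run
continues to 900 s to capture cooling.

Time stepping is implicit backward-Euler with Δt = 0.1 s, so stability is
independent of resolution; the system matrix is factorized once (LU) and
re-used every step. An explicit CFL-limited mode exists for
cross-checking. With h_a = 0 the scheme conserves energy to round-off by
construction, which the tests verify.

The in-water setup does not resolve fluid flow. The convective term is
replaced by an effective-conductivity surrogate: water voxels get
k_eff = k_water · max(1, Nu), with `Nu = C·Ra^{1/4}` (enclosure
correlation, default C = 0.29), the Rayleigh number built on the 2.5 mm
radial scaffold–wall gap and the instantaneous scaffold-surface minus
water-average temperature difference, re-evaluated every 5 s of simulated
time (the matrix is re-factorized only when the factor moves by more than
0.01). The correlation constant and exponent are configuration, not
physics: the surrogate reproduces the *magnitude* of convective flattening
(a few K at bench conditions, enhancement factor ≈ 2), not flow fields.

**Problem sizes.** Production-style runs use a 1 mm grid; the packaged
studies and tests use 2 mm (≈ 2 400 solid voxels for the full phantom),
where the peak volume-average temperature agrees with the 1 mm result to
within ~3%. The voxelized scaffold volume is within 5% of the analytic
cylinder volume at 1 mm.

## Thermometry and estimators

Virtual probes: C at the scaffold centre, L/R at ±7 mm on x, T at +9 mm
on z, O at +20 mm on z — O sits on the phantom's top face because the
protocol's "about 1 cm outside the sample volume" cannot be placed
radially through a 2.5 mm annular gel gap. Probe coordinates are not
dimensioned by the bench description; these defaults are symmetric
choices within the drilled-hole layout and are configurable. Sampling is
trilinear in space (coordinates clamped to the voxel-centre grid, so a
face probe reads the outer voxel layer), linear in time, 1 Hz, with
Gaussian sensor noise of SD 0.1 °C — typical fibre-optic thermometry.

The initial-slope window is not standardized; the default is 30 s from
field-on, and every SAR result also reports the 10/30/60 s window
sensitivity, because on a saturating curve the OLS slope falls with
window length (0.96 → 0.89 → 0.82 W/g on the reference run). The
multi-probe SAR is the arithmetic mean of per-probe SARs with the sample
(n−1) SD quoted as the spread. The corrected-slope estimator fits
T₀ + ΔT_max(1 − e^{−t/τ}) to the heating branch, shares τ with the
cooling branch when ≥30 s of post-switch-off data exist (which measurably
tightens the standard error), and returns ΔT_max/τ. Background
subtraction resamples a non-magnetic control onto the record's time base
and subtracts its excursion from its field-on value, restoring the
record's baseline.

## Placement studies

"Relative SAR variation" is defined everywhere as
(SAR(offset) − SAR(0)) / SAR(0) × 100 %, signed, positive =
overestimation; the report header restates this (some presentations of
the same quantity use the inverse ratio, which flips the sign). Axial
sweeps default to offsets {0, 1, 2} cm; radial sweeps to the 7×7 grid
over ±3 mm. Because the coil is axisymmetric and the pair shifts rigidly,
every radial metric depends on the offset magnitude only; the sweep
therefore runs once per unique radius (10 runs for the 7×7 grid) and
mirrors the table, flagged as symmetry-reduced. Sweeps use the 2 mm grid
and a heating-only (600 s) transient, since the peak occurs at switch-off.

On the default calibrated scene the studies give: ξ falling monotonically
(62 → 16 → 7) and an 11.2 °C peak-temperature drop for the 2 cm axial
shift; a maximum radial SAR overestimation of +0.4 % and a radial
peak-temperature spread of 0.40 °C; a 3.7 °C surface-vs-volume peak gap
in air; and a 5.1 °C convective flattening in water. These numbers are
recomputed, not stored, by `scripts/acceptance.py` and the test suite.

## Known limitations

- **Loss-amplitude exponent.** The truncation rule caps the sensitivity
  of deposited power to field amplitude at exponent 1. Benches whose
  composites operate in a steeper (Rayleigh-like, ∝H³) minor-loop regime
  will show *larger* radial misplacement effects than this model: with
  the default coil the ±3 mm field variation is only ~0.5 %, so the
  simulated radial SAR error (+0.4 %) and peak-temperature spread
  (0.40 °C) sit well below the ~8 % / ~1 °C scale reported for a real
  bench of this type. The axial effect (driven by a ~25 % field drop) is
  insensitive to the exponent and is reproduced.
- **In-air gap is power-limited.** The surface-vs-volume peak gap in air
  scales directly with the deposited power density; at the 1 W/g
  calibration and 600 s it is 3.7 °C, versus ~10 °C reported for a
  hotter bench case. The *direction* and mechanism (IR thermometry
  reads the cooler surface) are reproduced; the magnitude tracks the
  calibration.
- Free-space field: no scaffold-induced distortion, no coil skin or
  proximity effects, no supply modelling.
- No dynamic hysteresis (Jiles–Atherton/Preisach), no temperature
  dependence of material or magnetic properties, no perfusion term.
- The water surrogate is a correlation, not CFD; porous/architected
  scaffold geometries are out of scope (the scaffold is homogeneous).
- Synthetic temperature logs are single-exponential per probe; passing
  estimator-recovery tests on them demonstrates estimator correctness,
  not robustness to the multi-time-constant shape of real records.
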