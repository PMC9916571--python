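# Methods

## Scope and reduction

mdtsim replaces a 3D finite-volume CFD solve with a prescribed analytic
flow: every vessel is a straight rigid cylinder carrying a quasi-steady,
fully developed parabolic profile modulated by a piecewise-polynomial
cardiac waveform. This keeps every quantity the particle physics needs —
sampled velocity, shear rate, viscosity — exact and cheap, at the cost of
all secondary-flow features (skewed profiles, separation, vortices at
bifurcations, true Womersley unsteadiness). Consequences for interpreting
results are listed under Limitations.

## Hemodynamics

- **Rheology.** Carreau model with µ0 = 0.056, µ∞ = 0.0035 kg/(m·s),
  λ = 3.313 s, n = 0.3568 (whole-blood fit). Blood density defaults to
  1060 kg/m³ (standard literature value; not part of the published
  parameter set). Viscosity is evaluated at the local profile shear rate
  γ̇ = 4ū|y|/R².
- **Waveform.** Five polynomial branches over a 0.8 s period, selected on
  half-open intervals, with per-inlet scaling constants 1 / 1.4 / 1.5
  (basilar, left ICA, right ICA). The published coefficients of branches 2
  and 4 are discontinuous with their neighbours by orders of magnitude
  (interior values −25 and −1000 m/s; apparent decimal loss in
  typesetting). The package stores the published coefficients verbatim as
  the default `PiecewiseWaveform`; a **repaired** branch set
  (`repaired=True`) replaces those two branches with cubic Hermite
  interpolants matching the neighbouring branches' values and slopes,
  giving C¹ joins, a 0.36 m/s systolic peak and a dicrotic notch. Any
  simulation driven by the waveform should use the repaired set (the
  `SimulationConfig` default); the printed set exists for audit. The
  waveform is only near-periodic as printed (0.1307 at t→0.8 s vs 0.1375
  at t = 0, a ~5% seam); time is reduced modulo the period, so the seam
  appears as a small jump once per cycle.
- **Junctions.** Flow-split fractions are configuration inputs (the source
  model determines splits implicitly through its 3D solve). Each segment's
  volumetric flow is a precomputed linear combination of the inlet
  waveforms (topological propagation; cycles are rejected, so communicating
  arteries carry a prescribed flow direction), making junction mass balance
  exact by construction.
- **Windkessel.** The outlet ODE is implemented with its published
  coefficient C·R_d on the di/dt term (the conventional three-element form
  uses C·R_p; the steady state p = i(R_p+R_d) is identical either way).
  The one-step update is the exponential (integrating-factor) solution with
  inputs frozen at the step midpoint: exact for constant inflow,
  unconditionally stable, first/second-order for varying inflow. Default
  R_p = 9e8, R_d = 6.8e9 Pa·s/m³, C = 2.5e−10 m³/Pa are repo-chosen values
  giving a physiological pressure envelope for the fixture's ~1–2 ml/s
  outlet flows; the upstream source for such values is cited but not
  reproduced in the paper trail, so they carry no published authority.
- **Diagnostics.** WSS τ_w = µ(γ̇_w)γ̇_w with γ̇_w = 4ū/R; vorticity of the
  parabolic profile |∇×u| = 4ū|y|/R² (azimuthal). Both follow analytically
  from the prescribed profile rather than from a stress tensor on a mesh.

## Magnetics

The 2D line-dipole field of the cylindrical electromagnet is evaluated with
analytic components and analytic Jacobian; the dipole force uses
F = (4/3)πR_mp³ µ0 (3χ/(χ+3)) (H·∇)H. For this curl- and divergence-free
field (H·∇)H = ∇(|H|²/2) with |H| = M_s R²/2/((x+d)²+y²), so the on-axis
force decays as (x+d)⁻⁵; the central-difference oracle
(`magnetic_force_numeric_oracle`) confirms the analytic components to
better than 1e−6 relative and is the arbiter for the published simplified
force expressions, whose printed forms are internally inconsistent.

- χ (particle susceptibility) is not published; default 1000, saturating
  3χ/(χ+3) ≈ 3, consistent with magnetite cluster treatments. Configurable.
- µ_r of blood defaults to 1 (non-magnetic medium).
- The published geometry pairs "magnet surface 7.8 cm from the network
  centroid" with "ROI-average flux density 0.545 T at 2 T remanence".
  On-axis, 7.8 cm gives 0.148 T, so the targeted artery must sit much
  nearer the magnet than the centroid. `MagnetModel` defaults to the
  printed 7.8 cm; the trend scenario derives its standoff by inverting the
  on-axis field law at 0.545 T (→ 4.06 cm), via
  `magnetics.standoff_for_field`.
- The 2D plane is embedded in 3D by `MagnetFrame` (plane spanned by the
  magnet axis and the ROI segment axis); the out-of-plane force component
  is zero.

## Particle dynamics

- **Regimes.** d_p ≤ 200 nm (configurable): Stokes drag with Cunningham
  slip correction and Brownian forcing. Above: Morsi–Alexander banded
  spherical drag (coefficients embedded from the original correlation), or
  Haider–Levenspiel when the shape factor φ < 1; no Brownian forcing.
  The molecular mean free path in blood is not published; default 1 nm
  (C_e ≈ 1.25 at 10 nm, ≈ 1.0006 at 4 µm), configurable, and set to 0
  (continuum) where an oracle requires exact Stokes–Einstein behaviour.
- **Brownian spectral density.** The published expression carries
  (ρ_p/ρ) to the first power; the standard white-noise density it derives
  from squares the ratio, and only the squared form is consistent with the
  Stokes–Einstein diffusion coefficient used by the β_m diagnostics. The
  default is the squared form (`density_ratio_exponent = 2`); the printed
  form is available as exponent 1 and yields an effective diffusivity
  exactly ρ_p/ρ ≈ 4.93× larger (asserted by a unit test).
- **Integration.** The drag relaxation time τ = ρ_p d_p²C_e/(18µ) is
  ≤ 1.3 µs for every class of interest, far below any affordable transport
  timestep, so the "explicit Euler" branch of the source scheme is
  implemented as an integrating-factor (exponential) Euler: the linear
  force balance is solved exactly for coefficients frozen over the step,
  which is unconditionally stable, reduces to explicit Euler as Δt → 0 and
  reproduces terminal-velocity relaxation to machine precision. In the
  overdamped limit the per-step Brownian kick reproduces per-axis
  MSD = 2Dt exactly in expectation. Classic Euler and adaptive RK45
  (scipy, for hypothetical inertial parcels with τ ≳ Δt, standing in for
  the source's high-order Runge–Kutta branch) are selectable.
- **Coupling.** One-way only: parcels never alter the prescribed flow.
  (The source framework advertises two-way coupling inside its CFD solver;
  with a prescribed analytic flow there is no continuum to update.)
- **Gravity** defaults off (the model's orientation w.r.t. gravity is
  never fixed); direction and magnitude configurable. With ρ_p = ρ the
  buoyancy term vanishes identically.

## Injection, boundaries and capture

Releases of `parcels_per_release` parcels occur every 0.008 s (one
hundredth of the cardiac period) from 0.8 s to 1.6 s by default, uniformly
random over the inlet disc; the magnet switches on at 0.8 s. Fates:
outlet plane → escaped; wall contact → specular reflection (tangential
velocity preserved); inside the ROI, capture is tested before reflection —
a parcel closer to the wall than the threshold while the magnetic force
points wall-ward is captured. Thresholds: parcel radius (published rule)
or the 50 µm capture distance d_c (relaxed rule, used by the trend
scenario); a `trap` wall rule (capture on any ROI wall contact) is also
available. Efficiency is η_c = (N_in − N_out)/N_in × 100 — the published
formula reads N_in/N_out × 100, which exceeds 100% whenever anything is
captured; the surrounding text and all reported values imply the captured
fraction, and the literal form is retained behind a flag for audit.
Parcels still in flow at the end time (mostly no-slip wall-creepers near
the inlet) are excluded from both numerator and denominator and reported
separately.

Parcel conservation (injected = escaped + captured + in-flow) holds exactly
at every census step by construction and is asserted in the tests.

## Randomness

All draws flow from `SeedSequence([seed, parcel_uid])` Philox substreams:
placement first, then per-step Brownian normals in chunks. Parcel noise is
therefore independent of how many other parcels exist and of the particle
class — sweep cells over diameter and field strength are driven by common
random numbers, the standard variance-reduction device that makes
monotone-trend comparisons paired rather than independent.

## Trend scenario (what the shipped sweep emulates)

A 30 mm tube of radius 1.5 mm (middle-cerebral-artery scale) stands in for
the targeted artery; the magnetized section spans the central 80% of the
tube (the field is nearly uniform over 3 cm at 4 cm standoff, so the whole
short tube is effectively "the magnetized section"), with the relaxed
d_c = 50 µm capture rule and the left-ICA waveform scale 1.4. 100 releases
× 20 parcels give 2000 parcels per cell; end time 2.4 s clears all but the
wall-creeping stragglers. With these conditions the diameter sweep at 8 T
is strictly monotone (≈3.9% → 4.9% → 42% → 100%); at 2 T the 10 nm and
100 nm cells tie within Monte-Carlo error because Brownian-assisted
capture of the smallest class offsets the negligible 2 T drift at 100 nm —
a real desk-scale effect of a straight tube, not present in the full 3D
geometry's reported range. The field sweep at 10 nm changes η_c by at most
a few parcels (drift at these sizes is nanometres per transit); the field
dependence is carried robustly by β_m (increasing) and Pe_m (decreasing).

What passing these trends does **not** show: absolute capture-efficiency
percentages of the 3D patient-derived geometry (99/95/48/33% in the source
study depend on an unpublished mesh and solver and are out of scope here),
near-wall hydrodynamic lift/lubrication, particle–particle interactions,
or wall adhesion biology.

## Fixtures

The idealized Circle-of-Willis network (16 segments, 3 inlets, 6 outlets,
posterior/anterior communicating segments closing the ring with prescribed
flow directions) uses anatomical-literature radii — basilar 1.6 mm, ICA
2.0 mm, MCA 1.4 mm, ACA/PCA 1.2 mm, communicating 0.7 mm — and equal or
conventional split fractions (ICA: 50% MCA / 30% ACA / 20% PCoA). None of
these dimensions are published model values. The straight-tube fixture is
the oracle geometry for kinematics, capture and trend tests.

## Numerical choices and degenerate inputs

- Default transport timestep 2e−4 s (≲ 60 µm axial travel per step at peak
  flow; capture shell 50 µm is tested every step against the radial gap,
  which moves orders of magnitude slower).
- Branch selection and ROI intervals use half-open/closed comparisons with
  1e−12 guards; positions exactly on the wall reflect to the interior.
- Zero strain rate, zero inflow, zero remanence, λ_mfp = 0 and φ = 1 are
  all exact special cases with closed-form behaviour asserted in tests.
- Zero-diameter particles, negative strain rates, non-positive timesteps,
  unknown configuration keys and cyclic networks are rejected with errors
  naming the offence.

## Known limitations

- No Navier–Stokes solve, secondary flow, or fluid–structure interaction;
  the parabolic profile underestimates near-wall shear skewness at bends.
- The 2D magnet model ignores out-of-plane field decay; forces are exact
  only in the symmetry plane.
- Capture treats the wall as perfectly absorbing under the rule's
  conditions — no adhesion kinetics, detachment, or saturation of the wall.
- Micron-parcel drag uses the relative-Reynolds correlations with the
  local Carreau viscosity; particles smaller than blood cells physically
  see plasma viscosity, so superparamagnetic capture here is, as in the
  source analysis, likely an underestimate.
- Trajectory export is CSV only (no VTK writer in the dependency set).
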