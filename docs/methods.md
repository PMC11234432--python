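# Methods

This note records the models, parameter choices, numerical decisions and
limitations behind `pvtarget`. Everything quantitative here is computed by
the test suite or the `analysis/` drivers; nothing is asserted that the
code does not reproduce.

## Magnetostatics

The targeting magnet is an axially magnetized N40 neodymium disc:
remanence `Br = 1.3 T`, radius `R = 2.0 mm`, thickness `D = 2.4 mm`,
held with a 0.4 mm gap between its near face and the top lumen surface of
the printed channel. On the axis the field has the standard closed form
(see README); at the working gap it evaluates to 0.4015 T, and across the
2 mm lumen it falls to 0.1007 T — a 75% drop, so "uniform across the
lumen" holds only as an order-of-magnitude statement.

Off the axis, a uniformly magnetized cylinder is equivalent to an
azimuthal surface-current sheet. We superpose circular current loops at
64 Gauss–Legendre nodes over the thickness (Biot–Savart via complete
elliptic integrals `K`, `E`). Gauss–Legendre rather than equally spaced
loops matters: it reproduces the closed form on the axis to better than
1e-6 relative with 64 nodes, where a midpoint stack would need several
hundred. Gradients are taken by central differences (step `R/100`, or a
tenth of the grid spacing when sampling on a mask); the on-axis component
is cross-checked against the analytic derivative.

The magnetophoretic force is `F = V · M(B) · (B̂·∇)B` with
`M = min(χ|B|/μ0, Msat)`. Defaults `χ = 20` (effective, demagnetization-
corrected) and `Msat = 480 kA/m` (magnetite) are literature-typical
placeholders — the study's particles were never magnetically
characterized — and are exposed in the config. At the working field
(≈0.1–0.4 T in the lumen) the magnetization is saturated, so the force
scales linearly with remanence through `∇B`.

**Magnetic load per particle.** The DLS sizes are hydrodynamic; the
magnetic content is configured as `cores_per_particle` 10 nm
magnetite-equivalent spheres. The single-core force across millimetre
gaps moves an 80 nm particle by micrometres per minute — utterly
invisible in minutes of simulated time, consistent with the experiments
needing days of recirculation plus field-induced aggregation to build up
deposits. The capture and dish scenarios therefore default to an
aggregate load of 1500 cores (≈115 nm solid-magnetite equivalent,
representing field-induced chains/clusters), and the package makes
ordering claims only — capture monotone in remanence, anti-monotone in
gap — never quantitative capture efficiencies.

## Indentation

The chain implements linear contact mechanics for a spherical tip:
stiffness from an ordinary-least-squares line over the **initial 5–20% of
the unloading segment by sample index** (the fraction's basis is not
uniquely defined in common usage; index fraction is reproducible),
`ε = 0.75`, `β = 1`, tip modulus 2 GPa, both Poisson ratios 0.5. The
"500 µm spherical tip" is read as a tip *diameter*, so `R = 250 µm`
(configurable) — indentation tips are conventionally named by diameter
and the area function needs the radius.

On noise-free synthetic Hertz curves at the study's three surface modulus
levels (56.4, 72.2, 87.6 kPa) the chain recovers the truth with a +1.8%
bias: the OLS secant under-reads the tangent stiffness by ~6.5% at this
window, which propagates through `h_c` and `A` into a small net
overestimate at `h_max/R = 0.4`. With 2% multiplicative force noise the
median recovery error over 20 seeds stays below 1%. `h_c > R` is an
error, not a clamp — the spherical-cap area formula is meaningless past
the hemisphere. Using ν = 0.5 in a linear-elastic inversion is the
incompressible limit and is applied verbatim; no poroelastic or adhesive
corrections are attempted.

## Geometry

The Y-channel is parametric: 2 mm lumen, 4 mm outer wall, trunk 10 mm,
branches 8 mm at ±30° — the branch angle and segment lengths are not
dictated by the source geometry (only the footprint and diameters are),
so they are documented defaults chosen to fit the 14 × 25 mm printed
footprint. Rasterization is cell-centered on the planform; the branches
are extended by `r·tanθ` past the outlet plane and the domain cropped
there, so each outlet is a clean full-lumen cut of the grid boundary.
Fidelity ratios are plain measured/CAD quotients with a ±10% flag band;
circularity is the isoperimetric quotient `4πA/P²` (the index is named
but not defined in the source protocol).

STL export voxelizes the footprint, extrudes it through the lumen
diameter and surfaces it with marching cubes — a watertight triangulated
solid whose bounding box matches the footprint within one voxel.

## The 2D planform and the two magnet reductions

The solver works in the single 2D plane that contains the Y geometry
(x along the trunk, y transverse). The physical magnet sits *above* this
plane over the apex. That forces a choice, because no single in-plane
placement is faithful:

- an **in-plane magnet** raised clear of the upper branch puts the
  strongest pull at the branch shoulder nearest its face — the right
  *mechanism* for particle capture (particles get pinned against the wall
  nearest the magnet, the planar analog of pinning against the top lumen
  surface), and the capture scenarios use it (with the target ROI radius
  at 3 mm so the ROI covers the walls under the magnet footprint);
- the **overhead projection** — the radial in-plane component of the
  overhead magnet's force evaluated at the mid-plane height — decays with
  distance from the apex and is the faithful reduction for the *fluid*
  body force; the solver uses it.

A subtlety governs the body force: with a spatially uniform particle
concentration, any magnetophoretic force with `M ∥ B` in a current-free
field is the gradient of a potential, and an incompressible flow absorbs
it entirely into pressure — velocity and WSS do not change at all. What
actually perturbs the flow is the *non-uniformity* of the particle phase:
the drag reaction `f(x) = n(x)·F(x)` with the suspended-particle
concentration `n(x)` enriched near the apex. The package estimates `n(x)`
from a seeded tracer run (time-averaged occupancy, normalized to a
configurable bulk concentration, default 1e15 m⁻³) and feeds `n·F` to the
solver. The resulting ΔWSS concentrates in the apex ROI (mean |ΔWSS|
about an order of magnitude above the far field) and scales linearly with
force amplitude, which is what the perturbation analysis asserts. The 3D
reference solver's printed perturbation ranges arise from an unstated
force implementation and are treated as order-of-magnitude context only.

## Flow solver

Explicit Chorin projection on a masked MAC (staggered) grid: first-order
upwind advection, central viscous terms with reflected no-slip ghosts,
and a direct (pre-factorized sparse LU) pressure solve with Neumann
walls/inlet and zero-Dirichlet outlet faces. That construction enforces
cell-wise incompressibility, so inflow/outflow balance holds to solver
precision at every step. The inlet carries a developed parabolic profile
at the prescribed rate; the 3D volumetric rate (2 mL/min) maps to a
per-depth rate using the lumen diameter as the out-of-plane depth, giving
Re ≈ 17 — laminar, and the solver rejects configurations beyond Re 500.
Time steps sit at 0.4× the diffusive/advective stability limit; steady
convergence is declared when the velocity change per viscous cell time
falls below 1e-6 relative.

The perfusion waveform is a mean plus two Fourier harmonics solved so the
forward peak (6.5 mL/min at t = 0.07 s) and the reverse peak (−2 mL/min at
t = 0.24 s) are stationary points and the average is exactly 2 mL/min;
the published waveform is a plot without printed samples, so the peak
values are parametric stand-ins with the correct period, mean and peak
timing. Validation: mid-channel profiles match plane Poiseuille within
5% at 64 cells across (WSS likewise, via a two-point one-sided quadratic
fit that is exact for parabolic profiles), and the oscillatory centerline
response matches the plane-channel Womersley closed form (α ≈ 3.6) within
0.3% in amplitude at 32 cells across. During flow reversal the junction
carries counter-flowing regions; at the maximum-negative-flow phase the
whole junction runs backward.

Pulsatile runs use 2–4 cycles; cycle-to-cycle periodicity is monitored
(≲1e-2 relative on the bifurcation at three cycles, ≲1e-5 on straight
channels). Grid sizes (≈0.1–0.03 mm spacing) and cycle counts were chosen
to make the whole validation battery run in minutes on one core.

## Particle transport

Overdamped Langevin dynamics (particle Stokes number ≪ 1 at these scales;
inertia, gravity and particle–particle interactions neglected): per step,
drift = interpolated fluid velocity + `F/(3πμd)`, plus an isotropic
Brownian kick `√(2D dt)` per axis with Stokes–Einstein `D`. Deposition is
irreversible absorption on first wall contact (optional sticking
probability); particles leaving through open ends are "escaped", and
deposited + escaped + suspended = n always. Force lookups use
precomputed interpolation tables (per-scenario), not per-step field
evaluations.

The zero-field null (target/off-target ratio = 1) is checked in a
geometrically symmetric configuration — a straight channel with mirrored
top/bottom ROIs — because the bifurcation's apex and outlet ROIs are not
deposition-symmetric even without a field, so symmetry licenses the null
only there. The capture scenario perfuses the bifurcation at a slow
0.02 mL/min rate (a settling/low-flow phase; at the full 2 mL/min the
transit time is far too short for any mm-scale lateral drift, so ordering
would be measured mostly on noise) with 1500–2000 particles over 90–120 s.

The dish ("well") mode is fully 3D: a 11 mm-radius well filled 2 mm deep,
the magnet 1 mm under the bottom (plate bottom plus tape), deposition on
bottom contact, reflecting side wall and free surface. With the field on,
deposition is strongly enhanced over and just beyond the magnet footprint
and decays with radius (accumulation radius ≈5 mm at the aggregate
default, where the deposit density falls below 5% of the central value);
with the field off it is sparse and statistically uniform.

## Quantification

Segmentation is global threshold (Otsu default) → connected components →
area filter (min 5 px), with optional distance-transform watershed for
touching objects — the reference workflow was interactive ImageJ without
stated parameters, so the defaults here are explicit and deterministic.
Viability is `100·live/(live+dead)` on the two channel counts. AlamarBlue
reduction uses the two-wavelength molar-extinction formula with a small
editable coefficient table (540/570/600/630 nm, standard resazurin/
resorufin values); a 550/600 nm reader pair maps to the nearest tabulated
wavelengths (540/600). Pore equivalent diameter is `2√(A/π)` — the true
circular-equivalent diameter; note that converting the study's 124.9 µm²
mean pore area this way gives 12.61 µm, twice the ≈6.3 µm quoted alongside
it (that figure equals the radius). The package reports the standard
diameter and documents the discrepancy rather than replicating it.

## Cell cycle

The Dean–Jett–Fox model: Gaussian G0/G1 at `μ`, Gaussian G2/M at `ρμ`
with `ρ` fitted in [1.8, 2.1] (cytometer linearity drift), and an S-phase
continuum of quadratically weighted mean positions on `(μ, ρμ)`, each
broadened by a CV interpolated between the two peak CVs, discretized at
60 nodes. Fitting is Poisson-weighted nonlinear least squares;
initialization takes `μ` from the dominant low-intensity peak and
fractions from naive gating windows. The S-shape coefficients carry a
mild ridge toward a flat weight (weight 25 on the normalized
coefficients): the deconvolution is ill-posed near the peaks — a tilted S
weight can trade area with the Gaussian tails almost silently — and the
ridge stabilizes recovery to ≤2 points without preventing genuinely
tilted S phases when the data demand them. Fractions are component areas
and sum to 100 exactly. Recovery on synthetic truths: ≤3 points at
n = 10⁴ events and CV 5% across a 3×3 fraction grid, with median error
well under 1 point. When the true G2/M fraction is ~0 the G2 component is
unidentifiable (the ratio slides into the S edge) and errors grow to
~4 points; the boundary case the model does handle cleanly is S = 0.
Debris and doublet terms are omitted — synthetic histograms contain
neither — so real cytometry exports would need those terms added.

## Synthetic data: what it does and does not emulate

Generators are seeded, record their ground truth, and regenerate
byte-identically from their records. They emulate: Hertzian elastic
indentation (no viscoelasticity, adhesion or drift), disk-rendered
non-overlapping cells in two clean channels (no bleed-through, focus
blur or clumping), non-overlapping lognormal-area circular pores (no
irregular or connected porosity), Gaussian-spread DNA histograms without
debris or doublets, and a two-harmonic pump waveform. Passing the
recovery tests therefore shows the *estimators are correct on their own
forward models* — it does not certify performance on real images,
cytometry or indentation data with artifacts the generators omit.

## Problem sizes

Default test/driver sizes — grids of 32–64 cells across the lumen,
1.5–10 k particles, 90–180 s of simulated transport, 10⁴ cytometry
events — were chosen so the full suite and the analysis battery complete
in a few minutes on one core while keeping every validated tolerance
comfortably met; all are configuration parameters, and scaling them up
tightens nothing qualitative.
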