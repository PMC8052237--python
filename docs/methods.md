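# Methods

This note records the models, numerical choices and limitations behind
`rhinoflow`, in the order the pipeline runs.

## Air-space segmentation

A voxel is air iff its value is ≤ −460 HU; the boundary value counts as air
so the rule is deterministic. Tip detection scans anterior → posterior and
returns the first tissue voxel whose *anterior* neighbour belongs to the
exterior air (air 26-connected to the anterior volume face), restricted to
a central band of the left–right axis (half-width 25 % of the axis,
configurable). The anterior-adjacency condition makes the rule robust to
air cavities whose side walls would otherwise masquerade as "tissue next to
exterior air". Published descriptions of automated tip detection are
scarce, so this definition is this package's own and is exposed as a
configurable step.

Probe regions: the ambient sphere (default 70 mm diameter at patient
scale) is centred on the tip and may be clipped by the volume boundary, as
happens with field-of-view-limited scans; it is an error only if the
sphere cannot fit the grid at all. The outlet cuboid (default
60 × 40 × 30 mm³, stored AP × SI × LR as 30/60/40) is placed on the most
inferior connected air slab posterior to the channel junction (posterior
55 % of the AP axis), centred on the slab centroid with its floor at the
lowest air voxel — an operational stand-in for "positioned onto the
oropharynx". Region growing keeps the 26-connected component seeded in the
cuboid; 26-connectivity is deliberate, as weaker connectivity tends to
sever thin nasal passages on coarse grids.

Nostril blocking is algorithmic: the aperture is the first anterior slice
in which one side's air cross-section is fully enclosed by tissue; a plug
of 3 slices (configurable) becomes wall, and connectivity between the
ambient surface and the cuboid is re-checked. A user-supplied plug mask can
replace this rule by editing the mask directly.

The ambient-pressure boundary is the one-voxel sphere shell *intersected
with exterior air*. The raw geometric shell clips the channel mouths just
behind the nostrils; venting those interior voxels to ambient would
partially defeat a nostril plug, so the boundary is restricted to air
connected to the anterior face.

## Lattice-Boltzmann solver

D3Q19 stencil over an indexed fluid-voxel list. Collision is
two-relaxation-time (TRT) with magic parameter Λ = 3/16, which pins the
half-way bounce-back wall position independently of viscosity; plain BGK is
selectable (`trt_magic <= 0`). The optional Smagorinsky closure
(`c_s = 0.14`) computes the eddy relaxation from the non-equilibrium
momentum flux, `τ_eff = (τ₀ + √(τ₀² + 18 c_s² |Π|/ρ))/2`. Walls are
half-way bounce-back; where a signed distance to an analytic surface is
available (phantoms, benchmark ducts) the wall links switch to Bouzidi
linear interpolation, which removes the stair-casing bias of voxelized
circles. CT masks have no analytic surface and run voxel-native, exactly as
the clinical workflow does.

The flow-rate boundary is a momentum-corrected (moving-wall) bounce-back on
the solid layer beneath the cuboid's inferior air: a wall moving with a
normal velocity injects mass at exactly ρ·u_n per unit face area, and the
wall speed is scaled so the net lattice mass flux equals the prescribed
flow rate to machine precision. A naive equilibrium velocity boundary was
rejected because it admits a spurious stagnant fixed point (a density
depression balancing the injected momentum) and does not enforce the flow
rate. Ambient nodes impose the equilibrium at ρ = 1 with the local
velocity.

Unit conversions follow `u_lat = u·dt/dx`, `ν_lat = ν·dt/dx²`,
`p = c_s²(ρ−1)·ρ_phys·(dx/dt)²` with `c_s² = 1/3`. Without the LES closure
the solver refuses to run at `τ ≤ 0.505`; the patient-scale resolution
(0.234 mm, 1.8 µs, air at 20 °C → τ ≈ 0.5015) therefore requires LES, which
is also the physically indicated regime there (nasal flow turns turbulent
above ≈ 290 ml/s). Air properties are fixed at 20 °C; the inspiratory
warming of air is deliberately not modelled.

Stationarity: the sphere–cuboid pressure drop is sampled every 25 steps;
the run stops when its peak-to-peak fluctuation over a 500-step window
falls below ±3 % of the running mean, with an absolute floor of 0.25 Pa so
zero-flow runs terminate. Non-converged runs are flagged and excluded
downstream, never imputed. Sweeps ramp the flow upward within each phase
and warm-start each run from the previous state, which cuts the transient
cost of a 25-condition sweep by roughly an order of magnitude.

### Desk-scale dynamic scaling

Phantom studies must cover the clinical pressure range (tens to hundreds of
Pa over 0…600 ml/s) on grids that run in seconds per condition on one CPU.
Air at true scale cannot do this — it puts τ at the stability limit and the
flow in the transitional regime. Instead `desk_scale_config` synthesises a
*scaled working fluid*: the kinematic viscosity is chosen so the
unconstricted channel's Hagen–Poiseuille resistance along the
nostril-to-cavity arc equals 0.55 Pa/(ml/s), anchoring the 150 Pa working
point near 270 ml/s, inside the sweep; τ = 0.6 and the implied time step
keep lattice velocities ≈ 0.02 and density deviations ≈ 1.5 % at 150 Pa.
The Reynolds number is then O(5), laminar, and the LES stays off. This is a
dynamic-similarity device: pressure–flow topology, binning, exclusion and
resistance extraction all behave as at patient scale, while absolute
Reynolds-number effects (turbulence, inertial losses) are out of reach —
which is why solver fidelity is validated separately on the analytic duct.

### Validation

The circular-duct benchmark imposes the piston flow boundary at one end and
ambient pressure at the other and measures Δp between two interior planes
in the developed region. With Bouzidi walls and a lattice velocity of 0.01
the result is within ≈ 2–3 % of `8 μ L Q/(π R⁴)` at R = 11 voxels; the
residual error is dominated by compressibility (the duct runs slightly
above ambient density and the LB dynamic viscosity scales with ρ). Halving
dx (same physical duct, acoustic scaling) moves Δp by ≈ 3 %, the package's
mesh-convergence check. Problem sizes (R = 11, length 80; refinement pair
R = 5.5/11) were chosen so the full validation completes in well under a
minute while keeping the staircase and compressibility errors within the
5 % target.

## Synthetic phantoms

One signed distance field defines the phantom: an anterior exterior-air
pocket with a protruding tip cone, two swept-circle channels following
quadratic Bézier arcs (anterior–superior–posterior, per-subject seeded
jitter of the control points), and a posterior cavity sized to admit the
outlet cuboid. The same field provides the HU volume (air/tissue two-level,
−1000/+40 HU), the exact lumen oracle for segmentation tests, and the
sub-voxel wall distances for the solver. A unilateral constriction
multiplies the channel radius by `constriction_factor` under a Gaussian
profile centred at mid-arc (width 0.15 of the arc), emulating a septal
deviation. Defaults: 64³ voxels at 2 mm spacing, nostril radius 9 mm,
constriction factor 0.85; the five-subject study uses 48³ at 2.667 mm
(12 mm nostrils — same voxel geometry) so that the 250-run sweep finishes
in about four minutes on one CPU. Probe proportions mirror patient scale:
sphere diameter 2.3 × nostril diameter; cuboid edges (3, 6, 4)/7 of the
sphere diameter.

What the phantom does *not* emulate: turbinate anatomy, CT noise and
beam-hardening, paranasal sinuses, mucosal surface texture. Passing tests
therefore demonstrate the pipeline's correctness on clean two-phase
geometry, not segmentation robustness on clinical scans.

## Synthetic rhinomanometry

Clinical curves follow the Rohrer law `Δp = k₁Q + k₂Q|Q|` with additive
Gaussian pressure noise (flow is the controlled variable). The real study
population's curve shapes are not published in closed form; the Rohrer
model is the standard quadratic-dominated description of airway
pressure–flow loops and is this package's modelling choice. Per subject,
decongested coefficients sit near the phantom's anatomical resistance
(k₁ ≈ 0.55 on the open side, ≈ 0.72 on the constricted side, ±7 %;
k₂ ≈ 2·10⁻⁴), and congestion scales both up by a factor 1.4–1.9, so
congested ≥ decongested holds per side. Pressure noise defaults to 5 Pa.

`breathing_trace` emulates what a rhinomanometer draws: three sine breaths
sampled densely (6000 samples/cycle), per-half-cycle depth variability
(±15 %, clamped to a realistic effort range), a ±30 Pa inertive hysteresis
loop, and two-channel sensor noise in which the flow error wanders slowly
(band-limited) so each breath traces a distinct path. These values were
chosen so rendered traces reach the pixel density of clinical report pages
(> 1500 digitizer points per curve at 847 × 757 px with a 5 × 5 window) —
that density is itself a property of the emulated data source.

The resistance working point of a noise-free Rohrer curve is
`Q* = (−k₁ + √(k₁² + 4k₂·150))/(2k₂)` (series expansion when the quadratic
term is negligible). Because flows are binned at 50 ml/s, the recovered
`R150 = 150/mean(flow)` is quantized; recovery to within 10 % of `150/Q*`
is achievable when the curve's slope at the working point stays below
≈ 1 Pa/(ml/s) so a single bin dominates the 125–175 Pa band. Steeper
curves can straddle the band between bins — a genuine resolution limit of
the 50 ml/s protocol, not an implementation artefact.

## Rendering and digitization

The renderer draws hard-edged polylines (width 4 px, no anti-aliasing) in
exact per-curve RGB on a white 847 × 757 px page with black axes, and
auto-scales both axes to the data with 5 % headroom, as report pages do.
It refuses colour assignments whose ±tolerance boxes intersect. The
digitizer keeps a pixel iff every channel is within ±10 (inclusive) of the
curve colour, tiles the mask into 5 × 5 cells, emits one kept-pixel
centroid per occupied cell ordered by x, and converts centroids with a
two-point affine calibration per axis (log axes unsupported). Anti-aliased
or overdrawn pixels simply drop out; when several curves share a plot, the
top curve claims overlapping cells, which slightly thins the curves below —
the same artefact a real colour-threshold digitization of a report page
has.

## Curve analysis

Binning assigns a sample to centre `50·floor((Q+25)/50)` — half-open bins,
boundary values go up. Aggregation is the per-bin mean (sd and count
retained); binning conserves the sample count. Bins whose aggregated
*signed* pressure lies in (−25, 25) Pa are excluded before absolute values
are taken: near zero, inspiration cannot be told from expiration. In a
simulated sweep exactly the zero-flow bin dies, leaving 24 of 25 per side
and 240 retained evaluations for five subjects.

`resistance150` titles samples with |Δp| ∈ [125, 175] Pa (inclusive) as
150 Pa, averages their absolute flows, and divides the *labelled* 150 Pa by
that mean flow; dividing the actual mean pressure instead is available via
`numerator="actual"`. Only inspiration-quadrant samples are used. A side
whose curve never reaches the band yields a missing record, not an error.

The clinical mucosal state (congested vs decongested) is chosen per
subject and side as the curve minimising the mean |log10 ratio| to the
simulated curve over their common retained bins (≥ 3 required); ties go to
congested and are logged. The "better matching" criterion is operational
here; the log-ratio metric is this package's construction.

## Agreement statistics

All comparisons run on log10-transformed positive values.
`d = log10(measured) − log10(simulated)` satisfies `10^d` = ratio row-exactly.
Bland–Altman summaries per stratum (side × phase for pressures;
unilateral-inspiration for resistances) report mean(d) and a dispersion
half-width of 1.96 sample sd, both back-transformed to ratio factors. The
1.96-sd half-width is a *limits-of-agreement*-style dispersion: at the
study's sample sizes a standard-error-based confidence interval would be
several times narrower than the spreads such comparisons report, so the sd
multiplier (configurable) is the only reading consistent with that usage.

The factor-adjusted pressure correlation residualises both log columns on
an additive model of subject, side and phase indicators (ordinary least
squares) and takes Pearson's r of the residuals; p uses the t transform
with df = n − rank(design) − 1. With constant factors it reduces to the
plain Pearson correlation of the logs, and it is invariant to rescaling
any one subject's values. Resistance strength categories: r ≥ 0.8 strong,
0.6 ≤ r < 0.8 moderate, else weak (boundaries assigned upward). The paired
t-test reports per-vector mean ± sd; all-zero differences give t = 0,
p = 1, and a constant non-zero difference reports an infinite t with a
warning. p-values are two-sided throughout and no multiple-testing
correction is applied.

## Known limitations

- Desk-scale sweeps are laminar by construction; inertial and turbulent
  pressure losses that dominate real nasal flow at high rates are not
  represented in the synthetic study (solver support for them exists via
  the LES path but is not exercised at desk scale).
- The Bouzidi wall interpolation is mass-conserving only approximately;
  closed-box mass conservation is exact only for half-way bounce-back.
- The digitizer assumes affine axes and hard-edged colours; anti-aliased
  sources lose edge pixels, and overlapping curves lose cells to the curve
  drawn on top.
- The oropharynx-cuboid placement rule assumes the segmented air ends on a
  roughly horizontal floor below the pharynx; exotic scan orientations
  must be brought to canonical (AP, SI, LR) order first.
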