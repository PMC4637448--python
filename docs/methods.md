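# Methods

## Scope and model

`atriadrift` simulates long-lived rotors (spiral/scroll waves) of electrical
excitation in idealised human-atrial geometries, to isolate how gross
anatomical features — wall-thickness gradients, ridges, and pectinate-muscle
(PM) bridges — move an otherwise stationary rotor.  Three deliberate
idealisations define the scope: a remodelled electrophysiology chosen to give
a stable, non-meandering rotor; spatially constant isotropic diffusive
coupling; and no fibre orientation.  Everything the package measures
(drift vectors, dominant frequencies, recurrence maps, breakthrough events)
is conditional on these idealisations.

### Cell model

The membrane kinetics are the Courtemanche–Ramirez–Nattel (CRN) human atrial
myocyte model: 21 state variables (V, 15 gates, 5 concentrations), standard
published constants (`constants.py`).  The control model is regression-tested
against its published quiescent state (V ≈ −81.2 mV, net current ≈ 0) and
1 Hz APD90 (≈ 302 ms; we obtain 297.6 ms).

The AF-remodelled variant scales g_CaL × 0.35 and g_Kr, g_Ks × 9, and adds
an acetylcholine-activated potassium current

    I_KACh = Cm · O_ACh · C_ACh(V) · (V − E_K)              [pA]
    O_ACh  = 10 / (1 + 9.13 / [ACh]^p),      p = 0.477 (configurable)
    C_ACh  = 0.052 + 0.45 / (1 + exp((V + 59.53)/17.18))

with E_K from the Nernst relation (K_o = 5.4 mM, dynamic K_i).  The exponent
p and the C_ACh constants are exposed in `RunConfig` so the formulation is
auditable.

**Study condition.**  The scenario presets and the acceptance pipeline use
the conductance-remodelled model with `[ACh] = 0`
(`scenarios.af_study_params`).  This condition produces the reference
behaviour all drift analyses build on: a stable, monomorphic, non-meandering
rotor on the homogeneous 25 × 25 mm sheet (period ≈ 112 ms, dominant
frequency ≈ 8.8 Hz, core diameter ≈ 7 mm, single-cluster recurrence map).
Raising [ACh] to 0.0035 µmol/L with the I_KACh magnitude above shortens the
single-cell APD90 from ≈ 78 ms to ≈ 52 ms and accelerates the sheet rotor to
≈ 12.5 Hz (period ≈ 80 ms); that condition remains available through
`RemodelParams(ach=...)` but is not what the presets run.

### Tissue model and numerics

Monodomain equation `Cm ∂V/∂t = −I_ion + D ∇²V` with no-flux boundaries;
`D = 0.07 mm²/ms`.  Space is discretised on a Cartesian voxel grid
(`dx = 0.33 mm` production, node-centred); the Laplacian is the 7-point
stencil with no-flux boundaries by the method of weights: a neighbour weight
is 1/dx² iff the neighbour is tissue, the centre weight is minus the sum.
Row sums vanish identically, so total diffusion flux is conserved to machine
precision (tested).

Time stepping: Rush–Larsen exponential updates for all gating variables,
forward Euler for V and concentrations, both advanced in one explicit pass
per step (no operator splitting); `dt = 0.01 ms` (stability bound
dx²/6D ≈ 0.26 ms).  Step-halving changes APD90 by < 1 ms and conduction
velocity by < 2 % (tested).

The compiled kernel (numba) removes all V-dependent transcendentals from the
inner loop via a lookup table over V ∈ [−120, 80] mV at 0.1 mV spacing
(linear interpolation; relative error ~1e−6, far below truncation error):
12 gate steady states, 12 Rush–Larsen factors exp(−dt/τ(V)), and 7 current
coefficients.  Reversal potentials and Na⁺-pump terms are refreshed every
10 substeps (their drivers change on second time scales).  The SR-release
gates u, v depend on the instantaneous release flux and are integrated with
two direct exponentials plus a 2nd-order Taylor Rush–Larsen factor
(dt/τ_v ≤ 0.01, error ~1e−8).  Throughput is ≈ 20 M voxel·steps/s on one
CPU core.

**Lattice conduction velocity.**  With D = 0.07 the solitary-wave CV in a
strand is 0.40 mm/ms at converged resolution (dx = 0.1 mm) — the value the
diffusion coefficient was chosen to produce.  At the production spacing of
0.33 mm the depolarisation upstroke (~1 mm wide) is under-resolved and the
wave propagates ≈ 25 % slower (0.30 mm/ms); CV rises monotonically to the
converged value under refinement (tested).  This lattice slowing is a known
property of explicit finite-difference cardiac solvers at 0.33 mm; all 2D/3D
rotor quantities reported by this package are properties of the production
lattice, which is also where the qualitative drift laws are asserted.

### Geometries (the synthetic data of this package)

All study domains are generated, not measured: a 25 × 25 mm sheet; a 1D
strand; a wedge whose wall tapers linearly from 3 mm to zero (the taper law
is the simplest monotone choice; the slope is configurable); a ridge — a
2 × 2 mm strip running the full width of a 3 mm wall; and three PM-bridge
configurations.  A voxel is tissue iff its centre lies inside the continuous
solid; in-plane extents of L map to round(L/dx)+1 nodes and thicknesses to
round(T/dx) layers (volumes agree with the analytic solids to 5–10 %,
tested, and converge under refinement).  Junction voxels are bridge voxels
6-adjacent to the wall or ridge.

* **PM1** — flat wall, semicircular-arc bridge of arc length 14 mm and
  diameter 2 mm in the plane perpendicular to the wall (the arc geometry is
  the simplest shape consistent with a curved PM standing on a flat wall);
  the junction separation is the semicircle chord 2·14/π ≈ 8.9 mm, i.e.
  the along-wall path is *shorter* than the bridge.
* **PM2** — hemispherical wall (outer Ø 30 mm, thickness 3 mm) with a
  straight 8 mm bridge on the concave side.  A straight 8 mm chord between
  points of the 12 mm-radius endocardial sphere dips only c²/8r ≈ 0.67 mm
  below the surface — less than the 1 mm bridge radius — so a literal chord
  would be embedded in the wall.  The bridge is therefore mounted on two
  2 mm radial posts: the 8 mm free span runs between the post tops with
  ≥ 1 mm clearance from the wall, touching it only at the junction feet.
  The along-wall geodesic between the feet is ≈ 9.9 mm > 8 mm: here the
  bridge *is* the short cut.
* **PM3** — PM2 plus a 2 mm-diameter ridge following the endocardial
  surface between the junctions (clear of the free span everywhere except
  at the feet).

These geometries emulate the anatomical features whose effects the analysis
measures (thickness gradients, sudden thickness steps, bridges with
junctions).  They do **not** emulate realistic atrial anatomy: no fibre
orientation or anisotropy, no spatial electrophysiological heterogeneity, no
trabeculated endocardium, and curvature only in the idealised hemispherical
form.  Passing tests therefore demonstrate the mechanisms in isolation, not
their quantitative magnitude in a real atrium.

### Rotor initiation (phase distribution)

A cell is paced to a steady oscillation (bcl 300 ms default for the
remodelled model); its states pace a 33 mm strand (end stimulation, bcl
200 ms); the full 21-variable cycle is recorded at the strand midpoint every
0.5 ms over one period (cyclic closure < 2 mV, tested) with phase 0 fixed at
the upstroke.  Each voxel of the target geometry receives the library state
at phase

    φ(r, θ) = frac(s·θ/2π + r/λ),    s = ±1 (chirality)

evaluated in the plane tangent to the wall at the prescribed centre and held
constant along the plane normal (transmural extension ⇒ the seeded filament
is transmural).  λ defaults to CV·P of the library (≈ 60 mm); any positive
pitch seeds the same rotor after the transient because only the unit winding
number matters.  The first two rotations after initiation are treated as
transient and discarded from all drift statistics (configurable).

### Filament and tip tracking

The filament is the intersection of the V = −50 mV and o_i = 0.5
isosurfaces.  On every face of every grid cube both fields are bilinear;
eliminating one face coordinate reduces the two iso-line equations to a
quadratic whose in-square roots are the filament's face-piercing points
(exact for (bi)linear fields; the analytic-line oracle recovers a known
intersection line to < dx, tested).  Points sharing a cube are joined into
segments and chained into broken-line polylines — the same family of
consistent-case constructions as Montani-style marching cubes, realised at
the face level.  The *tip* is the polyline endpoint nearest the epicardial
surface (the flat face opposite ridges/bridges; the convex face of the
hemisphere).  On the single-layer sheet the in-plane intersection points are
the tips directly.

Tips (sampled every 10 ms with the snapshots) are averaged over
non-overlapping one-rotation windows (rotation period from a zero-padded
periodogram of tip x(t) with parabolic peak refinement).  Core diameter is
2 × RMS distance of post-transient raw tips from their centroid.

### Drift classification

A rotor is *drifting* when the averaged-trace displacement exceeds 10 mm
over the 40 s reference protocol.  For shorter (desk) windows T the
threshold scales as 10 mm · √(T/40 s), not proportionally: the reference
rotor's residual motion is a bounded, direction-changing slow meander
(≈ 0.3 mm/s on the sheet; ~1 mm displacement over any 4 s window) which
spreads diffusively, while anatomy-induced drift is ballistic (1–6 mm/s,
direction-stable) and crosses the scaled bound within a few rotations.  A
proportional rescaling would misclassify the stationary reference at desk
durations; the √T form separates the regimes at any window length and
reduces exactly to the 10 mm criterion at full scale.  Motion whose path
length exceeds 4× its net displacement is reported *excluded* (not
interpretable as continuous drift).

### Rhythm analysis

Dominant frequency: single-taper periodogram of the mean-removed probe trace
(1 ms sampling), zero-padded to the next power of two, no smoothing; maximum
above 0.5 Hz.  Cycle lengths: successive upward −50 mV crossings with linear
interpolation; the recurrence map is the (CL_n, CL_{n+1}) scatter.  A trace
is *polymorphic* when ≥ 2 mutually non-harmonic peaks carry > 20 % of the
dominant power (thresholds configurable).  Breakthrough detection (focal
epicardial activation): a local minimum of the per-cycle epicardial
activation-time map whose 2 mm ring activates ≥ 2 ms later and which is not
connected, within the cycle's first 10 ms, to a front entering from the map
border; the detector is a defined heuristic making a visual notion testable.

## Desk-scale protocol (problem sizes)

The reference protocol simulates 40 s of activity; the packaged *desk*
presets run the same pipelines at sizes chosen for a single CPU:

| scenario | voxels | duration | dt |
|---|---|---|---|
| sheet2d | 5 929 | 4 s | 0.01 ms |
| wedge | 27 181 | 1.2 s | 0.02 ms |
| ridge (per site) | 56 133 | 0.8–1 s | 0.02 ms |
| pm1 | 54 456 | 1.3 s | 0.02 ms |
| pm2 / pm3 | ~98 000 | 1.5 s | 0.02 ms |

The 3D desk runs use dt = 0.02 ms; step-halving to 0.01 ms changes APD90 by
0.7 ms and CV by < 2 %, so the drift phenomenology is unaffected.  Preset
initiation sites keep the rotor core at least ~8 mm from the lateral no-flux
boundaries wherever a *null* drift result is asserted (homogeneous sheet,
PM1): a core within a few millimetres of a boundary acquires a decaying
boundary-repulsion drift of 1–2 mm/s that has nothing to do with the
anatomical feature under test and would confound short-window
classification.  The sheet
(whose spectral anchors are quantitative) keeps dt = 0.01 ms.  Desk
durations suffice because the anatomy-induced drifts start immediately after
the two-rotation initiation transient at 1–6 mm/s, far above the
classification bound; `scale="full"` reproduces the 40 s / dt 0.01
protocol unchanged.

## Known limitations

* The remodelled electrophysiology is one fixed operating point chosen for
  rotor stationarity; no restitution portraits or alternative remodelling
  sets are explored.
* Cycle length and core diameter inherit the ~25 % lattice CV deficit of
  the 0.33 mm grid; quantities are reproducible on that lattice but shift
  a few per cent under refinement.
* Rotor observables drift slowly (~1 ms cycle-length increase per 4 s)
  because intracellular Na⁺/K⁺ are not re-equilibrated at reentry rates —
  a property of the underlying cell model, shared by any long-running CRN
  simulation.
* The breakthrough detector's border heuristic assumes a map border at the
  array edge (flat walls) or the hemispheric rim; arbitrary masks with
  interior holes may need a user-supplied border.
* No bidomain effects, no mechanical feedback, no stochastic channel noise;
  the entire pipeline is deterministic.
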