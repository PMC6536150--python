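# Methods

## The model

`fibwave` simulates electrical activity in ventricular myocardium with the
monodomain reaction–diffusion equation

    chi * (C_m dV/dt + I_ion(u, V)) = div( sigma grad V ),

with surface-to-volume ratio chi = 1400 cm^-1, membrane capacitance
C_m = 1.0 uF/cm^2 and zero-flux (homogeneous Neumann) boundaries, the
standard choice for an isolated heart. Writing sigma = chi C_m D turns the
conductivity into a diffusivity D (cm^2/ms):

* anisotropic: D = D_T I + (D_L - D_T) f f^T with fiber direction f,
  D_L = 0.001 cm^2/ms and D_T = D_L / 9 (a 3:1 fiber/cross-fiber conduction
  velocity ratio);
* isotropic: sigma = 0.466 mS/cm, the geometric mean chi C_m sqrt(D_L D_T),
  which preserves wavefront area in planes containing the fiber direction.

The membrane model is the parsimonious rabbit ventricular action-potential
model: three state variables (V, m, h) and two currents,

    I_Na = g_Na m^3 h (V - E_Na)                 (upstroke)
    I_K  = g_K (V - V_rest) exp(-beta (V - V_rest)),  V_rest = -83 mV
                                                  (repolarisation)

The I_Na constants are shipped as a versioned JSON fixture
(`fibwave/data/ina_parsimonious_rabbit.json`, provenance recorded inside)
and are never hard-coded. The four named parameterisations vary only the
potassium current: P1 (g_K = 0.5 mS/cm^2, beta = 0.030 /mV), P2 (0.5,
0.035), P3 (0.5, 0.040), P4 (0.3, 0.035).

Two properties of I_K drive much of the behaviour below. First, it peaks at
V_rest + 1/beta (around -55 mV) and *decays exponentially* above that, so
the repolarising force is weak at plateau voltages: raising beta or
lowering g_K lengthens the action potential (APD90 ordering P1 < P2 < P3
and P2 < P4; the repolarisation-time integral (1/g_K) ∫ e^{beta u}/u du is
increasing in beta). Second, tissue driven far above the plateau — e.g. by
a grossly suprathreshold stimulus — lands in a region of nearly zero
repolarising current and recovers extremely slowly. This "overdrive dead
zone" shapes the stimulation protocol (below).

## Numerics

* Finite-volume stencil on regular voxel grids; faces to voxels outside
  the mask carry no flux, which implements the Neumann condition exactly
  and makes the discrete divergence telescope (sum over the mask of the
  diffusion term is zero to round-off).
* Anisotropic fluxes are conservative: the normal derivative is taken
  directly across each face, tangential derivatives are face-averaged
  masked centred differences, and tensor components are averaged between
  the two adjacent voxels.
* Time stepping: forward Euler on V fused with Rush–Larsen exponential
  gate updates (unconditionally stable for the gates; they can never
  leave [0, 1]).
* The voltage-dependent membrane functions (m_inf, h_inf, the h-gate
  Rush–Larsen factor, I_K) are evaluated through lookup tables sampled at
  0.05 mV and linearly interpolated — the standard device in cardiac
  tissue solvers. Tables are built per run from the exact cell-model
  functions, which remain the single source of truth (a dual-route test
  checks the fused kernel against the pure reference stencil).
* The kernels are compiled with strict IEEE semantics (no fast-math), so
  a run is bitwise reproducible on one machine and across machines with
  the same floating-point environment. Divergence of *chaotic* quantities
  under changed configurations is expected physics, not a defect, and is
  what the divergence metric measures.
* `stability_bound` combines the explicit diffusion limit
  dx^2 / (2 ndim D_max) with a reaction cap tau_m / 6 = 0.02 ms (six
  steps across the fastest gate time constant); `run` warns above it.
  Defaults: dt = 0.01 ms, snapshot interval 1 ms (at fibrillatory cycle
  lengths of 30–60 ms this gives >= 30 frames per rotation).

Grid resolution matters for this stiff sodium model: planar conduction
velocity at the isotropic sigma is 30.2 cm/s on a 50 um grid, 27.3 cm/s at
the default 125 um (the average edge length of MRI-derived rabbit
ventricular meshes), and collapses
at 250 um. All quantitative sheet results therefore use 125 um spacing;
the volumetric structure experiment uses 200 um, where propagation is
slowed (~21 cm/s) but robust, acceptable for a direction-of-effect
comparison. Two further discretisation figures worth knowing: the 5-point
stencil's directional CV bias is ~6% at 125 um and ~2% at 62.5 um (the
grid-anisotropy control is therefore measured at the finer spacing), and
the cross-fiber direction (D_T = D_L/9, upstroke width ~ sqrt(D)) is
under-resolved at 125 um — the 3:1 anisotropy ratio is recovered within
10% on a 31 um strip, whereas at 125 um it reads ~4.7.

## Stimulation protocol

S1 is a 2 ms, 2x-diastolic-threshold stimulus at the apex (shells) or a
left-edge strip (sheets). S2 is timed into the repolarisation wave of S1:
a short probe run records when a reference site (sheet: (0.3 L, 0.5 L);
shell: the wall voxel nearest the centroid) repolarises through -70 mV,
and S2 fires at that moment so that its region straddles the recovery
line.

Two protocol constants differ from the obvious defaults, both forced by
the I_K dead zone and verified by amplitude/geometry scans:

* S2 amplitude is 1.3x diastolic threshold, not 2x. A 2x S2 over a region
  that is partly refractory pushes that tissue ~+90 mV into the
  slow-recovery zone, creating a long-lived block that extinguishes the
  first rotation.
* On sheets, S2 is a circular patch (radius 0.6 cm) rather than the
  classic cross-field half-plane. The half-plane break produces a single
  tip that is dragged along with the S1 recovery line into the far
  boundary before it can curl. The patch, straddling the recovery line,
  breaks into a counter-rotating tip pair; the patch centre is offset
  from the sheet midline (y = 1.2 cm on the 3.5 cm sheet) so that one tip
  is born within a wavelength of the bottom boundary and is absorbed,
  leaving a single spiral centred in the sheet. A patch S2 also mirrors
  the whole-heart protocol — a large ellipsoidal patch on the ventricular
  wall — more closely than the half-plane does.

The standard sheet experiment (`induce_sheet_reentry`) is fully
deterministic: 3.5 cm isotropic sheet, 125 um spacing, dt 0.01 ms, 2.2 s
of simulated reentry after S2.

`vulnerable_window_scan` repeats the run over a list of S2 timings and
labels each outcome (no_reentry / sustained / self_terminated) from the
phase-singularity counts.

## Synthetic geometry

MRI-derived bi-ventricular rabbit meshes (~4M nodes, with and without
fine endocardial structure) are cluster scale; `fibwave` generates
voxelised stand-ins that keep the contrasts the analyses need:

* sheets (2-D, isotropic — the standard setting for 2-D spiral-wave
  experiments);
* slabs with linear transmural fiber rotation;
* an idealised bi-ventricular shell: a thick-walled "LV" ellipsoid with a
  thinner "RV" crescent, apex closed, base open, surfaces labelled
  epi/endo. Optional fine structure is carved procedurally from a seed:
  vessel-like tunnels marched through the wall and trabecula-like
  endocardial ridges, constrained to perturb total wall volume by < 15%.
  The claim under test is "fine structure destabilises reentry", not the
  anatomy of one rabbit; the structure statistics (cavity count,
  protrusion density, feature scale ~0.08 cm) are free parameters, chosen
  once at scales comparable to real vessels/trabeculae.
* shell fiber fields are circumferential with +/-60 deg transmural
  rotation (helix angle from the normalised endo/epi distance-transform
  depth, smoothed so the per-voxel angle step stays below ~25 deg). The
  apex cap necessarily carries an orientation vortex — no continuous
  non-vanishing tangent field exists on a cap — so fiber-continuity
  guarantees exclude a 0.35 cm column around the axis.

## Analysis definitions

* Phase: time-delay embedding, phase(t) = atan2(V(t+tau) - V*, V(t) - V*),
  defaults tau = 5 ms, V* = -40 mV.
* Phase singularities: topological charge of every 2x2 plaquette (wrapped
  loop sum = +/-2 pi); positions at plaquette centres. The detector is
  tested against a brute-force boundary winding integral on constructed
  fields.
* Tips are linked frame-to-frame by greedy nearest-neighbour matching
  (gate 0.25 cm, strict inequality so a zero gate fragments every
  detection). Meander extent is the axis-aligned bounding box of a track
  after a 200 ms transient discard; core area cycle-averages the orbit by
  rotation phase and applies the shoelace formula (non-periodic tracks
  are flagged and report the convex hull).
* Filaments: the plaquette test applied to all three face orientations of
  the voxel grid; in-plane axes are ordered cyclically so the winding sign
  is a consistent topological charge along each +axis. Punctured faces
  sharing an elementary cube are paired in-flux-to-out-flux
  (deterministic tie-break by face index) and chained into polylines:
  closed rings (O), transmural lines (endpoints on opposite surfaces), or
  U shapes (both endpoints on one surface). Filament counts may include
  or exclude single-puncture fragments; they are included by default.
* Cycle length: -40 mV rising crossings with a 30 ms lockout at a 4x4
  lattice of 16 sites (10% margin), intervals pooled over the 1-2 s
  window after initiation.
* PS density: mean PS count in a 1.5 x 1.5 cm window / 2.25 cm^2; the
  window placement is configurable because the quantity is strongly
  position-sensitive.
* Two-way ANOVA over the structure (wS/nS) and fiber (A/I) factors uses a
  statsmodels OLS fit; per-site windowed cycle lengths serve as samples,
  which is pseudo-replication and is flagged as such wherever reported.
* The divergence of two filament-count series is their absolute
  difference on a common time grid plus the first persistently (>50 ms)
  non-zero time.

## Desk-scale study conditions and what they show

The packaged experiments use (chosen once, stated here as the package's
own design):

* 2-D spirals: 3.5 cm sheet, 125 um, dt 0.01 ms, 2.2 s after S2.
* Structure comparison: shells with outer size ~2 x 2 x 2.4 cm at 200 um,
  parameter set P2, identical protocol for the smooth and each seeded
  structured shell, filament counts averaged over a post-induction
  window.

Emergent quantities reproduced at these conditions: the 2-D regime matrix
(P1 stable around a tiny core, P2 breakup into ~20 phase singularities,
P3/P4 single meandering spirals), P3/P4 cycle lengths within ~10% of the
reference values of ~55 and ~65 ms, and the P3 meander box near the
reference 1.1 cm.

Known quantitative deviations, measured and left standing rather than
tuned away:

* The P1 core area comes out ~0.002 cm^2, several-fold below the
  reference ~0.01 cm^2.
* The P4 meander bounding box (~1.9 cm on its long axis) exceeds both
  the reference 0.9 cm and our P3 box: in this implementation P4's tip
  drifts while it flowers, whereas P4 is expected to be the most compact
  meander.

Plausible sources, in estimated order: transcription uncertainty in the
sodium-current fixture (the printed source table could not be re-checked
when the fixture was written, and meander character is exquisitely
sensitive to recovery kinetics); the finite-volume/125 um discretisation
(CV ~10% below converged); boundary interaction of the meander with the
3.5 cm no-flux sheet; and unprinted protocol details. The well-known
sensitivity of long fibrillation simulations — different computer
configurations or slightly different S2 timings diverge after enough
beats, which the divergence metric here quantifies — is the same
phenomenon seen from another angle, and is why these trajectories are
compared at regime level, with fixed conditions, rather than point-wise.

What passing tests show about real data: the synthetic geometries emulate
scale contrasts, not rabbit anatomy; the cell model has no calcium
handling and essentially no APD restitution, so conclusions transfer only
to the maintenance phase of fibrillation-like reentry, not to initiation
mechanisms that depend on restitution or heterogeneity. No Purkinje
system and no APD gradients are modelled.

## Problem sizes and runtime

The default test-suite and acceptance runs are sized for a single CPU:
2-D sheets are 280 x 280 voxels for ~2.3 s simulated (a few minutes
each); the structure comparison uses ~3 x 10^5-voxel shells for ~0.7 s
each. The solver advances ~10^8 cell-steps per second per core with the
lookup-table kernels.
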