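# Methods

`lbmd` couples an implicit-solvent coarse-grained (CG) particle model
of lipid membranes (and elastic-network proteins) to a lattice-
Boltzmann (LB) fluid, so that hydrodynamic interactions (HI) and
external flows act on the particles.  This note documents the models,
the numerical choices, and what the shipped tests do and do not show.

## Units

Internal units are Å, fs, amu and kcal/mol.  Because kcal/mol is not
the natural energy of (amu, Å, fs), forces from the potential
(kcal mol⁻¹ Å⁻¹) are converted to accelerations with
1 kcal/mol = 4.184·10⁻⁴ amu Å² fs⁻².  File formats convert at the
boundary: GRO is nm, configs accept shear rates in s⁻¹ and kinematic
viscosities in m²/s.  The LB solver runs in lattice units behind a
single conversion layer (Δx = 3 Å, Δt = 10 fs, water mass density).

## Force field

The lipid model is Martini-like with roughly four heavy atoms per
bead and only bond and angle bonded terms:

- bonds: U = ½ k_b (r − r0)²;
- angles: the G96 cosine form U = ½ K_θ (cos θ − cos θ0)² by default.
  A second dialect, ½ K_θ cos²(θ − θ0), is selectable
  (`form="cos_squared"`).  We default to G96 because the literal
  cosine-squared form has its minimum 90° away from θ0 and therefore
  cannot hold an angle at its nominal equilibrium value; the G96 form
  is what the CG lipid ecosystem actually distributes in its topology
  files (function code 2), and it is the form our Boltzmann-sampling
  validation targets.

Nonbonded terms are 12-6 Lennard-Jones plus screened short-range
electrostatics between the charged head beads (choline +1,
phosphate −1) with relative dielectric ε_r = 15 and cutoff
r_c = 12 Å.  Both use the shifted-force polynomial with inner radius
zero: for a power r⁻ᵅ the force is α r⁻⁽ᵅ⁺¹⁾ + A r² + B r³ with
A = −α(α+4)/r_c^(α+3), B = α(α+3)/r_c^(α+4), integrated so U(r_c) = 0.
For α = 1 this yields Φ(r) = 1/r + 5r³/(3r_c⁴) − r⁴/r_c⁵ − 5/(3r_c),
which tends to the bare Coulomb as r → 0 and is C¹ at the cutoff.
Charged pairs can be evaluated from tables holding LJ + switched
Coulomb summed (0.002 Å spacing, linear interpolation, exportable as
three-column text).  Tables agree with the analytic forms to 10⁻¹⁰ on
the nodes by construction.

Exclusions: 1-2 bonded pairs always; 1-3 (angle-spanning) pairs by
default, matching the reference topology dialect (configurable).
Neighbour search uses a periodic k-d tree with a 1 Å Verlet skin,
rebuilt when any bead moves half the skin; results are validated
against a brute-force all-pairs evaluation to 10⁻¹⁰.

No dihedrals and no long-range electrostatics exist in this model by
design.  The package ships only toy parameter sets; published CG
lipid parameter files are accepted through the ITP-subset reader
(sections `[defaults]`, `[atomtypes]`, `[nonbond_params]`,
`[moleculetype]`, `[atoms]`, `[bonds]`, `[angles]`, `[exclusions]`,
both σ/ε and C6/C12 dialects, G96 angle code).

## Lattice-Boltzmann fluid

D3Q19 single-relaxation-time (BGK) with

    ν0 = c_s² (τ − ½) Δx²/Δt,  c_s² = 1/3.

Defaults: Δx = 3 Å, Δt = 10 fs synchronous with MD, and ν0 = 0.1 Å²/fs
(bulk water, 10⁻⁶ m² s⁻¹) giving τ ≈ 0.833.  Body forces enter
through Guo's second-order forcing, which removes O(F²) lattice
artefacts and makes the momentum input per step exactly Σ F.
Shear is generated by moving-wall halfway bounce-back at the two z
faces with wall velocities ±γ̇ L_z/2 (Couette); Lees–Edwards images
are a possible extension but the moving-wall scheme already yields
the linear profile to 10⁻³ and the uniform vorticity −γ̇ ŷ that the
validation suite checks.  Configs accept γ̇ in s⁻¹ (e.g. 3·10⁹ s⁻¹,
the magnitude regime where nanoscale vesicles respond on ns scales).

Low-Mach contract: |u| < 0.1 lattice units; the equilibrium clamps
and logs beyond that, and `set_shear` refuses wall speeds that would
violate it.

## Particle–fluid coupling (LBMD)

Each bead feels a Stokes-like drag toward the locally smeared fluid
velocity,

    F_D = −m γ (v − ũ),

plus a white-noise force with variance 2 m γ k_B T/Δt per component.
γ is printed in fs⁻¹ and interpreted per unit mass — this keeps the
drag dimensionally consistent and gives the standard Langevin limit
D = k_B T/(m γ).  ũ is a trilinear (8-node) interpolation of the
fluid velocity; the weights form a partition of unity, so uniform and
linear (Couette) flows are reproduced exactly at any particle
position.  Species-resolved γ values are plain config inputs
(lipids 2.5·10⁻⁴ fs⁻¹; protein-sized objects use larger values to
match their dilute-solution diffusivities).

Integration is velocity Verlet with the friction+noise applied as an
exact Ornstein–Uhlenbeck midpoint step (BAOAB splitting), stable at
10 fs with the stiff CG bonds.  The momentum the O-step removes from
the particles is deposited onto the fluid through the same trilinear
weights and applied as Guo forcing, so total particle+fluid momentum
is conserved to machine precision in a periodic box — this is checked
directly rather than assumed.  Whether the random kick is included in
the deposit is configurable (`deposit_noise`, default on: exact
closure).  With `hydrodynamics=False` the fluid is bypassed (ũ ≡ 0)
and the integrator reduces *exactly* to a plain Langevin thermostat —
the "without HI" arm of every comparison.  A multiple-timestep mode
updates the fluid every n-th MD step with ũ held in between; n = 1
reproduces the synchronous scheme bitwise.

Walls for shear runs reflect particles; systems are built with cargo
far from walls, so wall behaviour is deliberately unexercised.

## Elastic-network proteins

Structures reduce to one Cα bead per residue plus one side-chain (SC)
bead per non-glycine residue at the side-chain heavy-atom centroid.
All bead pairs within 8 Å in the reference structure get harmonic
springs (k = 5 kcal mol⁻¹ Å⁻²) at their reference length, keeping the
molecule near-rigid (the test suite checks the radius of gyration
stays within 5% under Langevin dynamics at 310 K; desk-scale runs are
0.2 ns rather than the production 100 ns, which bounds only the fast
relaxation — the EN has no slow unfolding modes, so this is the
relevant check).  Cα beads interact purely repulsively with their
radius increased by 50%, because the entire backbone collapses into
that one bead and small peptides would otherwise penetrate a
crowder's outer shell.  Lipid–protein interactions map choline → Lys,
phosphate → Glu, glycerol → Asn and tail → Leu SC types and rescale
the SC–SC well depth by f = 0.545.  The shipped SC–SC table
(`data/sc_pairs_toy.csv`) is a toy set with sensible sizes and
hydrophobicity ordering, not published force-field values; real
parameter files load through the same CSV interface.

## Builders

All builders are pure functions of their arguments plus a seed.

- **Bilayer**: lipids per leaflet = round(L_x L_y / a), a = 69.4 Å²
  by default; jittered near-square lattice; phosphate planes at
  mid-z ± 19 Å (38 Å thickness).
- **Random gas**: seeded rejection sampling, interbead clearance 3 Å
  (the self-assembly starting condition; 128 lipids in a 75 Å box is
  the reference composition).
- **Vesicle**: total lipid count = midplane area / a over both
  leaflets; outer:inner split by the leaflet-sphere area ratio at
  radius ± 19 Å; Fibonacci-sphere lattices with tails pointing to the
  midplane.  The template is laterally rescaled with radial depth
  (wedge packing) and the second tail chain is staggered outward
  1.5 Å, which keeps the deep tail shells clash-free.  At R = 34 Å
  this yields 419 lipids, within the expected ~400 for that geometry.
- **Nanotube**: 11 rings of 11 beads, radius 7.5 Å, length 43.1 Å,
  distal rings hydrophilic, EN springs within 8 Å making it rigid.
- **Cargo packing**: seeded rejection placement of EN payloads inside
  the lumen with a 30% volume cap and 3 Å clearance.

The 12-bead POPC-like template (choline, phosphate, 2 glycerol, 2×4
tails) carries strain-free bonded reference values computed from its
own geometry.  The toy amphiphilic parameter set makes tails attract
strongly (ε = 1.2 kcal/mol), heads moderately (0.5–0.6) and
head–tail weakly (0.25) — the hydrophobic effect of the missing
solvent folded into the well depths.

## Analysis

- Bond/angle/charged-distance distributions (normalized densities)
  against numerically integrated Boltzmann references.
- Membrane thickness from phosphate-plane separation, optionally
  along a fitted normal; radial distribution functions normalized by
  ideal-gas shell counts under PBC.
- Lateral diffusion: 2D MSD over independent blocks (default 100 ns)
  with a linear fit in a 20–40 ns window, D = slope/4, mean ± SE over
  blocks.  Per-leaflet centre-of-mass drift can be removed frame by
  frame (the convention is configurable because conventions differ
  between codes).  A log-log MSD exponent far from 1 flags anomalous
  transport instead of silently reporting a slope.
- Finite-size D(L): a log-linear fit D = a + c ln L (the asymptotic
  periodic-hydrodynamics form), and a truncated-sum periodic membrane
  model with the in-plane mobility summed over nonzero box
  wavevectors,
  Λs = 1/(η_m k² + 2 η_f k coth(kH/2)),
  Λa = the same + 4b,
  averaging the leaflet-symmetric and antisymmetric modes, truncated
  at k_max = π/R (R = 5 Å lipid size).  η_m is the free parameter of
  the fit; bulk viscosity η_f and intermonolayer friction b are held
  fixed.  The exact mode-coupling coefficients differ between
  published treatments; this implementation is validated by its
  limiting behaviour (logarithmic growth in L, monotone damping with
  b, exact self-recovery of η_m from model-generated data).
- Vesicle shape: mass-weighted gyration tensor per frame with ordered
  eigenvalues λ1 ≥ λ2 ≥ λ3 and |Λ⁽³⁾·ẑ| projections (absolute values,
  since the eigenvector sign is arbitrary); near-degenerate spectra
  are flagged and the degenerate-subspace projection reported.
  Oscillation periods come from the dominant periodogram peak of the
  detrended series, with a significance guard.
- Transport: minimal probe-CoM-to-membrane-surface distance (surface
  = phosphate beads by default, minus the bead radius), adsorption
  time as the first sustained crossing below 5 Å; per-substrate
  distance-to-centre traces with release at the first sustained
  excursion beyond the outer radius + 10 Å; shell-volume-corrected
  radial localisation densities.  The 5 Å and +10 Å thresholds are
  about one bead diameter and are logged, not load-bearing.

## Validation strategy and problem sizes

The production-scale phenomena (μs membranes, 3451-lipid vesicles,
nanoreactors) are far beyond desk scale, so validation is
property-based at sizes the test suite can run:

- LB: shear-wave decay recovers ν to <1% (τ ∈ [0.6, 1.5]); Couette
  slope to 10⁻³; mass/momentum conserved to machine precision over
  10⁴ steps on an 8³ grid.
- Coupling: exact exp(−γt) velocity decay; equipartition at 310 K
  within 2% (1000 free particles); D = k_B T/(mγ) within 5% (2000
  particles, 80 ps); momentum closure < 10⁻¹² relative.
- Sampling: 192 dimer/trimer replicas, 0.4 ns at 10 fs, L1 < 0.02
  against r² e^(−βU) and sin θ e^(−βU_θ).
- Self-assembly: 32 template lipids in a 62 Å box, 0.6 ns, with and
  without HI, condense into a single cluster with positive
  amphiphilic segregation.  The friction is set to 2.5·10⁻⁵ fs⁻¹ for
  this scaled run — γ is an adjustable coupling parameter, and a
  smaller value accelerates the Brownian coalescence so the final
  merge falls inside the short trajectory; the assembled state itself
  is friction-independent.

What these tests do **not** show: quantitative agreement with any
published force field (the shipped parameters are toys), membrane
undulation physics (boxes too small), or production diffusion
constants (trajectories far too short).  They do show that every
force routine is the exact gradient of its energy, that the
thermostat and fluid exchange momentum exactly, that the fluid solver
has the nominal viscosity, and that the analysis estimators recover
planted truths.

## Known limitations

- Single-relaxation-time collision only; no multi-resolution grids,
  no electrokinetics, no thermal LB.
- NVT only; no constant-pressure coupling.
- The vesicle builder matches total lipid counts approximately; the
  exact inner/outer split of specific reference vesicles is not
  reproduced.
- Flexible (non-EN) protein dynamics is out of scope; only the EN +
  rescaled nonbonded mapping is implemented.
- The trilinear smearing stencil does not grow with bead radius by
  default (a 27-node widened stencil is the documented extension
  point).
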