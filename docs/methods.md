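# Methods

## The model

`glutensim` simulates seed-storage proteins (gliadins, glutenins and
their mixtures) as flexible bead chains, one bead per residue at the
Cα position, in implicit solvent.  The model is built for intrinsically
disordered proteins: instead of biasing the chains toward a native
structure, the attractive interactions are *dynamic contacts* that are
created and destroyed from the instantaneous backbone geometry.

Reduced units are used throughout: length in nm, energy in the contact
well depth ε ≈ 1.5 kcal/mol, mass in units of the average residue mass
(m = 1), time in τ ≈ 1 ns.  One force unit ε/nm is ≈ 10.4 pN; stresses
in nN/nm² are GPa.  Room temperature is 0.3 ε/k_B.

### Equations of motion

Each bead obeys the Langevin equation

    m r̈ = F − γ ṙ + Γ,   γ = 2m/τ,   ⟨Γ²⟩ = 2 γ k_B T,

integrated with the Grønbech-Jensen–Farago discretization at
dt = 0.005 τ.  This integrator reduces to velocity Verlet at γ = 0,
reproduces the exact exponential velocity decay and free-particle
equipartition at any stable dt, and samples the exact configurational
Boltzmann distribution for linear forces.  Those three properties are
the integrator contract the test suite enforces; the specific
discretization behind them is an implementation choice.

### Interactions

* **Bonds**: V = k (r − r_b)² with k = 5000 ε/nm², r_b = 0.38 nm.  The
  convention carries no ½ prefactor; `k_bond` is configurable for users
  who read "elastic constant" the other way.
* **Local stiffness**: tabulated bond-angle and dihedral potentials per
  residue class (glycine, proline, generic), shipped as editable TSV
  tables under `glutensim/data/` and evaluated by cubic splines
  (periodic splines for dihedrals).  The shipped tables are smooth
  statistical-coil-like *surrogates* — quantitative parity with the
  parent parameterization requires substituting its coil-library
  tables.  An angle term takes the class of its central residue; a
  dihedral is proline-class if either central residue is proline, else
  glycine-class if either is glycine.
* **Excluded volume**: truncated-and-shifted repulsive Lennard-Jones
  core, V_r(r ≤ r_o) = ε(4(σ₀/r)¹² − 4(σ₀/r)⁶ + 1) with r_o = 0.5 nm
  and σ₀ = r_o·0.5^{1/6}, zero beyond r_o.  Pairs (i, i+2) are always
  limited to this repulsion.
* **Dynamic contacts**: interior beads carry a local frame from the
  (i−1, i, i+1) triple — the binormal ĥ points along a possible
  backbone hydrogen bond, −n̂ along the sidechain.  When two beads
  approach below the Lennard-Jones minimum of the candidate type and
  the better-aligned frame vectors of both beads point at the partner
  (|projection| ≥ 0.5, configurable), a contact forms: bb (minimum
  0.5 nm, double depth 2ε), bs/sb (0.68 nm), or ss (minimum R_i + R_j
  from the per-residue radius table; depth ε).  The well switches on
  linearly over t_switch = 10 τ and off the same way once r > f·σ with
  f = 1.5 (1.3 selectable).  During switching the pair potential is
  (1 − λ)·V_repulsive + λ·V_contact, so a pair interpolates smoothly
  between excluded volume and the full well.  Per-residue backbone and
  sidechain slot counts limit how many simultaneous contacts a bead's
  virtual sites can hold; the shipped counts (2 backbone slots; 0–3
  size-graded sidechain slots) are editable surrogates.
* **Disulfides**: cysteine pairs closer than 0.59 nm form an exclusive
  bridge, a Lennard-Jones well of depth 4ε with minimum at 0.59 nm,
  switched like any other contact.  A bonded cysteine cannot take a
  second partner until its bridge has ruptured (faded out after
  separating beyond f·σ).  Competing candidates are resolved closest
  pair first.
* **Static contacts**: structured domains declared per chain carry a
  native contact map; each pair gets a permanent Lennard-Jones well
  with its minimum at the native Cα–Cα distance.  These never switch
  off; for counting purposes a static contact is "made" while
  r < f·σ, the same criterion as the dynamic ones.
* **Electrostatics**: Debye–Hückel with distance-proportional relative
  permittivity ε_r(r) = 40 nm⁻¹ · r, giving V ∝ exp(−r/λ_D)/r²; Lys and
  Arg carry +1, Asp and Glu −1, His 0.  The screening length (default
  1.0 nm) and the 2.0 nm cutoff are configurable.  The published "κ =
  40 nm⁻¹ r" could also be read as a screening parameter; this package
  implements the permittivity reading and exposes both knobs.
* **Walls**: the box is periodic in X/Y and closed along Z by two solid
  walls at z = 0 and z = s.  Both walls always repel (truncated LJ,
  depth 4ε, minimum 0.5 nm, acting on the perpendicular distance).
  With adhesion enabled, a bead that comes within 0.5 nm of a wall
  acquires an interaction center: X/Y frozen at the first-touch
  position in the wall's frame, Z riding on the wall, well depth 4ε
  ramped on adiabatically.  A bead more than 2 nm from its center
  detaches (the well fades out) and may reattach elsewhere.  The force
  the beads exert back on the walls is recorded every step;
  block-averaging over 100 ns windows (scaled with the schedule) gives
  the measured force signals.  The reported normal force is positive
  under tension; the shear force is the drive force on the moving wall,
  so an ideally elastic sample responds in phase with the displacement.

### Numerical safeguards

The repulsive cores are linearized below an inner cap (0.3 nm for the
excluded volume, 0.7·σ for contact cores, 0.35 nm for the walls): the
capped forces (~10⁴ ε/nm) are far beyond anything thermally reachable
(the Boltzmann weight of such separations is ~e⁻³⁰), but remain
integrable when the moving wall sweeps beads into overlap during fast
desk-scale compression.  A step that would move a bead further than
0.5·r_o raises an error; the protocol layer responds by re-integrating
that interval with 10–1000× smaller steps.  A reflection guard at the
walls backs up the repulsive potential.  Neighbor search is a chunked
O(N²) pair list with a 0.3 nm Verlet skin, rebuilt on a
max-displacement trigger; for chargeless systems its cutoff shrinks to
the contact-creation range.  Contact birth/death scans run every 10
steps (0.05 τ), far below the 10 τ switching time; λ ramps advance
every step.

## Simulation protocol

The default schedule follows the sample's life cycle: chains are grown
as self-avoiding random walks (bond 0.38 nm, clash radius 0.5 nm,
min-image in X/Y, walks confined outside the walls' repulsive zone; a
box that cannot host a walk is enlarged by 5%, so the realized density
only drops below the requested 0.1 residues/nm³).  Then: 125 μs dilute
equilibration; affine compression at 2 mm/s (X, Y and s shrink
proportionally, bead X/Y rescale with the box, the wall sweeps beads in
Z) to ρ₀ = 3.5 residues/nm³; 150 μs equilibration; wall adhesion on,
150 μs more; then either five oscillation cycles — the moving wall is
first displaced to the minimum, then s(t) = s₀ − A cos ωt (normal) or
s′(t) = −A cos ωt (shear) with A = 1 nm and period 40 μs (70 μs
selectable) — or 100 μs of extra equilibration in the control; 75 μs of
final equilibration during which analysis snapshots are taken; finally
uniaxial extension at 0.5 mm/s to 2 s₀, recording force and work.

All durations divide, and all boundary speeds multiply, by one `scale`
factor, so desk-scale runs traverse the same code path with identical
geometry.  Every random draw descends from a single seed, and the seed
is shared between drive modes, so trajectories agree bit-for-bit until
the oscillation stage.  The tests and the acceptance script use a
4-chain × 50-residue glutamine-rich system at scale 1000 (~1.5×10⁵
steps, a few minutes on one core); tiny 24-bead runs at scale 5000 with
a reduced target density (1.5 nm⁻³ — at 24 beads the walls' 0.5 nm
exclusion zones dominate a ρ₀ = 3.5 box, which would leave no free
volume) cover protocol plumbing.

## Observables

* **Coordination number** z = 2·(active contacts)/ΣN; contacts count
  while switching on or on (λ > 0), static ones while r < f·σ.
* **n_inter**: active contacts joining different chains.
* **RMSF**: per-residue RMS deviation from the time-mean position over
  the post-kneading snapshots, after removing per-frame center-of-mass
  drift (toggleable); trajectories are unwrapped across the periodic
  boundary first.
* **Distortion w**: radii of inertia R₁ ≤ R₂ ≤ R₃ are square roots of
  the per-chain moment-of-inertia eigenvalues (unit masses); w =
  (R₂ − R̄)/R̄ with R̄ = (R₁+R₃)/2 — 0 for a sphere, 1 for a rod,
  negative for oblate shapes.
* **F_max**: mean ± SD of the 5 largest samples of the window-averaged
  pull force, with a minimum separation of one averaging window between
  chosen samples so a single spike is not counted five times; a
  cross-seed combiner weights by 1/SE².  **W_max**: maximum of
  W(s) = ∫F ds (trapezoid on the averaged curve).
* **Dynamic shear modulus**: least squares of the strain and force
  series on the (cos ωt, sin ωt, 1) basis after discarding the first
  drive period as transient; δ = phase(force) − phase(strain) folded to
  [0, π); γ₀ = A/s₀, φ₀ = F₀/S with S = Lx·Ly held fixed under shear
  tilt; G′ = (φ₀/γ₀) cos δ, G″ = (φ₀/γ₀) sin δ, reported in MPa.
  A non-positive fitted amplitude flags the result as low-signal.
* **Entanglements l_k**: each chain's path (ends pinned) is contracted
  toward straightness by iterative midpoint moves, rejecting any move
  whose swept triangles would be pierced by another path's segment
  (Z1-style non-crossing constraint).  On the contracted paths, a kink
  is a contiguous run of interior vertices with turning angle > 10°
  lying within 0.5 nm (≈ 2 bead radii) of another chain's path; each
  run counts once.  Self-entanglements never count because the
  proximity test ignores the own chain.  Non-convergence within the
  sweep budget is flagged, not raised.  Paths are unwrapped chains;
  periodic images are not used as obstacles — a known limitation for
  entanglements threading the periodic boundary.
* **Cavities**: grid-and-probe contour (default grid 0.1 nm, probe
  0.38 nm, one grid orientation).  A cell is occupied if its center is
  within the probe radius of a bead (beads replicated across X/Y
  wraps); free cells 6-connected to any box face — the periodic faces
  and both walls seed the flood fill — are exterior; remaining
  components are cavities.  Cell volumes are chosen so occupied +
  exterior + cavities equals the box volume exactly.  Pockets smaller
  than the probe sphere volume (e.g. the unreachable corners of a
  right-angle cage) cannot host the probe and are not counted as
  cavities.
* **Kneading-effect ratios**: each observable after oscillation divided
  by its matched-seed no-oscillation value, relative errors combined in
  quadrature.

## What the synthetic inputs do and do not emulate

The toy sequence generator reproduces gluten's glutamine richness
(default 35% Q), low charge content and adjustable cysteine count, but
not the repeat architecture, the gliadin/glutenin length asymmetry or
the real HMW/LMW composition.  The bundled gluten-like composition is
*synthetic*: two Q-rich repeat sequences whose record-mean length (384),
record-mean cysteine count (6.5) and total size (4271 residues) match
the published summary of the real mixture while the sequences
themselves do not.  Geometry fixtures (hook/straight chain pairs, bead
shells and channels) carry their ground truth by construction.  Passing
tests therefore demonstrate the machinery — contact dynamics,
integrator statistics, protocol plumbing, observable definitions — not
quantitative agreement with wheat gluten; desk-scale moduli and contact
numbers land in physically sensible ranges but are not expected to
match production-scale values, which require ~4000-residue systems
evolved for hundreds of μs.

## Known limitations

* Angle/dihedral tables, ss-radius and slot tables are surrogates (see
  above); substituting the parent model's tables is required for
  quantitative parity with it.
* No hydrodynamics, no explicit solvent, no barostat; density is set by
  the compression stage only.
* Entanglement counting ignores periodic images and counts kinks on
  both partners of a wrap, following the kink-counting convention.
* The Gear predictor-corrector used historically for this model family
  is replaced by a stochastically exact Langevin integrator; individual
  trajectories differ, statistics agree within the stated contracts.
* Desk-scale runs use a 24–200 residue system; quantities that grow
  with system size (l_k, n_inter, F_max, W_max) are not comparable to
  production-scale values, only their definitions and pipelines are.
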