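# Methods

## Model and protocol

The protocol alternates two stages on a receptor–ligand system held in
internal units nm / ps / kJ·mol⁻¹ / e.

**Direction search.** Candidate rigid translations `v` of the whole ligand
(no rotation, no internal flexibility — conformational relaxation is the
dynamics stage's job) are drawn uniformly from the ball ‖v‖ ≤ 0.7 nm and
scored with

E_score(v) = E(v) − E_prev + α·|E(v)|,  E = E_elec + E_vdw,

where E is the truncated (1.0 nm cutoff, no shift) Coulomb + 12-6
Lennard-Jones ligand–receptor interaction with Lorentz–Berthelot combination
rules, E_prev is the energy of the pose at the end of the previous interval,
and α = 2. Writing g(E) = E + α|E| shows what the score does: for α > 1 it
is minimised by the reachable pose of *smallest interaction magnitude*
(positive energies penalised (α+1)-fold, negative ones rewarded only
(α−1)-fold), so the search climbs out of the binding well toward the least
interacting — most solvent-like — direction while overlap poses are strongly
rejected. With α = 0 the score reduces to the energy difference and dives
into the deepest attraction; α = 2 balances escape against trapping.

The minimiser is classic DE/rand/1/bin: mutant `x_r1 + F (x_r2 − x_r3)`
with three distinct partners, binomial crossover (CR = 0.9, one guaranteed
mutant coordinate), greedy one-to-one selection with ties keeping the
incumbent, F = 0.5. Infeasible trials are rescaled radially onto the ball
boundary, which preserves their direction and keeps feasibility exact.
Production-scale defaults are population 3000 and 100 generations; the
fixture studies run 48 / 30, which the synthetic landscapes (hundreds of
receptor atoms, a handful of basins) resolve comfortably. The best
candidate's unit vector becomes the interval's pulling direction. If the
interaction field is identically zero across the probe ball — the ligand has
left the receptor — the previous direction is reused, so the pull continues
straight once outside (on the first interval this raises an error instead).

**Pulling stage.** Overdamped Langevin (Brownian) dynamics,
dx = F/γ dt + √(2 k_B T dt/γ) N(0,1), with receptor atoms fixed and
per-atom friction γ = 50 kJ·mol⁻¹·ps·nm⁻². The spring (k = 600
kJ·mol⁻¹·nm⁻², the AFM-typical stiffness) ties a dummy atom moving at
v = 5 nm/ns along the current direction to the ligand atom nearest the
ligand centre of mass (unit masses; the selection is translation/rotation
invariant and ties break on the lowest atom id). By default the ligand
translates as a rigid body — net force over summed friction — because a
single-atom pull with no intra-ligand terms would otherwise strip the pulled
atom off the molecule; a fully flexible per-atom mode exists
(`rigid_ligand=False`) for single-atom or loosely coupled ligands.

**Spring anchor carry-over.** The dummy's position persists across interval
boundaries (a vector spring, continuous through direction changes), so
extension accumulates until contacts rupture. This is essential: a spring
re-anchored at every τ = 20 ps interval can never exceed ≈ k·v·τ = 60
kJ·mol⁻¹·nm⁻¹ and would never free a realistically bound ligand. Rupture
forces of hundreds of kJ·mol⁻¹·nm⁻¹ in constant-velocity pulling likewise
presuppose accumulated extension. Per-interval re-anchoring is available
(`PathfinderConfig(spring_reset=True)`) for diagnostics.

**Termination.** Exit: the minimum ligand–receptor atom distance exceeds
cutoff + 0.2 nm (equivalently, both truncated energy components are exactly
zero) at two consecutive interval ends; after the first crossing the
direction is frozen for the confirmation intervals. Stuck: ligand CoM moves
less than 0.01 nm per interval for five consecutive intervals. Otherwise the
interval budget N (simulation time / τ) decides.

## Numerical choices

- Euler–Maruyama integration, Δt = 0.002 ps default (0.01 ps in the fixture
  studies, where k Δt/γ ≤ 0.12 and T ≤ 20 K keep the update well inside the
  stability region). The free-ligand trajectory matches the closed form
  x(t) = vt − (γv/k)(1 − e^(−kt/γ)) to < 10⁻⁴ nm at 20 ps.
- Per-step displacements are capped at 0.03 nm per atom. The cap only
  engages when a trial step would jump into/out of a Lennard-Jones core
  (where explicit Euler would otherwise explode); resolved dynamics moves
  ~10⁻⁴–10⁻² nm per step and is untouched.
- Each profile sample pairs the end-of-step displacement with the force that
  acted *during* the step (pre-step evaluation). Recording the post-step
  force would correlate the force with that step's thermal kick and bias the
  work sum by −k·Var(noise) per step (an Itô-correction artefact worth ~10³
  kJ/mol over a trajectory at 300 K).
- A distance clamp (0.01 nm) bounds pair energies and forces for deeply
  overlapping probe poses; the α-term is the physical overlap guard, the
  clamp only protects floating-point range.
- Receptor sums use an exact distance prune: atoms within cutoff + margin of
  the ligand CoM, with the margin covering ligand extent plus the worst
  observed drift (the interval re-runs with a doubled margin if exceeded),
  so pruned results equal the full sums.
- Work uses the left-Riemann sum over profile samples (trapezoid optional);
  W_pull is reported for trajectories that reached the unbound state, since
  it is defined as the work at the end of egress.
- Ties in DE selection keep the incumbent; among equal-score finalists the
  lowest population index wins — determinism for fixed seeds. Non-finite
  objective values become +∞ and are never selected.

## Synthetic systems

The generator builds receptors from concentric near-uniform
(Fibonacci-sphere) layers of neutral LJ atoms (σ = 0.2 nm, ε = 0.3 kJ/mol)
spaced 0.21 nm in-layer and radially — below 2^(1/6)·σ, so the shell is
leak-proof — from a binding-pocket radius (0.45 nm) out to the shell radius
(1.08 nm default). Channels are carved by deleting atoms within a clearance
radius of a centreline polyline (optionally tapered per segment); each
carries a labelled exterior gate sphere as ground truth for pathway
classification. The binding well is a ring of six small-σ (0.05 nm)
attractive atoms at 0.30 nm around the site centre, with ε calibrated so the
bound-pose ligand–ring energy equals −ε_site exactly (the total binding
energy adds a constant shell-contact term of a few kJ/mol). The default
ligand is a rigid 3-atom equilateral triangle (side 0.15 nm, σ = 0.3 nm,
ε = 1 kJ/mol).

Fixtures and their study conditions (all with the published pulling
parameters k/v/τ/α/CR/F; DE 48/30; Δt = 0.01 ps):

- **STRAIGHT** — one axial channel (r = 0.35 nm); T = 0; 20 trajectories;
  every trajectory must exit through the gate.
- **BENT** — the easy route turns 90° at an elbow 0.72 nm above the site;
  the straight continuation is a tight vent (r = 0.26 nm) passable only by
  squeezing at several-hundred force units. T = 0. Adaptive pulling turns
  the elbow at ~30 kJ/mol; a fixed +z pull squeezes through the vent at
  ~120 kJ/mol with a secondary force peak after the initial rupture — the
  obstructed-tunnel scenario that motivates multidirectional pulling.
- **TWO_CHANNEL** — equal 0.40/0.42 nm mouths up and down, the lower channel
  tapering to 0.30 nm in the outermost layer; T = 20 K. The first direction
  choice is a genuine near-tie, mild thermal noise splits the ensemble, and
  the wider, cheaper channel holds the majority. The constriction sits
  beyond the interaction cutoff of the pocket so it cannot bias the initial
  choice by its extra wall attraction.
- **CAGE** — no channel; nothing may exit under any seed (the wall's core
  repulsion exceeds any force the spring can build within the interval
  budget by orders of magnitude).

Temperatures of 0–20 K look small against laboratory conditions but are the
right scale here: the fixture's energy landscape is ~10–40 kJ/mol deep,
roughly a tenth of a real binding site, so the k_B T that probes it scales
down accordingly.

**What the generator does not emulate:** receptor flexibility (gating
loops, induced fit), solvent and electrostatic screening, ligand
conformational change, and the rugged many-atom energy landscape of a real
protein. Passing the fixture studies therefore demonstrates the protocol's
mechanics — direction selection toward open channels, obstacle avoidance,
multi-pathway discovery, work-based ranking — not production accuracy on
real complexes, which requires the external-engine adapter and an all-atom
setup.

## Design decisions that were genuinely open

- **Direction from the single best candidate.** The optimal-score level set
  can be broad (any near-zero-interaction pose ties); the protocol relies on
  per-interval re-decision, not on any single direction being perfect.
- **Probe constraint by radial rescaling** onto the ball boundary rather
  than rejection/resampling: cheap, deterministic, preserves direction.
- **Fresh DE population every interval** (no warm start): the pose changes
  by a full interval of dynamics, and independence keeps intervals
  reproducible in isolation.
- **Exit criterion via zero truncated contact** (distance > cutoff + 0.2 nm
  sustained twice): "has left the receptor" is exactly representable under
  truncation, and the buffer makes the test robust to single-step
  backsliding.
- **Stuck reporting, never silent retries:** arrested trajectories are part
  of the result (they carry the success-rate statistic).
- **Vacuum dielectric (ε_r = 1)** for the electrostatic component,
  configurable; the score only ranks candidate translations, so screening
  choices shift all candidates together.

## Known limitations

- The toy engine's rigid-body ligand cannot capture conformational gating;
  use the adapter for anything all-atom.
- Overdamped dynamics has no inertia, so rupture events relax
  instantaneously on the friction timescale; rupture forces are
  qualitative.
- The force profile is sampled every integrator step; at production τ/Δt
  this is ~10⁴ samples per interval and dominates memory before it dominates
  time (downsampling is an analysis-side concern).
- Gate-based pathway classification needs disjoint gates; the angular
  clustering fallback (complete linkage, 45° threshold) is a labelled
  heuristic for gate-free use.
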