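# Methods

## Overview

`embryosim` simulates early C. elegans embryogenesis as an agent-based
system in which the three basic cell behaviors are handled by separate,
independently testable models:

* **fate and division timing** are *data*: the invariant lineage (a binary
  tree of named, timed divisions) is read from a table and drives the
  simulation clock;
* **division orientation** is a fitted geometric model: the axis is the
  normalized weighted sum of three unit cues;
* **position** is mechanics: cells are point masses joined by springs,
  and at every 1-minute observation step the configuration minimizes
  potential energy inside a rigid ellipsoidal eggshell;
* **directed migration** (the Cpaaa intercalation scenario) is a separate
  reinforcement-learning module on a lattice, not coupled into the main
  loop by default.

Times are integer minutes throughout, matching the 1-minute live-imaging
cadence the data formats emulate.

## Lineage module

A `LineageTree` validates at construction: unique names, one root, 0 or 2
children per cell, daughter birth time equal to mother division time.
Fate labels (`pharynx`, `neuron`, `hypodermis`, `muscle`, `gut`, `other`,
`unassigned`) are inert annotations with no mechanical effect. Daughter
naming uses Sulston suffixing restricted to `a`/`p` — the simulator only
resolves the division axis against the anterior-posterior (AP) axis — with
the founder-cell exceptions (P0→AB+P1, P1→EMS+P2, P2→C+P3, P3→D+P4,
EMS→MS+E) in a fixed lookup table. When two cells share a division time
they are processed in lexicographic name order; the tie-break is a package
convention, as observation data fix none.

Newick export writes branch lengths as cell-cycle lifetimes in minutes and
fates as `[&fate=...]` metadata comments; terminal cells get length 0,
which is unambiguous because a real cell cycle lasts ≥ 1 minute. dendropy
is the Newick reader on re-import.

## Mechanics module

Each cell is a point mass with an effective radius r (in μm). Contacting
pairs — |x_i − x_j| ≤ `contact_factor`·(r_i + r_j), default factor 1.2 —
are joined by linear springs of rest length r_i + r_j and global stiffness
k (default 1 energy/μm²). The graph is rebuilt after every division. The
eggshell is the ellipsoid g(x) = ‖((x−c)/a, (y−c)/b, (z−c)/c)‖ = 1 with
default semi-axes (25, 15, 15) μm, matching an embryo roughly 50 μm long
and 30 μm across, and enters the energy as a one-sided quadratic penalty
½·k_shell·max(0, g + ρ − 1)² with k_shell = 10·k, where ρ = r·g/|x−c| is
the radius converted to normalized units along the ray from the shell
center through the cell (exact on that ray). Inertia and damping are
dropped entirely: relaxation is assumed fast relative to the observation
cadence, so positions at each step are a potential-energy minimum
("quasi-equilibrium").

Minimization uses L-BFGS-B with the analytic gradient (verified against
central finite differences in the tests); convergence demands gradient
max-norm ≤ 1e-6 energy/μm within 10,000 iterations and never-increasing
energy, else a `ConvergenceError` carrying the last iterate. Without a
shell the energy is invariant under rigid motions; the first cell is then
pinned and the second constrained to the line joining it to the first,
which removes five of the six zero modes without altering any inter-cell
distance (the remaining rotation about that line is a true zero mode and
does not affect convergence of distances or gradients). Exactly coincident
cells are separated by a 1e-6 μm seeded jitter before relaxation.

Division places equal-volume daughters at ±`offset_fraction`·r along the
chosen axis with radius r/2^(1/3), conserving total volume to machine
precision.

**Penalty-method containment.** With no opposing load, a cell outside the
shell relaxes onto the contact surface (overlap ≤ 1e-6 in normalized
units). Under load the penalty admits a finite squeeze: a boundary cell
equilibrates where the shell force k_shell·overlap·|∇g| balances the net
spring push, which at the default 60% 16-cell packing gives overlaps of
order 0.1–0.2 normalized units. This is the intended soft-shell behavior
of a quadratic penalty, not a convergence failure; a hard-wall guarantee
would require constrained optimization or k_shell several orders larger.

## Division-direction module

The axis of a dividing cell is d = normalize(K_p·p + K_s·s + K_e·e):

* p — the cell's polarity (unit vector). A daughter's default polarity is
  its mother's division axis; the root's polarity is the AP axis.
* s — composite cell–cell squeeze: the normalized overlap-weighted sum of
  repulsion directions, Σ_j max(0, (r+r_j) − d_j)·(x−x_j)/d_j, zero when
  no neighbor overlaps.
* e — cell–eggshell squeeze: the inward ellipsoid normal at the cell's
  radial projection when the cell presses on the shell (g + ρ above the
  contact threshold, default 1), else zero.

The two squeeze forms are package modeling choices; the cues are only
named, not specified, by the observational protocol this emulates.

Axes are undirected (microscopy cannot orient a spindle consistently), so
the error between a prediction and an observation is arccos|d_pred·d_obs|
∈ [0, π/2], and all objectives are invariant to sign flips. The
coefficients are fitted by minimizing the summed angular error over
observations. Because the objective is invariant to positive rescaling of
K, the gauge K ≥ 0, ‖K‖₁ = 1 is imposed for identifiability. The
optimizer is multi-start Nelder-Mead (default 16 starts: the three simplex
corners, the barycenter, and seeded Dirichlet draws) over the
unconstrained parametrization K = z²/‖z²‖₁; a coarse pass ranks the
starts and only the best is polished to tight tolerances, since the
objective is cone-shaped (non-smooth) at a perfect fit and simplex search
crawls there. The reported objective is evaluated at the returned
(normalized) K so that recomputation reproduces it exactly; note that
arccos amplifies last-bit rounding of a unit dot product to ~1e-8 rad,
which is the practical floor for "zero" angular error.

With 200 observations at 5° mean angular noise the fit recovers a
simplex-interior K with cosine similarity ≥ 0.98 in ≥ 95% of seeded
replicates (measured 50/50 in the acceptance run), and ≥ 0.999 with
noiseless data.

## Movement module

Directed migration is a path-optimization problem on a bounded integer
lattice (2-D or 3-D): neighbor cells are static occupied sites, the
eggshell is the lattice boundary, and the agent must reach an ordered
sequence of sub-goals (the rosette waypoints of the Cpaaa intercalation)
before its destination. Actions are axis-aligned unit moves plus stay;
a blocked move leaves the agent in place. Rewards: −`step_cost` (default
1) per step, −`collision_penalty` (default 5) extra when blocked,
+`goal_reward` (default 100) on reaching the current goal, which advances
the goal index. The constants are package defaults exposed in the
scenario file.

The learner is tabular Q-learning over the state (offset to current goal,
occupancy mask of adjacent sites, goal index) — exact, seeded, and
bit-reproducible for a fixed seed, with the environment/reward contract
kept learner-agnostic so a function-approximation agent could be swapped
in. The goal-relative state deliberately aliases lattice sites with equal
offset and local mask; the bundled scenarios are sized so aliasing never
changes the optimal path, which the tests verify against a breadth-first
shortest-path oracle. Defaults: 3000 episodes (4000 for the sub-goal
scenario), α = 0.5, γ = 0.95, ε linear from 1.0 to 0.05. Greedy rollouts
break ties toward the lowest action index and abort on a revisited
(site, goal-index) pair. Path statistics follow the 50-run averaging
protocol: per-step mean and standard deviation across rollouts, ragged
paths padded with their final position.

## Simulator engine

Per 1-minute step: (1) all divisions scheduled at t execute in
lexicographic mother order — axis from the direction model on current
geometry, daughters placed, named (anterior daughter on the hemisphere
the axis shares with the AP axis) and given the axis as polarity; (2) the
contact graph is rebuilt and the network relaxed once after the batch;
(3) a snapshot is recorded and checked against the lineage's alive set.
Steps without divisions reuse the existing equilibrium (nothing has
changed, so the configuration is a fixed point).

The initial state is a single root cell at the shell center with radius
(fill·a·b·c)^(1/3), chosen so the 16-cell stage occupies `fill_fraction`
(default 60%) of the shell volume under equal-volume splitting — exactly
15 μm for the default shell.

**Axis symmetry breaking.** A noise-free axis pipeline started from a
single cell is degenerate: every predicted axis lies along the AP axis,
all cells stay exactly collinear (a measure-zero saddle of the energy
that the relaxation can never leave), and the chain extends far outside
the shell. Real division axes scatter; the simulator therefore tilts each
chosen axis by a seeded random angle (half-normal, mean `axis_noise_deg`,
default 3°, about a uniform transverse direction). Runs remain bitwise
reproducible per seed. Setting `axis_noise_deg: 0` restores the
deterministic axis model for isolated-division studies. The default
division coefficients (0.5, 0.3, 0.2) are polarity-dominant but
squeeze-aware; no observational value constrains them.

## Synthetic data

All fixtures are pure functions of a spec plus a seed:

* `synth_lineage` — complete binary tree (root "AB"), uniform division
  interval (default 15 min), fates cycled over the five tissue-marker
  labels in breadth-first order.
* `synth_divisions` — cue triples uniform on the sphere (s and e zeroed
  with probability 0.2 / 0.3 — a dividing cell need not feel any
  squeeze), observed axis = model composition tilted by a half-normal
  angle about a uniform transverse axis. The half-normal is parametrized
  by its *mean* (scale = mean·√(π/2)) so the generated data's mean
  angular deviation equals the nominal noise level — the natural
  calibration for a generator whose purpose is a known noise magnitude.
* `synth_migration_scenario` — `corridor` (1×7 lane), `open_grid` (7×7),
  `detour` (7×7 with a wall forcing a 6-step detour), and `cpaaa_like`
  (a 4-row band of occupied cells crossed by a single free channel, four
  ordered sub-goals in the channel, destination beyond the band).
  Reachability of every goal leg is verified by construction.

What the generators do **not** emulate: tracking errors and cell
misidentification, division-time variability between embryos, unequal
divisions (all splits are equal-volume), cue correlations (real polarity
aligns with tissue axes rather than being isotropic), and moving neighbor
cells during migration. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not fidelity to any particular
real embryo recording.

## Numerical choices and limitations

* Relaxation tolerance 1e-6 energy/μm (max-norm), max 10,000 L-BFGS-B
  iterations; fit polish tolerances 1e-10 (simplex size) / 1e-14
  (objective); Q-learning is exact arithmetic on a dict.
* Problem sizes: the bundled embryo runs go to the 16-cell stage
  (4 synchronous generations, 61 recorded minutes); the K-recovery study
  uses 200 observations × 50 replicates; migration lattices are ≤ 9×8.
  All were chosen as the smallest sizes at which the respective behaviors
  (packing, identifiability, detour/sub-goal structure) are non-trivially
  exercised.
* Division handling assumes at most one division per mother per step and
  a binary, equal-volume split; the engine raises on any lineage
  inconsistency rather than repairing it.
* The fate labels are carried but never consumed; a pluggable fate
  provider could later map genotype → fate without touching the engine.
* The mechanics has no cell shape, adhesion heterogeneity, cortical
  tension or viscoelasticity; the migration module has no deep function
  approximation, multi-agent training, or continuous actions.
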