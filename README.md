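# embryosim

Agent-based simulation of early *C. elegans* embryogenesis for
systems-biology researchers who want a small, fully testable sandbox for
hypothesis testing about cell fate, division and movement.

The *C. elegans* embryo is uniquely suited to this: its lineage is
invariant and fully mapped, so each cell's fate and division time can be
treated as observation data while mathematical models handle the rest.
`embryosim` implements that split:

* **Lineage** — fate and division timing come from a Sulston-style
  lineage table (`name,parent,birth_time,division_time,fate`); the tree
  drives the simulation clock. Newick export/import included.
* **Division orientation** — the division axis is modeled as
  d = normalize(K_p·**p** + K_s·**s** + K_e·**e**), where **p** is the
  cell's polarity, **s** the composite cell–cell squeeze direction from
  overlapping neighbors, and **e** the cell–eggshell squeeze direction.
  The coefficients K ≥ 0, ‖K‖₁ = 1 are fitted to observed axes by
  minimizing Σᵢ arccos|d_pred,i · d_obs,i| (axes are undirected).
* **Mechanics** — cells are point masses; contacting pairs are joined by
  springs with rest length r_i + r_j; the eggshell (ellipsoid with
  semi-axes 25 × 15 × 15 μm) is a one-sided quadratic penalty. Inertia
  and damping are neglected, so at every 1-minute step the positions
  minimize E = Σ ½k(|xᵢ−xⱼ|−L₀)² + Σ ½k_shell·max(0, g(x)+ρ−1)²
  (quasi-equilibrium).
* **Migration** — directed single-cell movement (the anterior
  intercalation of Cpaaa) as tabular Q-learning on a lattice of occupied
  neighbor sites, with an ordered sequence of sub-goals (rosette
  waypoints) before the destination, and the 50-run mean ± SD path
  statistics protocol.
* **Synthetic data** — seeded generators for lineages, division
  observations with known K and controlled angular noise, and migration
  scenarios, so everything is testable without downloads.

## Worked example

Generate observations from a known coefficient vector, fit, and simulate:

```sh
embryosim synth lineage --generations 3 --interval 10 --out lin.csv
embryosim synth divisions -n 100 --noise-deg 5 --seed 2 --out obs.csv
embryosim fit-divdir --observations obs.csv --seed 2 --out model.json
embryosim simulate --lineage lin.csv --divdir model.json --seed 3 --out traj.csv
```

prints

```
wrote 15-cell lineage (3 generations)
wrote 100 observations (noise 5.0 deg)
fitted K=(Kp=0.5932, Ks=0.3031, Ke=0.1038) objective=8.629524 rad over 100 observations
simulated 31 time points, 7 divisions, final count 8
```

The generator's true coefficients are K = (0.6, 0.3, 0.1); with 100 noisy
observations (5° mean angular scatter) the fit lands at
(0.593, 0.303, 0.104) — an average residual of 8.63/100 ≈ 0.086 rad ≈ 4.9°
per observation, consistent with the injected noise. The trajectory file
`traj.csv` is a nuclei time-series table (`time,name,x,y,z,radius`, μm)
with one row per live cell per minute, in the style of automated-lineaging
output.

The migration scenario end-to-end:

```sh
embryosim synth scenario --kind cpaaa_like --out scen.yaml
embryosim train-move --scenario scen.yaml --episodes 4000 --seed 0 --out pol.json
embryosim rollout --scenario scen.yaml --policy pol.json --runs 50 --out paths.csv
```

prints `trained 4000 episodes; final return 493.0` and
`50 rollouts, path length 7 steps`: the learned policy threads the single
free channel through the occupied band, visiting the four sub-goals in
order before the destination, on the shortest possible route.

Everything is also available as a library (`embryosim.lineage`,
`.mechanics`, `.division_direction`, `.movement`, `.simulator`,
`.synthetic_data`); the CLI is a thin wrapper.

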