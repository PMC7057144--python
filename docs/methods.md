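# Methods

## The supervision model

The sampled object is a ligand–target binding pathway. The reaction
coordinate is the Euclidean distance between the mass-weighted centre of
mass (COM) of the ligand and the COM of a user-selected set of target
groups (the binding site). Dynamics proceeds in segments of
`segment_length` (default 600 time units). Within each segment
`n_fit_points` (default 20) equally spaced distance samples are taken,
endpoint included; the start point of the segment is not a sample, so a
segment's fit reflects only its own dynamics. The ordinary-least-squares
slope of (time, distance) decides the segment's fate:

* slope < `slope_threshold` (default 0, strict inequality): **accept** —
  the segment's frames join the trajectory and dynamics continues from its
  end state;
* otherwise: **reject** — coordinates revert bit-identically to the
  segment start, velocities are redrawn from Maxwell–Boltzmann at the
  thermostat temperature with a fresh seed, and the segment is retried;
* any sample below `switch_off_distance` (default 5 Å) overrides both:
  **switch-off** — the triggering segment is retained (the approach is part
  of the pathway), supervision is disabled permanently, and
  `relaxation_length` (default: one segment) of plain dynamics ends the run
  with status `bound`.

Budgets make failure explicit rather than silent: `max_segments`
(default 500) bounds the total *attempted* segments (accepted + rejected),
and `max_failed_attempts` (default 30) bounds consecutive rejections at one
segment position; exhausting either terminates the replica with a distinct
status. A slope exactly at the threshold rejects, mirroring the strict
"slope is negative" rule.

Replica campaigns run up to 10 independent supervised simulations from the
same start. "Best" is defined quantitatively (the protocol itself gives no
formula): among bound replicas, lowest mean COM distance over the final
quarter of frames, ties broken by lower mean interaction energy.

## Energetics

The per-frame estimator is the ligand–target interaction energy only; no
target-internal or ligand-internal nonbonded terms enter. For each
(ligand atom *i*, target atom *j*) pair within `nonbonded_cutoff`
(default 9 Å, plain truncation, no switching function):

* electrostatics: k·q_i·q_j / (ε_r·r) · exp(−r/λ_D), with k = 332.0636
  kcal·Å/(mol·e²), relative dielectric ε_r = 80 and Debye length
  λ_D = 8 Å by default. The screening stands in for aqueous solvent and a
  physiological ionic atmosphere; it replaces a generalized-Born solvation
  estimate while preserving the analysis shape (a per-frame scalar plus a
  per-group decomposition). Outputs are labelled "interaction energy
  (MM, screened)".
* van der Waals: 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination
  (σ arithmetic mean, ε geometric mean).

Each pair is attributed to the *target* atom's group (the ligand is one
body), giving the per-nucleotide electrostatic/vdW decomposition; totals
are exact sums of the per-group entries. Cumulative series sum the
per-group values frame by frame.

## The built-in engine

Units: Å, ps, kcal/mol, amu, elementary charge; 1 kcal/mol =
418.4 amu·Å²/ps², k_B = 0.0019872041 kcal/(mol·K). The integrator is BAOAB
Langevin (velocity half-kick, half-drift, exact Ornstein–Uhlenbeck step,
half-drift, half-kick) at 310 K with friction 1 ps⁻¹ by default. Forces are
the exact negative gradient of the energetics above, plus intra-ligand
harmonic bonds (the ligand has no rigid-body treatment) and, in
`restrained` target mode, harmonic positional restraints
(1 kcal·mol⁻¹·Å⁻² by default) tethering target atoms to reference
coordinates. The default target mode is `fixed` (target atoms never move);
full target flexibility is out of scope. Overlapping atoms (r → 0) raise
an integration error naming the pair and step.

Determinism is a contract, not an accident: the RNG stream lives *in the
state* (a serialized PCG64 token), so advancing is a pure function of
(state, steps, config), and a recorded manifest (master seed + per-replica
seeds + config snapshot) replays any run or campaign bit-identically. The
inner kernel is JIT-compiled (numba) with all noise pre-drawn from the
state's generator, which keeps the arithmetic identical to a pure-numpy
evaluation order per chunk.

`dt` defaults to 0.05 ps. This is a stability choice: the steepest
curvature the fixture systems reach (the LJ repulsive core at the pocket
contact distance, with 100–300 amu beads) makes 0.05 comfortably stable
while 0.2 is not. The friction default follows the thermostat convention
(1 ps⁻¹); the synthetic-fixture conditions override it (below).

A scripted `MockEngine` satisfies the same contract by translating the
ligand along a prescribed per-segment displacement schedule; the
supervision loop is tested against both engines.

## The synthetic systems

`make_system` builds a rigid helical lattice of target beads (36 beads,
radius 9 Å, pitch 6 Å, 3 turns by default), one bead per group — a
caricature of one nucleotide per bead. Backbone beads carry −1 e
(polyanionic backbone); a contiguous arc of 5 beads around turn 1.5 forms
the cleft: uncharged, with a deeper LJ well (ε = 1.2 vs 0.1 kcal/mol), so
electrostatic steering and vdW-dominated binding are independently tunable.
The ligand is a 3-bead chain (100 amu/bead, bonds r₀ = 2 Å,
k = 5 kcal·mol⁻¹·Å⁻²) with net charge +1 spread uniformly.

The bound reference pose is the local interaction-energy minimum reached by
deterministic rigid-translation descent (step-halving gradient descent,
tolerance 10⁻⁶ kcal/mol) seeded at the cleft centroid, with a deterministic
fallback start just outside the bead shell if the centroid descent stalls
in the repulsive core; no global search is claimed. The unbound start
places the ligand COM exactly 30 Å from the site COM along the cleft's
outward radial normal — beyond the 9 Å nonbonded cutoff, so the early
dynamics is pure diffusion and supervision (not force bias) must produce
the approach.

Fixture engine conditions ("standard funnel"): 310 K, friction 10 ps⁻¹,
dt 0.05, fixed target. The higher friction is the implicit-solvent drag
appropriate to whole-nucleotide-scale beads; it sets the ligand COM
diffusion so that one 600-unit segment moves the COM by roughly one
segment-scale step (σ ≈ 10 Å per coordinate), which is the regime the
supervision rule is designed for.

What the generator deliberately does **not** emulate: real RNA geometry,
base pairing and sequence effects, conformational change of the target
upon binding, explicit water and ions, and rugged energy landscapes with
competing metastable sites. Passing tests on these fixtures therefore
demonstrate the correctness of the supervision logic, energetics,
integrator contracts and analyses — not force-field accuracy or predictive
power on real complexes.

## The benchmark

`benchmark_supervision` pairs, seed for seed, one supervised and one
unbiased run from the identical unbound start, sharing the engine, the
distance-sampling stride and the engine-step budget (`max_segments` worth
of segments). The endpoint is the engine-step count at the first sampled
distance below the switch-off threshold; runs that never get there report
exactly the budget (right-censoring). Because censoring replaces a larger
unknown value with the budget, the reported supervised/unbiased median
ratio is an upper bound on the true ratio — censoring can only make the
comparison *less* favourable to supervision. Under the standard conditions
(20 pairs) every supervised replica binds and the median ratio is ~0.02.

## Analyses

* **Superposition**: Kabsch via SVD with a determinant correction, always a
  proper rotation; degenerate (collinear) fit selections raise. The fit
  selection defaults to target atoms named "P" (nucleic backbone
  phosphates), falling back to all target atoms for bead fixtures.
* **Ligand RMSD**: each frame is superposed on the reference's target fit
  selection, then the ligand heavy-atom RMSD is measured without
  re-fitting. Multi-model references (NMR ensembles) yield per-model series
  and the per-frame minimum. Hydrogens are excluded by default.
* **Target RMSD**: fit and measurement on the same selection, reference
  defaulting to the first trajectory frame; an unfitted variant
  (`superpose=False`) reports raw deviation.
* **Contacts**: a target group is contacted in a frame iff any of its atoms
  lies within the cutoff (default 4 Å) of any ligand atom; the per-group
  frequency over frames ranks the "most contacted" groups, ties by group
  id. Frames are weighted equally.
* **Landscape**: a 2-D histogram over (COM distance, interaction energy)
  with per-bin frame counts and mean energies; empty bins carry NaN,
  distinct from a genuine zero mean, and counts always sum to the frame
  count (outliers are clipped into the outer bins rather than dropped).
* Dynamic-energy panels are emitted raw per frame; an optional centered
  moving average (`moving_average`, shrinking windows at the edges) is the
  only smoothing provided.

## Numerical and interface choices

* PDB I/O follows the wwPDB v3.3 fixed-column ATOM/HETATM layout;
  occupancy/B-factor are ignored on read and written as 1.00/0.00. Group
  identity is (chain, residue number); insertion codes are rejected.
  Multi-MODEL files yield one coordinate set per model; downstream
  consumers default to model 1 (energy-based model selection across an NMR
  ensemble is not re-implemented).
* Parameter tables are TSV keyed by (group_name, atom_name) with `*`
  wildcards; precedence exact > (group, \*) > (\*, atom) > (\*, \*), and
  unmatched atoms are an error listing them.
* Configuration is flat YAML with defaults mirroring the protocol values
  (600 / 20 / 5 Å / 20 / 4 Å / 9 Å / 310 K / 1 ps⁻¹); unknown keys and
  mistyped values are rejected by name, and defaulting is idempotent.
* Problem sizes in the shipped tests and acceptance script (39-atom
  fixture, 20 benchmark pairs, 3-replica campaign, 2000-sample thermostat
  average) are chosen so the whole protocol is exercised end to end at
  interactive cost on one CPU.

## Known limitations

* The energy model has no solvation term beyond dielectric + Debye
  screening, no PME, and no bonded terms for the target; absolute energies
  are not comparable to MMGBSA values.
* Supervision assumes a single ligand and a single site; re-supervision
  after drift, unbinding protocols and selectivity screens are out of
  scope.
* The distance slope is a 1-D criterion: on rugged landscapes it can trap
  the ligand at non-productive surface sites; the explicit attempt budget
  surfaces this as `attempt_budget_exhausted` instead of hiding it.
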