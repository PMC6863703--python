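# Methods

## Problem and model

`hbnetforge` designs *connected* enzyme active sites. The input is a 2D
"wiring diagram": a list of catalytic side-chain functional groups
(hydroxyl, phenol, carboxylate, carboxamide, imidazole, guanidinium,
primary amine) together with the hydrogen bonds and partial covalent bonds
they are required to make — with a ligand or transition-state model, and
with each other. The output is (i) the set of all 3D arrangements of those
groups, at a controlled resolution, in which **every** specified
interaction is geometrically realized (network configurations), and (ii)
placements of those networks into protein scaffold backbones, with a
verdict on whether the placed geometry still realizes the full
connectivity (completeness).

The chain of stages is:

1. **Enumerate** — for each group, all rigid poses of its functional-group
   template that realize the group's ligand interaction, deduplicated on a
   grid.
2. **Filter/assemble** — pairwise tables of placements that realize each
   group–group hydrogen bond, then a backtracking assembly of one placement
   per group satisfying every edge without steric clashes.
3. **Realize** — inverse rotamers: each placement is expanded backward into
   a full side chain with a backbone anchor frame (N, CA, C).
4. **Cluster** — k-means on the concatenated central-atom coordinates of
   each network, to control side-chain remixing during matching.
5. **Match** — rigid-transform hashing of (scaffold position, rotamer)
   pairs into 6-D ligand-pose bins; a match is a bin populated by every
   group at pairwise-distinct positions. Four modes: `residue` (each
   group independent of the network structure), `pooled` (all networks'
   rotamers in one calculation), `clustered` (one calculation per cluster),
   and `per_network` (one calculation per network).
6. **Report** — per-stage counts and a completion table (incomplete /
   complete / completion rate).

## Hydrogen-bond model

A bond between donor heavy atom D (with hydrogen H) and acceptor heavy
atom A (with lone-pair base atom(s) B) is accepted when

- `d_min <= |D-A| <= d_max` (defaults 2.6–3.2 Å),
- donor angle D–H···A >= `theta_min` (default 120°),
- acceptor angle B–A···H >= `psi_min` (default 90°, best over equivalent
  bases).

These thresholds are conventional structural-biology values and are
config-overridable; the method itself only needs *some* geometric
definition of "the hydrogen bond is present". The score of an accepted
bond is `-f(d)·f(theta)` with linear ramps peaking at 2.8 Å / 180° and
vanishing on the window boundary; it is used only to rank placements and
networks (lowest total score first), never as a physical energy. Window
comparisons carry a guard band of 1e-6 Å / 1e-4° so that poses sampled
exactly on a boundary survive round-trips through a rigid transform.

## Enumeration and the grid

A hydrogen-bonded pose of a rigid functional group has six continuous
degrees of freedom, parameterized as: donor–acceptor distance, donor
angle, acceptor angle, torsion about the acceptor–base axis, torsion about
the hydrogen-bond axis, and a spin of the group about its own interacting
bond. Each is sampled on a ladder; the default ladders are

| DOF | default | count |
|---|---|---|
| distance | 2.6–3.2 Å, step 0.1 | 7 |
| donor angle | 120–180°, step 15 | 5 |
| acceptor angle | 90–180°, step 10 | 10 |
| base torsion | 0–350°, step 10 | 36 |
| H-bond-axis torsion | 0–340°, step 20 | 18 |
| spin | 0–340°, step 20 | 18 |

Every sampled pose is audited against the hydrogen-bond test and a clash
pre-filter (any group heavy atom within 2.7 Å of a ligand heavy atom,
excluding the interacting pair, rejects the pose). Survivors are
deduplicated on a grid: the group's central heavy atom position, expressed
in the ligand's local frame, is quantized at the grid spacing `g`
(default 0.2 Å; rounding is half-away-from-zero), and only the
best-scoring pose per cell is kept (first seen wins ties). Covalent
attachments fix bond length (1.5 Å) and angle (109.5°) at ideal values and
sample only the torsion about the ligand substituent axis plus the group
spin; the displaced hydrogen of the nucleophile is dropped from the pose.

Two consequences of the single-reference-atom grid key are deliberate:
counts are controlled by the grid (refining the sampling ladders converges
instead of exploding), and the default ladders were chosen so that one
donor–acceptor interaction at `g = 0.2 Å` resolves to ~1.3×10³ unique
placements — the expected order of magnitude for a production grid. The
retained orientation per cell is canonical (the deterministic tie rule),
which trades some orientational diversity for exact reproducibility.

All enumeration happens in a canonical ligand frame: inputs are
re-expressed in the frame of their own first three non-collinear atoms and
rounded to 1e-6 Å. Scaffolds are likewise canonicalized to their first
residue's backbone frame before matching. This makes every downstream
count exactly invariant under rigid motions of the inputs — the property
the acceptance suite asserts as bit-identical summaries.

## Assembly

For each group–group edge, all placement pairs within `d_max` (found with
a k-d tree, equivalent to an all-pairs scan) are tested against the
hydrogen-bond criteria over all role-compatible atom options; "auto" ends
try every donor pair / acceptor atom of the template. Assembly then
backtracks over groups in specification order, candidate placements in
ascending score order, enforcing pair-table membership and an inter-group
clash check (heavy–heavy < 2.7 Å rejects, with the edge's own
donor–acceptor pair exempted). Networks are emitted sorted by total score
and truncated at a cap (default 2×10⁶) with a logged warning.

Groups must interact with the ligand directly; a group whose only edges
are to other groups (a "second-shell" group) is rejected with an explicit
error, since enumeration is defined against ligand sites.

## Inverse rotamers

Side chains are grown backward from the fixed functional group using ideal
bond lengths and angles in a per-identity z-matrix. Every rotatable bond —
including the final torsion that places N and C around CA — is sampled from
the same ladder (default staggered -60/60/180), so a Ser hydroxyl with its
two rotatable bonds yields at most 9 realizations. Chain atoms that clash
with the ligand (< 2.7 Å heavy–heavy, ignoring atoms bonded to a covalent
attachment) reject the rotamer. The functional-group atoms are never
rebuilt, so realizations reproduce their parent placement exactly. The
carbonyl O is added for export; its orientation is a fixed convention.

The product rule follows directly: the number of full side-chain
realizations of a network is the product over its groups of per-group
rotamer counts, and the suite verifies this against direct enumeration.

## Matching

Superposing a realization's backbone frame onto a scaffold residue implies
a unique rigid ligand pose relative to the scaffold. Poses are binned:
translation cells of 1.0 Å (floor) and orientation cells built from the
sign-canonicalized quaternion quantized at half the angular bin width
(default 10°); "fine" bins (0.25 Å / 2.5°) are used when a mode must not
blur distinct networks together. Entries whose side chain hits the
scaffold backbone (outside the host residue ±2 neighbors on the same
chain) are excluded; per bin, at most `per_bin_cap` best-scoring entries
per group are kept (pruning, default 100; 0 disables). A candidate match
is a bin containing entries for every group at pairwise-distinct
positions; each combination (bounded by a per-bin rebuild cap, default
1000) is rebuilt in full coordinates, checked for ligand–backbone and
side-chain–side-chain clashes, and every specification edge is
re-evaluated in the placed geometry. Covalent edges are checked by a
1.2–1.8 Å bond-length window. A match is *complete* iff every edge passes.
Results are deduplicated on (scaffold, ligand bin, position set).

The completion report prints, per simulation, the number of incomplete
matches, the number of complete matches, and the completion rate — the
ratio of complete matches to the first column, formatted with three
decimals below 0.1% and two otherwise.

## Synthetic fixtures and what they do (not) show

The toy ligands (a vicinal diol, a ketone bearing a phosphate, a
carbinolamine tetrahedral intermediate) are hand-built minimal molecules
with ideal internal coordinates and annotated donor/acceptor/covalent
sites. They are chemically sensible but are **not** quantum-chemical
transition-state models, and the ideal helix / planted-segment scaffolds
are not real protein folds: passing tests demonstrate the combinatorial
and geometric machinery (completeness, equivalence with brute force,
planted-network recovery, invariances), not catalytic competence or
performance on crystallographic scaffold libraries. In particular the
absolute match counts on these fixtures have no biological meaning.

Planted scaffolds place one ideal extended 5-residue segment per group
with the central residue carrying the rotamer's anchor frame exactly, and
are rejected at construction if segments approach each other, another
group's side chain, or the ligand within 3.2 Å — comfortably above the
matcher's 2.8 Å backbone-clash threshold, so recovery is never blocked by
the clash filter.

## Problem sizes used by the test suite and acceptance script

The suite runs the two-group phosphate-bridge system at a 0.5 Å grid with
mid-density ladders (~10²–10³ placements per interaction, a few hundred
networks), 20 seeded planted scaffolds for recovery, and a single
full-density enumeration at 0.2 Å for the placement-count check. These
sizes keep a complete run at desk scale while exercising every stage at
meaningful combinatorial depth.

## Known limitations

- Second-shell groups (no direct ligand edge) are not enumerable.
- Water-mediated bridges are not modeled.
- One orientation per grid cell survives deduplication; orientational
  fine structure below the grid resolution is intentionally discarded.
- Hydrogen-bond thresholds and the ranking score are conventions, not
  fitted physics; both are exposed in the configuration.
- Scaffold residues are treated as pure backbone hosts (native identity
  ignored, no design step).
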