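# hbnetforge

Computational enzyme design tools for building **hydrogen-bond-connected
active sites**. Classic active-site matching places each catalytic side
chain by its geometry relative to the reaction transition state alone, so
the catalytic residues rarely interact with one another. `hbnetforge`
starts instead from a 2D "wiring diagram" — which side-chain functional
groups hydrogen-bond (or covalently bond) to which ligand sites *and to
each other* — and enumerates every 3D realization of the full connected
network before ever looking at a protein scaffold.

Who it is for: protein designers and structural bioinformaticians who want
pre-organized catalytic constellations (serine/tyrosine/lysine/asparagine
quartets and the like) as geometric targets for scaffold matching.

## Method in brief

For a ligand **L** with annotated donor/acceptor/covalent sites and groups
*G₁…G_n* with required interactions *E* (ligand–group and group–group):

1. **Placement enumeration.** For each ligand edge, sample the hydrogen
   bond's six degrees of freedom (distance *d* ∈ [2.6, 3.2] Å, donor angle
   θ(D–H···A) ≥ 120°, acceptor angle ψ(B–A···H) ≥ 90°, two torsions, one
   group spin) on dense ladders; keep poses that pass the H-bond test and
   a 2.7 Å clash pre-filter; deduplicate on a grid of spacing *g* (default
   0.2 Å) over the group's central atom in the ligand frame. One
   interaction typically resolves to ~10³ placements at *g* = 0.2 Å.
2. **Network assembly.** For each group–group edge, tabulate all placement
   pairs that realize the bond; backtracking assembly then emits every
   clash-free assignment of one placement per group satisfying all of *E*
   — the *network configurations* — ranked by the sum of edge scores
   −f(d)·f(θ).
3. **Inverse rotamers.** Each placement grows backward into full side
   chains (staggered χ sampling) with backbone anchor frames; the number
   of full 3D realizations of a network is the product over groups of its
   rotamer counts.
4. **Scaffold matching.** Superposing a rotamer's anchor frame onto a
   scaffold residue implies a ligand pose; poses are hashed into 6-D bins
   (1 Å translation / 10° orientation by default). A bin populated by all
   groups at distinct positions is a match; it is *complete* when every
   edge of the wiring diagram is realized in the placed geometry. Modes:
   `residue` (network-blind), `pooled`, `clustered` (k-means on central
   functional-group coordinates, k ≈ 250 at production scale), and
   `per_network`.

See `docs/methods.md` for the full model, defaults, and limitations.

## Worked example

The built-in `phosphate_bridge` system asks a carboxamide (Asn-like) and a
hydroxyl (Ser-like) to donate to two phosphate oxygens of a toy
keto-phosphate ligand while also hydrogen-bonding to each other:

```python
from hbnetforge.fixtures import make_toy_ligand, make_demo_spec
from hbnetforge.reporting import RunConfig, run_pipeline, summarize_counts

lig = make_toy_ligand("keto_phosphate")
spec = make_demo_spec("phosphate_bridge", lig)
summary = run_pipeline(cfg, lig, spec, [scaffold])   # cfg: mid-density scheme,
text, tsv = summarize_counts(summary)                # scaffold: planted fixture
print(text)
```

prints

```
ligand: keto_phosphate   spec: phosphate_bridge
placements[N1]: 1142
placements[S1]: 133
compatible pairs[e_n1_s1]: 291
complete networks: 291
full side-chain realizations (product rule over 5 networks): 264
clusters: 3 (requested 3)
match[per_network]: 1 matches, 1 complete, rate n/a
```

Reading: 1142 grid-unique poses of the carboxamide realize its phosphate
hydrogen bond (133 for the hydroxyl); 291 of the 1142×133 combinations
also realize the amide→hydroxyl bond without clashing — those are the
complete two-residue networks. The five best networks expand to 264 full
side-chain realizations by the product rule. Matching each network
individually into a scaffold that was built to host one of them finds
exactly that network back, fully connected (the rate column divides
complete by incomplete matches, table-style, and prints `n/a` when there
are no incomplete ones).

The same stages are scriptable from a shell:

```bash
hbnetforge fixtures --name diol --out fixtures/
hbnetforge enumerate --ligand fixtures/diol.pdb --spec site.yaml --grid 0.2 --out placements.json
hbnetforge run --config run.yaml --ligand fixtures/diol.pdb --spec site.yaml --out results/
```

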