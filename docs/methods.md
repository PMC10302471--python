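# Methods

## Monomers and the placeholder convention

Every structure is handled as a molecular graph with **explicit hydrogens**
(materialized on load from any format). This makes the conservation
arithmetic exact and gives the torsion enumerator a complete neighbour
list. A monomer designates one element as its placeholder; the element is a
parameter, never hardcoded, since any rare-in-context element works (Br and
Pt in the bundled catalog). Validation requires at least one placeholder
atom and that each one has exactly one neighbour — a placeholder stands in
for the single substituent displaced when the inter-monomer bond forms.

The new bond formed by a join is always **single order**. Aromaticity is
re-perceived (RDKit sanitization) after every edit, so joining two aromatic
rings or capping a placeholder on an aromatic carbon yields a valid
kekulizable molecule. Stereochemistry is not propagated through joins.

Every graph edit (join, ring closure, capping) returns or preserves 0-based
contiguous indices; joins return old→new index maps for both operands so
callers can track sites and bonds through re-compaction. The random-ring
test generator relies on exactly this to carry ground-truth linker bonds
through an arbitrary number of edits.

## Builders

All chain builders share one assembly loop: each distinct monomer is
embedded once (ETKDGv3, fixed seed), copy *i* is translated by `i·shift`
along the x axis, and copies are merged tail(i)↔head(i+1), where the head
of a two-site monomer is its lower-index placeholder. This head/tail rule
makes every build deterministic without user input. After merging, leftover
placeholders are capped with hydrogen (linear/branched/patterned) or
consumed by one extra bond (ring), and the product is minimized.

Parameters that matter:

- `shift` (Å, default 3.0): pre-merge spacing between copies. The value
  only sets the initial geometry; minimization removes its influence on
  topology entirely. 3 Å keeps small aromatic monomers from overlapping
  while leaving the new bond short enough for the force field to contract.
- `ff_iterations` (default 400): minimization steps. 0 skips relaxation
  and returns assembly coordinates untouched — useful when only the
  topology matters.
- `force_field` (`MMFF`|`UFF`, default MMFF): MMFF94 is the better choice
  for organic backbones; when it cannot type an atom (e.g. boron) the
  builder warns and falls back to UFF, which covers the periodic table.
  Minimization happens after capping, on the final chemical species.
- `seed`: drives random sequence generation and, when set, the embedding.

Random copolymers are count-exact rather than Bernoulli-per-position: the
composition n_A = round(p_A·ℓ) (round half up) is fixed first and the
multiset is shuffled uniformly (seeded). The two readings differ — a
per-position draw would give binomially distributed composition — and the
count-exact one is adopted because the composition is specified as a
product p·ℓ, not as an accept/reject rate. For three-monomer chains,
half-up rounding of both p_A·ℓ and p_B·ℓ can overshoot ℓ by one unit in
edge cases (e.g. ℓ=1, p_A=p_B=0.5); the later blocks absorb the
correction so the counts always sum to ℓ.

Ring closure requires length ≥ 3: with two units the closure bond would
duplicate an existing bond (a two-membered bridge), which the graph model
rejects. Builders compose: `linear_chain`/`patterned_chain`/`diblock_chain`
return *uncapped* oligomers that are themselves valid monomers, so a
diblock chain can be closed into a copolymer ring and a partially-capped
oligomer can serve as the arm of a branched polymer. A branched build
attaches one arm per core placeholder (arms must carry exactly one
placeholder and the same placeholder element as the core; differing
elements are rejected rather than silently cross-matched).

`unique_pattern_permutations` enumerates distinct multiset permutations
(SymPy's multiset enumerator), not all ℓ! orderings, so repeated letters
collapse correctly.

## Torsion detection

A linker bond is defined as *a bond in no SSSR ring whose two endpoints
both lie in at least one SSSR ring*. The alternative degree-based
criterion (backbone atom with three intra-unit neighbours plus one
inter-unit neighbour) over-constrains once hydrogens are explicit and
misfires inside fused aromatics; the ring-exclusion form is equivalent for
planar conjugated backbones and strictly more robust. Torsion quadruples
a–b–c–d take every neighbour a of b (≠c) against every neighbour d of c
(≠b); hydrogens are excluded by default, matching the heavy-atom convention
of dihedral scans, giving (deg_heavy(b)−1)·(deg_heavy(c)−1) quadruples per
linker bond. Quadruples are stored with b < c so reversals are never
double-counted. Sketches are SVG with all atom indices printed and the
four torsion atoms highlighted; the filename encodes the quadruple.

Only identification is in scope: the package does not run dihedral scans or
fit force-field terms, and it does not measure 3D angle values.

## High-throughput utilities

Unique directories use 128-bit random hex names (collision probability
~2⁻¹²⁸; the impossible collision is retried). File relocation is
non-recursive by design — only files directly under the root move, each
into its own fresh directory, and the returned mapping is a bijection.
Dispatch uses a thread pool with per-task error capture: a failing task
records its exception in its own result slot and never aborts siblings,
and results stay positionally aligned with tasks regardless of worker
count. External calculator commands (xtb with GFN2 or GFN-FF flags, or a
python driver for SCF work) are assembled as argv lists and never executed,
so whole workflows validate on machines without quantum-chemistry binaries.

## Synthetic test inputs

The fixture catalog contains the small monomers a polymer-builder exercise
actually needs — 2,5-dibromofuran/-thiophene/-pyrrole, 1,4-dibromobenzene,
a dibromosilanediol, a four-placeholder ethylenediamine core (one site per
amine hydrogen), a single-site benzene arm, and a Pt-decorated furan —
each parsed from a SMILES literal and validated on construction.
`random_ring_assembly` grows random trees of aromatic rings joined by
acyclic single bonds and returns the formed bonds as ground truth, giving
the linker-bond detector an oracle that is constructed rather than
re-derived. These fixtures are topologically realistic but deliberately
small (≤ 8 rings, ≤ ~40 heavy atoms); passing tests demonstrate
correctness of graph assembly, composition statistics and torsion
identification, not conformational realism of large macromolecules,
polydispersity, or packing behaviour.

## Numerical choices and problem sizes

Distance-geometry embedding uses a fixed seed (1789) unless the build seed
is given, so identical calls produce identical coordinates. Energy
assertions allow 1e-6 kcal/mol slack for minimizer round-off.
Property suites run at deliberately small sizes — chains of ≤ 8 units, 100
randomized conservation builds, 50 random ring assemblies, the full
p×ℓ grid up to ℓ=20 with relaxation disabled — sizes at which every
identity checked is already fully exercised, since the identities are
exact graph invariants independent of scale.

## Known limitations

- No packing into simulation cells and no MD force-field topology export.
- One level of branching (core + arms); dendrimer generations require
  composing builds manually.
- PDB input carries no bond orders; orders are taken as perceived by the
  reader. XYZ bond perception assumes neutral molecules.
- Stereochemistry and tautomer state are not preserved through joins.
- Ring-closure geometry for long chains starts far from closed; the
  closure is topologically exact but may need more minimization steps than
  the default to look relaxed.
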