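# polyforge

Building molecular models of polymers is routinely the most tedious part of
a polymer simulation or materials-screening workflow: a monomer is easy to
draw, but a hundred-atom branched copolymer with sensible 3D coordinates is
not. `polyforge` automates that step. Starting from monomers decorated with
**placeholder atoms** (any element — Br and Pt are conventional) that mark
the polymerization sites, it assembles polymers with linear, ring and
branched topologies and homopolymer, diblock, random or fully
pattern-specified compositions, relaxes the result with a classical force
field, and hands back a clean molecular graph in standard formats.

It is aimed at computational chemists and soft-matter researchers who need
many polymer models quickly — for force-field work, semiempirical or *ab
initio* screening, or database generation — rather than one hand-crafted
structure.

## The model

A monomer is a molecular graph *M* with explicit hydrogens plus a designated
placeholder element X; every X atom has exactly one neighbour. Joining two
monomers deletes one X from each and bonds their former neighbours with a
single bond, so for a chain of *n* units:

- atoms: |A| = n·A_mon − 2(n−1)  bonds: |B| = n·B_mon − (n−1)
- ring closure consumes the two terminal placeholders instead of capping
  them, giving |A| = n·(A_mon − 2), |B| = n·(B_mon − 1) and raising the
  cyclomatic number (|B| − |A| + components) by exactly one;
- placeholders that survive a build are rewritten to hydrogen.

Random copolymers are **count-exact**: a chain of length ℓ contains exactly
round(p_A·ℓ) units of A (round half up), the remainder B (and C), in a
seeded uniform shuffle of that multiset. Coordinates come from laying
monomer copies along an axis with a fixed per-copy shift, merging, and
minimizing with MMFF94 or UFF (with automatic fallback when atom typing
fails).

For conjugated polymers, `polyforge` also identifies the inter-ring
torsions that classical force fields describe poorly: a **linker bond** is
a bond outside every SSSR ring whose two atoms both lie in rings, and the
reported dihedrals a–b–c–d are all heavy-atom quadruples having a linker
bond b–c as central bond — the inputs one needs to set up dihedral-scan
reparametrizations.

## Worked example

```python
import polyforge as pf

furan = pf.load_monomer("Brc1ccc(Br)o1", "Br")   # 2,5-dibromofuran
poly = pf.linear_polymer(furan, 5)                # pentamer, MMFF-relaxed

print(poly.graph.n_atoms)                         # 37
print(poly.sequence)                              # ('A', 'A', 'A', 'A', 'A')
print(len(pf.detect_linker_bonds(poly.graph)))    # 4

ring = pf.ring_polymer(furan, 5)
print(ring.graph.cyclomatic_number())             # 6  (5 furan rings + 1 macrocycle)
```

The pentamer has 37 atoms (5×9 decorated-monomer atoms minus the 8
placeholders consumed by 4 joins; the 2 terminal Br become H), its four
inter-ring bonds are exactly the torsion centres a dihedral scan would
target, and the ring polymer gains precisely one macrocycle over the open
chain.

The same builders are available from the shell:

```bash
polyforge build linear -m "Brc1ccc(Br)o1" --n 5 --out pentamer.mol
polyforge torsions --in "c1ccc(-c2ccccc2)cc1" --json
polyforge htc organize --ext smi --root ./batch
```

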