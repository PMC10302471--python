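"""Inter-ring torsion detection for conjugated polymers.

The dihedrals about the single bonds that link aromatic subunits along a
conjugated backbone are poorly described by stock classical force fields, so
identifying them is the first step of any reparametrization workflow.  A
*linker bond* is a bond that is not itself a member of any ring (SSSR basis)
but whose two end atoms both belong to rings; the torsions of interest are
all quadruples a–b–c–d having a linker bond b–c as their central bond.

Quadruples are stored canonically with ``b < c`` so a torsion and its
reversal are never reported twice; hydrogens are excluded from the outer
positions unless requested, matching the heavy-atom convention of dihedral
scans.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

from rdkit.Chem import AllChem, Draw
from rdkit.Chem.Draw import rdMolDraw2D

from .chem_graph import MolecularGraph


class LinkerBond(NamedTuple):
    """An acyclic bond whose two endpoints both belong to rings."""

    atom_i: int
    atom_j: int


class TorsionQuadruple(NamedTuple):
    """Four atom indices a–b–c–d; the central bond b–c is a linker bond."""

    a: int
    b: int
    c: int
    d: int


def _ring_membership(g: MolecularGraph) -> tuple[set[int], set[frozenset]]:
    """Atoms-in-ring and bonds-in-ring from the SSSR ring basis."""
    mol = g.to_rdkit()
    info = mol.GetRingInfo()
    ring_atoms = {i for ring in info.AtomRings() for i in ring}
    ring_bonds = set()
    for ring in info.BondRings():
        for bidx in ring:
            b = mol.GetBondWithIdx(bidx)
            ring_bonds.add(
                frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            )
    return ring_atoms, ring_bonds


def detect_linker_bonds(g: MolecularGraph) -> list[LinkerBond]:
    """All ring-to-ring connecting bonds, sorted by (i, j).

    A qualifying bond lies in no SSSR ring while both of its atoms lie in at
    least one; this is exactly the inter-subunit backbone bond of a
    conjugated polymer.  Acyclic and single-ring molecules yield an empty
    list.
    """
    ring_atoms, ring_bonds = _ring_membership(g)
    out = []
    for i, j, _ in g.bonds:
        if frozenset((i, j)) in ring_bonds:
            continue
        if i in ring_atoms and j in ring_atoms:
            out.append(LinkerBond(i, j))
    return sorted(out)


def enumerate_torsions(
    g: MolecularGraph,
    bonds: Iterable[LinkerBond] | None = None,
    include_h: bool = False,
) -> list[TorsionQuadruple]:
    """All torsion quadruples whose central bond is a linker bond.

    For each linker bond b–c, every neighbor a of b (a ≠ c) is combined with
    every neighbor d of c (d ≠ b).  Hydrogens are skipped at the outer
    positions unless ``include_h``; the count per bond is then
    ``(heavy_deg(b) − 1)·(heavy_deg(c) − 1)``.
    """
    if bonds is None:
        bonds = detect_linker_bonds(g)

    def outer(center: int, excluded: int) -> list[int]:
        return [
            n
            for n in g.neighbors(center)
            if n != excluded and (include_h or g.elements[n] != "H")
        ]

    out = []
    for bond in bonds:
        b, c = sorted(bond)
        for a in outer(b, c):
            for d in outer(c, b):
                out.append(TorsionQuadruple(a, b, c, d))
    return sorted(out, key=lambda t: (t.b, t.c, t.a, t.d))


def render_torsion_sketches(
    g: MolecularGraph,
    torsions: Iterable[TorsionQuadruple],
    outdir: str | Path,
) -> list[Path]:
    """Write one 2D sketch (SVG) per torsion, the four atoms highlighted and
    every atom labeled with its index.

    Filenames encode the quadruple (``torsion_a-b-c-d.svg``) so a sketch can
    be traced back to its atom indices.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol = g.to_rdkit()
    mol.RemoveAllConformers()
    AllChem.Compute2DCoords(mol)
    written = []
    for t in torsions:
        drawer = rdMolDraw2D.MolDraw2DSVG(500, 400)
        opts = drawer.drawOptions()
        opts.addAtomIndices = True
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol, highlightAtoms=list(t)
        )
        drawer.FinishDrawing()
        path = outdir / f"torsion_{t.a}-{t.b}-{t.c}-{t.d}.svg"
        path.write_text(drawer.GetDrawingText())
        written.append(path)
    return written


def parse_sketch_filename(path: str | Path) -> TorsionQuadruple:
    """Recover the quadruple encoded in a sketch filename."""
    stem = Path(path).stem
    a, b, c, d = (int(x) for x in stem.removeprefix("torsion_").split("-"))
    return TorsionQuadruple(a, b, c, d)
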