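"""Molecular-graph data model and placeholder-atom primitives.

A polymer is assembled from *monomers*: small molecules decorated with
placeholder atoms (any element — Br and Pt are conventional) that mark where
inter-monomer bonds form.  Each placeholder is bonded to exactly one real
atom; joining two monomers deletes one placeholder from each and bonds their
former neighbours, so the placeholder stands in for the substituent that the
polymerization reaction would displace.  Placeholders that survive a build
are rewritten to hydrogen.

The in-memory representation is :class:`MolecularGraph`, a plain
element/bond/coordinate container that converts losslessly to and from RDKit
molecules.  All chemistry (sanitization, aromaticity perception, ring
perception, file formats) is delegated to RDKit; the graph edits themselves
(join, ring closure, capping) are performed here so that atom-index
provenance can be tracked exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDetermineBonds

from .exceptions import (
    DecorationError,
    ParseError,
    StructureError,
)

RDLogger.DisableLog("rdApp.*")

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_TO_RDKIT_ORDER = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_FROM_RDKIT_ORDER = {v: k for k, v in _TO_RDKIT_ORDER.items()}


def _normalize_bond(i: int, j: int, order: str) -> tuple[int, int, str]:
    if order not in BOND_ORDERS:
        raise StructureError(f"unsupported bond order {order!r}")
    if i == j:
        raise StructureError(f"self-bond on atom {i}")
    return (i, j, order) if i < j else (j, i, order)


@dataclass(frozen=True)
class MolecularGraph:
    """Atoms-as-nodes, covalent-bonds-as-edges molecule representation.

    Parameters
    ----------
    elements :
        Element symbol per atom; indices are implicit, 0-based, contiguous.
    bonds :
        ``(i, j, order)`` triples with ``i < j`` and order one of
        ``single|double|triple|aromatic``.  No duplicates.
    formal_charges :
        Formal charge per atom (defaults to all zero).
    coords :
        Optional ``(n_atoms, 3)`` Cartesian coordinates in Å.
    """

    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]
    formal_charges: tuple[int, ...] = ()
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not self.formal_charges:
            object.__setattr__(self, "formal_charges", (0,) * n)
        if len(self.formal_charges) != n:
            raise StructureError("formal_charges length != atom count")
        norm = tuple(_normalize_bond(*b) for b in self.bonds)
        seen: set[tuple[int, int]] = set()
        for i, j, _ in norm:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i},{j}) references missing atom")
            if (i, j) in seen:
                raise StructureError(f"duplicate bond ({i},{j})")
            seen.add((i, j))
        object.__setattr__(self, "bonds", norm)
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (n, 3):
                raise StructureError(
                    f"coords shape {c.shape} != ({n}, 3)"
                )
            if not np.all(np.isfinite(c)):
                raise StructureError("coords contain non-finite values")
            c.setflags(write=False)
            object.__setattr__(self, "coords", c)

    # -- basic introspection ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        """Indices bonded to atom ``i``, ascending."""
        out = [b + a - i for a, b, _ in self.bonds if i in (a, b)]
        return sorted(out)

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def element_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e] = out.get(e, 0) + 1
        return out

    def n_components(self) -> int:
        parent = list(range(self.n_atoms))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, _ in self.bonds:
            parent[find(i)] = find(j)
        return len({find(i) for i in range(self.n_atoms)})

    def cyclomatic_number(self) -> int:
        """Number of independent cycles: E − V + components."""
        return self.n_bonds - self.n_atoms + self.n_components()

    # -- RDKit interchange --------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        charges = tuple(a.GetFormalCharge() for a in mol.GetAtoms())
        bonds = []
        for b in mol.GetBonds():
            order = _FROM_RDKIT_ORDER.get(b.GetBondType())
            if b.GetIsAromatic():
                order = "aromatic"
            if order is None:
                raise StructureError(
                    f"unsupported RDKit bond type {b.GetBondType()}"
                )
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        coords = None
        if mol.GetNumConformers():
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        return cls(elements, tuple(bonds), charges, coords)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule with all hydrogens explicit.

        Every atom is flagged ``NoImplicit`` so RDKit never adds hydrogens
        of its own; sanitization re-perceives aromaticity and validates
        valences.
        """
        rw = Chem.RWMol()
        for sym, q in zip(self.elements, self.formal_charges):
            atom = Chem.Atom(sym)
            atom.SetFormalCharge(int(q))
            atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), _TO_RDKIT_ORDER[order])
            if order == "aromatic":
                rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
                rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
                rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
        mol = rw.GetMol()
        if self.coords is not None:
            conf = Chem.Conformer(self.n_atoms)
            for idx, (x, y, z) in enumerate(self.coords):
                conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # pragma: no cover - rdkit msg varies
                raise StructureError(f"sanitization failed: {exc}") from exc
        return mol

    def with_coords(self, coords: np.ndarray) -> "MolecularGraph":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class Monomer:
    """A molecular graph plus the element that marks its polymerization sites.

    ``sequence`` is populated on oligomer chains that are reused as monomers
    (e.g. a diblock chain about to be closed into a ring) so backbone
    provenance survives module composition.
    """

    graph: MolecularGraph
    placeholder: str
    label: str = "A"
    sequence: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        sites = find_placeholders(self.graph, self.placeholder)
        if not sites:
            raise DecorationError(
                f"no {self.placeholder} placeholder atom present"
            )
        for s in sites:
            if self.graph.degree(s) != 1:
                raise DecorationError(
                    f"placeholder atom {s} has {self.graph.degree(s)} "
                    "neighbors; placeholders mark a single attachment site"
                )

    @property
    def sites(self) -> list[int]:
        """Ascending indices of this monomer's placeholder atoms."""
        return find_placeholders(self.graph, self.placeholder)


@dataclass(frozen=True)
class BuildConfig:
    """Build-wide knobs: force field, relaxation length, packing, seed.

    ``shift`` is the Å translation between consecutive monomer copies in the
    pre-merge placement; ``ff_iterations = 0`` skips relaxation entirely.
    """

    force_field: str = "MMFF"
    ff_iterations: int = 400
    shift: float = 3.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.force_field not in ("MMFF", "UFF"):
            raise StructureError(
                f"force_field must be MMFF or UFF, got {self.force_field!r}"
            )
        if self.ff_iterations < 0:
            raise StructureError("ff_iterations must be >= 0")
        if not self.shift > 0:
            raise StructureError("shift must be > 0 Å")


@dataclass(frozen=True)
class JoinResult:
    """Joined graph plus old→new index maps for both operands.

    Consumed placeholder atoms map to ``None``.
    """

    graph: MolecularGraph
    map_a: tuple[Optional[int], ...]
    map_b: tuple[Optional[int], ...]


# ---------------------------------------------------------------------------
# placeholder primitives
# ---------------------------------------------------------------------------


def find_placeholders(g: MolecularGraph, placeholder: str) -> list[int]:
    """Ascending indices of atoms whose element equals ``placeholder``."""
    return [i for i, e in enumerate(g.elements) if e == placeholder]


def _require_attachment_site(g: MolecularGraph, i: int, name: str) -> int:
    if not 0 <= i < g.n_atoms:
        raise StructureError(f"{name}={i} is not an atom index")
    nbrs = g.neighbors(i)
    if len(nbrs) != 1:
        raise StructureError(
            f"atom {i} ({g.elements[i]}) has {len(nbrs)} neighbors; a "
            "placeholder must have exactly one"
        )
    return nbrs[0]


def _compact(
    g: MolecularGraph,
    drop: set[int],
    extra_bonds: Iterable[tuple[int, int, str]] = (),
) -> tuple[MolecularGraph, tuple[Optional[int], ...]]:
    """Delete ``drop`` atoms, re-compact indices, optionally add bonds
    (given in *old* indices)."""
    amap: list[Optional[int]] = []
    nxt = 0
    for i in range(g.n_atoms):
        if i in drop:
            amap.append(None)
        else:
            amap.append(nxt)
            nxt += 1
    elements = tuple(e for i, e in enumerate(g.elements) if i not in drop)
    charges = tuple(q for i, q in enumerate(g.formal_charges) if i not in drop)
    bonds = [
        (amap[i], amap[j], o)
        for i, j, o in g.bonds
        if i not in drop and j not in drop
    ]
    for i, j, o in extra_bonds:
        bonds.append((amap[i], amap[j], o))
    coords = None
    if g.coords is not None:
        keep = [i for i in range(g.n_atoms) if i not in drop]
        coords = g.coords[keep]
    return (
        MolecularGraph(elements, tuple(bonds), charges, coords),
        tuple(amap),
    )


def join(
    ga: MolecularGraph, ia: int, gb: MolecularGraph, ib: int
) -> JoinResult:
    """Bond two graphs through a placeholder site on each.

    Both placeholder atoms are deleted and a new single-order bond is formed
    between their former neighbours.  Atom counts therefore obey
    ``|join| = |ga| + |gb| − 2`` and bond counts ``+ bonds − 1``.
    """
    na = _require_attachment_site(ga, ia, "ia")
    nb = _require_attachment_site(gb, ib, "ib")

    off = ga.n_atoms
    elements = ga.elements + gb.elements
    charges = ga.formal_charges + gb.formal_charges
    bonds = list(ga.bonds) + [(i + off, j + off, o) for i, j, o in gb.bonds]
    coords = None
    if ga.coords is not None and gb.coords is not None:
        coords = np.vstack([ga.coords, gb.coords])
    union = MolecularGraph(elements, tuple(bonds), charges, coords)
    merged, amap = _compact(
        union, {ia, ib + off}, [(na, nb + off, "single")]
    )
    return JoinResult(
        merged,
        amap[:off],
        tuple(amap[off:]),
    )


def close_ring(
    g: MolecularGraph, ia: int, ib: int
) -> tuple[MolecularGraph, tuple[Optional[int], ...]]:
    """Consume two placeholder sites of the *same* graph to close a cycle.

    Returns the closed graph and the old→new index map.
    """
    na = _require_attachment_site(g, ia, "ia")
    nb = _require_attachment_site(g, ib, "ib")
    if na == nb:
        raise StructureError("ring closure would bond an atom to itself")
    if any({i, j} == {na, nb} for i, j, _ in g.bonds):
        raise StructureError("ring closure endpoints are already bonded")
    return _compact(g, {ia, ib}, [(na, nb, "single")])


def cap_placeholders(
    g: MolecularGraph,
    placeholder: str,
    indices: Optional[Sequence[int]] = None,
) -> MolecularGraph:
    """Rewrite placeholder atoms to hydrogen.

    Topology, atom count and bond count are unchanged — caps convert atoms,
    they do not add them.  ``indices`` restricts capping to a subset of
    sites (used e.g. to turn one end of a chain into a terminus while the
    other stays reactive).
    """
    targets = set(
        find_placeholders(g, placeholder) if indices is None else indices
    )
    for t in targets:
        if g.elements[t] != placeholder:
            raise StructureError(
                f"atom {t} is {g.elements[t]}, not {placeholder}"
            )
    elements = tuple(
        "H" if i in targets else e for i, e in enumerate(g.elements)
    )
    charges = tuple(
        0 if i in targets else q for i, q in enumerate(g.formal_charges)
    )
    return replace(g, elements=elements, formal_charges=charges)


def validate_valence(g: MolecularGraph) -> None:
    """Raise :class:`StructureError` unless every atom's valence is legal."""
    g.to_rdkit(sanitize=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_EXT_FORMATS = {
    ".smi": "smiles",
    ".smiles": "smiles",
    ".mol": "mol",
    ".sdf": "mol",
    ".pdb": "pdb",
    ".xyz": "xyz",
}


def _infer_format(source: str | os.PathLike) -> str:
    ext = Path(source).suffix.lower()
    if ext in _EXT_FORMATS and Path(source).exists():
        return _EXT_FORMATS[ext]
    if isinstance(source, os.PathLike) or Path(str(source)).exists():
        raise ParseError(f"cannot infer format of {source}")
    # bare strings default to SMILES
    return "smiles"


def read_structure(
    source: str | os.PathLike, format: str = "auto"
) -> MolecularGraph:
    """Read a structure with explicit hydrogens materialized.

    ``format='auto'`` dispatches on file extension; bare strings are treated
    as SMILES.  Supported: SMILES, MDL MOL/SDF, PDB (HETATM records), XYZ
    (bonds perceived from geometry).
    """
    if format == "auto":
        format = _infer_format(source)
    mol: Optional[Chem.Mol] = None
    try:
        if format == "smiles":
            text = str(source)
            if Path(text).exists():
                text = Path(text).read_text().split()[0]
            mol = Chem.MolFromSmiles(text)
        elif format == "mol":
            mol = Chem.MolFromMolFile(str(source), removeHs=False)
        elif format == "pdb":
            mol = Chem.MolFromPDBFile(str(source), removeHs=False)
        elif format == "xyz":
            mol = Chem.MolFromXYZFile(str(source))
            if mol is not None:
                rdDetermineBonds.DetermineBonds(mol, charge=0)
        else:
            raise ParseError(f"unknown format {format!r}")
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"failed to parse {source!r} as {format}: {exc}")
    if mol is None:
        raise ParseError(f"failed to parse {source!r} as {format}")
    mol = Chem.AddHs(mol, addCoords=bool(mol.GetNumConformers()))
    return MolecularGraph.from_rdkit(mol)


def load_monomer(
    source: str | os.PathLike,
    placeholder: str,
    format: str = "auto",
    label: str = "A",
) -> Monomer:
    """Read a placeholder-decorated monomer from any supported format."""
    graph = read_structure(source, format=format)
    return Monomer(graph, placeholder, label=label)


def to_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES (explicit hydrogens kept as atoms)."""
    return Chem.MolToSmiles(g.to_rdkit())


def write_structure(
    g: MolecularGraph,
    format: str,
    path: Optional[str | os.PathLike] = None,
) -> str:
    """Serialize to SMILES / MOL / XYZ / PDB; returns the text, optionally
    writing it to ``path``.  Coordinate formats require coords."""
    if format == "smiles":
        text = to_smiles(g) + "\n"
    elif format == "mol":
        text = Chem.MolToMolBlock(g.to_rdkit())
    elif format in ("xyz", "pdb"):
        if g.coords is None:
            raise StructureError(f"{format} output requires coordinates")
        mol = g.to_rdkit()
        text = (
            Chem.MolToXYZBlock(mol)
            if format == "xyz"
            else Chem.MolToPDBBlock(mol)
        )
    else:
        raise ParseError(f"unknown format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
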