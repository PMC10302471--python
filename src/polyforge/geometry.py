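"""Initial 3D placement and classical force-field relaxation.

Builders work in two stages: monomer copies are first embedded and laid out
along an axis (``place_copies``), spaced by the ``shift`` distance, and the
assembled polymer is then relaxed with MMFF94 or UFF (``minimize``).
Relaxation only moves coordinates — the molecular graph (elements, bond
multiset) is never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_graph import BuildConfig, MolecularGraph, Monomer
from .exceptions import MinimizationError, StructureError

#: Distance-geometry embedding seed used when no build seed is supplied, so
#: SMILES-born monomers always embed to the same conformer.
DEFAULT_EMBED_SEED = 1789


@dataclass(frozen=True)
class EmbeddingPlan:
    """Axis (normalized) and per-copy shift in Å for the pre-merge layout."""

    axis: np.ndarray = None  # type: ignore[assignment]
    shift: float = 3.0

    def __post_init__(self) -> None:
        axis = self.axis if self.axis is not None else np.array([1.0, 0, 0])
        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not norm > 0:
            raise StructureError("axis must be a nonzero vector")
        axis = axis / norm
        axis.setflags(write=False)
        object.__setattr__(self, "axis", axis)
        if not self.shift > 0:
            raise StructureError("shift must be > 0 Å")


@dataclass(frozen=True)
class MinimizeResult:
    graph: MolecularGraph
    energy_initial: Optional[float]
    energy_final: Optional[float]
    force_field_used: Optional[str]


def ensure_coords(
    g: MolecularGraph, seed: Optional[int] = None
) -> MolecularGraph:
    """Return ``g`` with 3D coordinates, embedding by ETKDG if absent.

    The embedding seed is fixed (``DEFAULT_EMBED_SEED``) unless given, so
    builds are reproducible.
    """
    if g.coords is not None:
        return g
    mol = g.to_rdkit()
    params = AllChem.ETKDGv3()
    params.randomSeed = DEFAULT_EMBED_SEED if seed is None else int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        # fall back to unconstrained random coords for exotic species
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise StructureError("3D embedding failed")
    return g.with_coords(np.array(mol.GetConformer().GetPositions()))


def place_copies(
    m: Monomer | MolecularGraph, n: int, plan: EmbeddingPlan
) -> MolecularGraph:
    """Disjoint union of ``n`` copies, copy *i* translated by ``i·shift·axis``.

    No bonds are created between copies; merging is a separate step.
    """
    if n < 1:
        raise StructureError("n must be >= 1")
    g = m.graph if isinstance(m, Monomer) else m
    g = ensure_coords(g)
    elements: tuple[str, ...] = ()
    charges: tuple[int, ...] = ()
    bonds: list[tuple[int, int, str]] = []
    blocks = []
    for i in range(n):
        off = len(elements)
        elements += g.elements
        charges += g.formal_charges
        bonds += [(a + off, b + off, o) for a, b, o in g.bonds]
        blocks.append(g.coords + i * plan.shift * plan.axis)
    return MolecularGraph(elements, tuple(bonds), charges, np.vstack(blocks))


def _typed_force_field(mol: Chem.Mol, name: str):
    if name == "MMFF":
        if not AllChem.MMFFHasAllMoleculeParams(mol):
            return None
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            return None
        return AllChem.MMFFGetMoleculeForceField(mol, props)
    if AllChem.UFFHasAllMoleculeParams(mol):
        return AllChem.UFFGetMoleculeForceField(mol)
    return None


def minimize(g: MolecularGraph, cfg: BuildConfig) -> MinimizeResult:
    """Relax coordinates with the configured force field.

    Falls back to the alternate force field (with a warning) when atom typing
    fails — UFF covers the whole periodic table, so exotic elements still
    relax.  ``ff_iterations = 0`` returns the input coordinates untouched.
    """
    if cfg.ff_iterations == 0:
        return MinimizeResult(g, None, None, None)
    g = ensure_coords(g, seed=cfg.seed)
    mol = g.to_rdkit()
    order = [cfg.force_field] + [
        f for f in ("MMFF", "UFF") if f != cfg.force_field
    ]
    ff = None
    used = None
    for name in order:
        ff = _typed_force_field(mol, name)
        if ff is not None:
            used = name
            break
        if name == cfg.force_field:
            warnings.warn(
                f"{name} typing failed; falling back to the alternate "
                "force field",
                stacklevel=2,
            )
    if ff is None:
        raise MinimizationError(
            "neither MMFF nor UFF could type this molecule"
        )
    ff.Initialize()
    e0 = ff.CalcEnergy()
    ff.Minimize(maxIts=int(cfg.ff_iterations))
    e1 = ff.CalcEnergy()
    coords = np.array(mol.GetConformer().GetPositions())
    return MinimizeResult(g.with_coords(coords), e0, e1, used)
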