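"""Programmatic test inputs: a catalog of decorated monomers and random
multi-ring molecules with known ground-truth linker bonds.

Nothing here is downloaded or read from disk; every structure is built from
a SMILES literal or assembled with the graph primitives, so the whole suite
is self-contained.
"""

from __future__ import annotations

import random
from typing import Optional

from .chem_graph import (
    MolecularGraph,
    Monomer,
    cap_placeholders,
    join,
    load_monomer,
)
from .torsional import LinkerBond

#: name → (SMILES, placeholder element)
CATALOG_SMILES: dict[str, tuple[str, str]] = {
    # two-site aromatic monomers (backbone repeat units)
    "furan": ("Brc1ccc(Br)o1", "Br"),
    "thiophene": ("Brc1ccc(Br)s1", "Br"),
    "benzene": ("Brc1ccc(Br)cc1", "Br"),
    "pyrrole": ("Brc1ccc(Br)[nH]1", "Br"),
    # two-site non-aromatic monomer (silanol repeat unit)
    "silanol": ("Br[Si](Br)(O)O", "Br"),
    # four-site core: ethylenediamine with a placeholder per amine hydrogen
    "ethylenediamine_core": ("BrN(Br)CCN(Br)Br", "Br"),
    # one-site arm
    "benzene_arm": ("Brc1ccccc1", "Br"),
    # platinum decoration variant (the placeholder element is arbitrary)
    "furan_pt": ("[Pt]c1ccc([Pt])o1", "Pt"),
}

#: two-site aromatic rings used by :func:`random_ring_assembly`
RING_VOCABULARY = ("benzene", "furan", "thiophene", "pyrrole")


def catalog() -> dict[str, Monomer]:
    """All named monomers, freshly parsed and validated."""
    return {
        name: load_monomer(smi, ph, label=name)
        for name, (smi, ph) in CATALOG_SMILES.items()
    }


def get_monomer(name: str) -> Monomer:
    smi, ph = CATALOG_SMILES[name]
    return load_monomer(smi, ph, label=name)


def random_ring_assembly(
    n_rings: int, seed: int
) -> tuple[MolecularGraph, list[LinkerBond]]:
    """Random tree of aromatic rings joined by acyclic single bonds.

    Rings are drawn from :data:`RING_VOCABULARY` and attached one at a time
    at a randomly chosen open site, so the result is a random tree with
    exactly ``n_rings − 1`` inter-ring bonds.  Those bonds are tracked
    through every index re-compaction and returned as the ground truth a
    linker-bond detector must reproduce.  Leftover placeholders are capped,
    so the molecule is chemically valid.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    rng = random.Random(seed)

    def pick() -> Monomer:
        return get_monomer(rng.choice(RING_VOCABULARY))

    first = pick()
    g = first.graph
    open_sites = list(first.sites)
    truth: list[tuple[int, int]] = []
    for _ in range(n_rings - 1):
        m = pick()
        site = open_sites.pop(rng.randrange(len(open_sites)))
        head, tail = m.sites
        # endpoints of the about-to-form bond, in pre-join indices
        na = g.neighbors(site)[0]
        nb = m.graph.neighbors(head)[0]
        res = join(g, site, m.graph, head)
        g = res.graph
        open_sites = [res.map_a[s] for s in open_sites]
        open_sites.append(res.map_b[tail])
        truth = [(res.map_a[i], res.map_a[j]) for i, j in truth]
        truth.append((res.map_a[na], res.map_b[nb]))
    g = cap_placeholders(g, "Br")
    bonds = sorted(LinkerBond(*sorted(b)) for b in truth)
    return g, bonds
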