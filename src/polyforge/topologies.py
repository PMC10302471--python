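"""Polymer builders: linear, diblock, random, ring, branched, patterned.

Every builder follows the same two-phase recipe: monomer copies are laid out
along an axis (spaced by ``cfg.shift``), merged through their placeholder
sites head-to-tail, surviving placeholders are capped with hydrogen (or
consumed by ring closure), and the product is relaxed with the configured
force field.  Builders compose: ``linear_chain`` / ``patterned_chain``
return *uncapped* oligomers that can themselves serve as monomers — a
diblock chain can be closed into a copolymer ring, an oligomer can become
the arm of a branched polymer.

In two-site monomers the lower-index placeholder is the head and the
higher-index one the tail; joins always consume ``tail(i) ↔ head(i+1)``, so
builds are deterministic without user intervention.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from sympy.utilities.iterables import multiset_permutations

from . import chem_graph as cg
from .chem_graph import BuildConfig, MolecularGraph, Monomer
from .exceptions import ProbabilityError, TopologyError
from .geometry import EmbeddingPlan, ensure_coords, minimize

__all__ = [
    "PolymerResult",
    "PatternSpec",
    "linear_polymer",
    "linear_chain",
    "diblock_copolymer",
    "random_ab_copolymer",
    "random_abc_copolymer",
    "ring_polymer",
    "ring_from_chain",
    "branched_polymer",
    "patterned_polymer",
    "patterned_chain",
    "unique_pattern_permutations",
]


@dataclass(frozen=True)
class PolymerResult:
    """A built polymer: graph, topology tag, backbone sequence, seed."""

    graph: MolecularGraph
    topology: str  # linear | ring | branched
    sequence: tuple[str, ...]
    seed_used: Optional[int] = None


@dataclass(frozen=True)
class PatternSpec:
    """Alphabetic pattern plus the monomer list it indexes (A→0, B→1, ...)."""

    pattern: str
    monomers: Sequence[Monomer]

    def __post_init__(self) -> None:
        if not self.pattern:
            raise TopologyError("pattern must be nonempty")
        for ch in self.pattern:
            idx = ord(ch) - ord("A")
            if not 0 <= idx < 26 or ch != ch.upper():
                raise TopologyError(f"pattern letter {ch!r} outside A..Z")
            if idx >= len(self.monomers):
                raise TopologyError(
                    f"pattern letter {ch!r} has no monomer (list has "
                    f"{len(self.monomers)} entries)"
                )

    def resolve(self) -> list[Monomer]:
        return [self.monomers[ord(ch) - ord("A")] for ch in self.pattern]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _require_two_sites(m: Monomer, who: str) -> None:
    if len(m.sites) != 2:
        raise TopologyError(
            f"{who} must carry exactly 2 placeholder atoms, found "
            f"{len(m.sites)}"
        )


def _require_same_placeholder(*monomers: Monomer) -> str:
    elems = {m.placeholder for m in monomers}
    if len(elems) != 1:
        raise TopologyError(
            f"monomers use different placeholder elements: {sorted(elems)}"
        )
    return elems.pop()


def _assemble_chain(
    units: Sequence[Monomer], cfg: BuildConfig
) -> tuple[MolecularGraph, int, int]:
    """Merge monomer copies head-to-tail.

    Returns the chain graph plus the indices of the two surviving terminal
    placeholders (head of the first unit, tail of the last).
    """
    plan = EmbeddingPlan(shift=cfg.shift)
    embedded: dict[int, MolecularGraph] = {}
    for m in units:
        _require_two_sites(m, "chain monomer")
        if id(m) not in embedded:
            embedded[id(m)] = ensure_coords(m.graph, seed=cfg.seed)

    first = embedded[id(units[0])]
    chain = first
    head, tail = units[0].sites
    for i, m in enumerate(units[1:], start=1):
        g = embedded[id(m)]
        g = g.with_coords(g.coords + i * plan.shift * plan.axis)
        m_head, m_tail = m.sites
        res = cg.join(chain, tail, g, m_head)
        chain = res.graph
        head = res.map_a[head]
        tail = res.map_b[m_tail]
    return chain, head, tail


def _finalize(
    graph: MolecularGraph,
    placeholder: str,
    topology: str,
    sequence: Sequence[str],
    cfg: BuildConfig,
    seed_used: Optional[int] = None,
) -> PolymerResult:
    capped = cg.cap_placeholders(graph, placeholder)
    relaxed = minimize(capped, cfg).graph
    return PolymerResult(relaxed, topology, tuple(sequence), seed_used)


# ---------------------------------------------------------------------------
# linear family
# ---------------------------------------------------------------------------


def linear_polymer(
    m: Monomer, n_copies: int, cfg: Optional[BuildConfig] = None
) -> PolymerResult:
    """Homopolymer of ``n_copies`` units joined end-to-end, termini capped."""
    cfg = cfg or BuildConfig()
    if n_copies < 1:
        raise TopologyError("n_copies must be >= 1")
    _require_two_sites(m, "monomer")
    chain, _, _ = _assemble_chain([m] * n_copies, cfg)
    return _finalize(
        chain, m.placeholder, "linear", [m.label] * n_copies, cfg, cfg.seed
    )


def linear_chain(
    m: Monomer, n_copies: int, cfg: Optional[BuildConfig] = None
) -> Monomer:
    """Uncapped homopolymer chain, reusable as a monomer (2 live termini)."""
    cfg = cfg or BuildConfig()
    if n_copies < 1:
        raise TopologyError("n_copies must be >= 1")
    _require_two_sites(m, "monomer")
    chain, _, _ = _assemble_chain([m] * n_copies, cfg)
    return Monomer(
        chain, m.placeholder, label=m.label, sequence=(m.label,) * n_copies
    )


def diblock_copolymer(
    ma: Monomer,
    mb: Monomer,
    len_a: int,
    len_b: int,
    cfg: Optional[BuildConfig] = None,
) -> PolymerResult:
    """Two consecutive blocks: ``len_a`` units of A then ``len_b`` of B."""
    cfg = cfg or BuildConfig()
    if len_a < 1 or len_b < 1:
        raise TopologyError("block lengths must be >= 1")
    ph = _require_same_placeholder(ma, mb)
    _require_two_sites(ma, "block A monomer")
    _require_two_sites(mb, "block B monomer")
    units = [ma] * len_a + [mb] * len_b
    seq = "A" * len_a + "B" * len_b
    chain, _, _ = _assemble_chain(units, cfg)
    return _finalize(chain, ph, "linear", seq, cfg, cfg.seed)


def diblock_chain(
    ma: Monomer,
    mb: Monomer,
    len_a: int,
    len_b: int,
    cfg: Optional[BuildConfig] = None,
) -> Monomer:
    """Uncapped diblock chain, e.g. for closure into a copolymer ring."""
    cfg = cfg or BuildConfig()
    if len_a < 1 or len_b < 1:
        raise TopologyError("block lengths must be >= 1")
    ph = _require_same_placeholder(ma, mb)
    chain, _, _ = _assemble_chain([ma] * len_a + [mb] * len_b, cfg)
    return Monomer(
        chain, ph, label="A", sequence=tuple("A" * len_a + "B" * len_b)
    )


def _random_sequence(
    letters: list[str], seed: Optional[int]
) -> tuple[list[str], int]:
    seed_used = (
        seed if seed is not None else random.randrange(2**31)
    )
    rng = random.Random(seed_used)
    shuffled = list(letters)
    rng.shuffle(shuffled)
    return shuffled, seed_used


def random_ab_copolymer(
    m1: Monomer,
    m2: Monomer,
    length: int,
    pA: float,
    cfg: Optional[BuildConfig] = None,
) -> PolymerResult:
    """Random two-monomer copolymer with composition fixed by ``pA``.

    Exactly ``round(pA·length)`` units of ``m1`` are placed (round half up),
    the remainder being ``m2``; the order is a seeded uniform shuffle of
    that multiset, so composition is exact rather than binomial.
    """
    cfg = cfg or BuildConfig()
    if not 0 <= pA <= 1:
        raise ProbabilityError(f"pA={pA} outside [0, 1]")
    if length < 1:
        raise TopologyError("length must be >= 1")
    ph = _require_same_placeholder(m1, m2)
    nA = _round_half_up(pA * length)
    seq, seed_used = _random_sequence(
        ["A"] * nA + ["B"] * (length - nA), cfg.seed
    )
    by_letter = {"A": m1, "B": m2}
    chain, _, _ = _assemble_chain([by_letter[ch] for ch in seq], cfg)
    return _finalize(chain, ph, "linear", seq, cfg, seed_used)


def random_abc_copolymer(
    m1: Monomer,
    m2: Monomer,
    m3: Monomer,
    length: int,
    pA: float,
    pB: float,
    cfg: Optional[BuildConfig] = None,
) -> PolymerResult:
    """Random three-monomer copolymer; counts are round(pA·len),
    round(pB·len) and the remainder."""
    cfg = cfg or BuildConfig()
    if pA < 0 or pB < 0:
        raise ProbabilityError("probabilities must be >= 0")
    if pA + pB > 1:
        raise ProbabilityError(f"pA + pB = {pA + pB} exceeds 1")
    if length < 1:
        raise TopologyError("length must be >= 1")
    ph = _require_same_placeholder(m1, m2, m3)
    nA = min(_round_half_up(pA * length), length)
    # half-up rounding of both pA and pB can overshoot by one unit; the
    # later blocks absorb the correction so counts always sum to length
    nB = min(_round_half_up(pB * length), length - nA)
    nC = length - nA - nB
    seq, seed_used = _random_sequence(
        ["A"] * nA + ["B"] * nB + ["C"] * nC, cfg.seed
    )
    by_letter = {"A": m1, "B": m2, "C": m3}
    chain, _, _ = _assemble_chain([by_letter[ch] for ch in seq], cfg)
    return _finalize(chain, ph, "linear", seq, cfg, seed_used)


# ---------------------------------------------------------------------------
# ring family
# ---------------------------------------------------------------------------


def ring_polymer(
    m: Monomer, length: int, cfg: Optional[BuildConfig] = None
) -> PolymerResult:
    """Cyclic homopolymer: a linear chain whose two terminal placeholders
    are consumed to bond head to tail, adding exactly one macrocycle."""
    cfg = cfg or BuildConfig()
    if length < 3:
        raise TopologyError("ring polymers need length >= 3")
    _require_two_sites(m, "monomer")
    chain, head, tail = _assemble_chain([m] * length, cfg)
    closed, _ = cg.close_ring(chain, head, tail)
    relaxed = minimize(closed, cfg).graph
    return PolymerResult(relaxed, "ring", (m.label,) * length, cfg.seed)


def ring_from_chain(
    chain: Monomer, cfg: Optional[BuildConfig] = None
) -> PolymerResult:
    """Close any uncapped two-site chain (e.g. a diblock) into a ring."""
    cfg = cfg or BuildConfig()
    _require_two_sites(chain, "chain")
    head, tail = chain.sites
    closed, _ = cg.close_ring(chain.graph, head, tail)
    relaxed = minimize(closed, cfg).graph
    seq = chain.sequence or (chain.label,)
    return PolymerResult(relaxed, "ring", tuple(seq), cfg.seed)


# ---------------------------------------------------------------------------
# branched
# ---------------------------------------------------------------------------

_ARM_DIRECTIONS = (
    (1.0, 0.0, 0.0),
    (-1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, -1.0, 0.0),
    (0.0, 0.0, 1.0),
    (0.0, 0.0, -1.0),
)


def branched_polymer(
    core: Monomer, arm: Monomer, cfg: Optional[BuildConfig] = None
) -> PolymerResult:
    """Attach one copy of ``arm`` at every placeholder site of ``core``.

    A core with k placeholders yields k arms; the arm must carry exactly
    one placeholder (its attachment point).
    """
    cfg = cfg or BuildConfig()
    if len(arm.sites) != 1:
        raise TopologyError(
            f"arm must carry exactly 1 placeholder, found {len(arm.sites)}"
        )
    ph = _require_same_placeholder(core, arm)
    core_g = ensure_coords(core.graph, seed=cfg.seed)
    arm_g = ensure_coords(arm.graph, seed=cfg.seed)
    sites = core.sites
    k = len(sites)
    graph = core_g
    pending = list(sites)
    for j in range(k):
        d = _ARM_DIRECTIONS[j % len(_ARM_DIRECTIONS)]
        radius = cfg.shift * (2 + j // len(_ARM_DIRECTIONS))
        offset = (radius * d[0], radius * d[1], radius * d[2])
        placed = arm_g.with_coords(arm_g.coords + offset)
        res = cg.join(graph, pending[0], placed, arm.sites[0])
        graph = res.graph
        pending = [res.map_a[p] for p in pending[1:]]
    seq = ("core",) + ("arm",) * k
    return _finalize(graph, ph, "branched", seq, cfg, cfg.seed)


# ---------------------------------------------------------------------------
# patterned
# ---------------------------------------------------------------------------


def patterned_polymer(
    spec: PatternSpec, cfg: Optional[BuildConfig] = None
) -> PolymerResult:
    """Backbone whose unit sequence equals the pattern string exactly."""
    cfg = cfg or BuildConfig()
    units = spec.resolve()
    ph = _require_same_placeholder(*units)
    chain, _, _ = _assemble_chain(units, cfg)
    return _finalize(chain, ph, "linear", tuple(spec.pattern), cfg, cfg.seed)


def patterned_chain(
    spec: PatternSpec, cfg: Optional[BuildConfig] = None
) -> Monomer:
    """Uncapped patterned chain, reusable as a monomer."""
    cfg = cfg or BuildConfig()
    units = spec.resolve()
    ph = _require_same_placeholder(*units)
    chain, _, _ = _assemble_chain(units, cfg)
    return Monomer(chain, ph, label="A", sequence=tuple(spec.pattern))


def unique_pattern_permutations(pattern: str) -> list[str]:
    """Sorted distinct multiset permutations of a pattern's letters."""
    if not pattern:
        raise TopologyError("pattern must be nonempty")
    return sorted(
        "".join(p) for p in multiset_permutations(sorted(pattern))
    )
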