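"""Builder correctness: composition, conservation, determinism."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import polyforge as pf
from polyforge import topologies as tp

from conftest import canon, count_substructure

FURAN_RING = "c1ccoc1"
THIOPHENE_RING = "c1ccsc1"
BENZENE_RING = "c1ccccc1"


def rhu(x: float) -> int:
    return int(math.floor(x + 0.5))


class TestLinearPolymer:
    def test_pentamer_contains_five_furan_units(self, furan):
        poly = pf.linear_polymer(furan, 5)
        assert count_substructure(poly.graph, FURAN_RING) == 5
        assert poly.topology == "linear"
        assert poly.sequence == ("furan",) * 5

    def test_single_copy_is_the_capped_monomer(self, furan):
        poly = pf.linear_polymer(furan, 1, pf.BuildConfig(ff_iterations=0))
        assert canon(poly.graph) == canon(FURAN_RING)

    def test_pentamer_conservation_arithmetic(self, furan, fast_cfg):
        a_mon, b_mon = furan.graph.n_atoms, furan.graph.n_bonds
        poly = pf.linear_polymer(furan, 5, fast_cfg)
        assert poly.graph.n_atoms == 5 * a_mon - 2 * 4 == 37
        assert poly.graph.n_bonds == 5 * b_mon - 4

    def test_no_placeholders_survive(self, furan, fast_cfg):
        poly = pf.linear_polymer(furan, 5, fast_cfg)
        assert pf.find_placeholders(poly.graph, "Br") == []

    def test_invalid_inputs_rejected(self, furan, catalog):
        with pytest.raises(pf.TopologyError):
            pf.linear_polymer(furan, 0)
        with pytest.raises(pf.TopologyError):
            pf.linear_polymer(catalog["benzene_arm"], 3)
        with pytest.raises(pf.TopologyError):
            pf.linear_polymer(catalog["ethylenediamine_core"], 3)


class TestDiblockCopolymer:
    def test_block_sequence_and_composition(self, furan, thiophene, fast_cfg):
        poly = pf.diblock_copolymer(furan, thiophene, 2, 3, fast_cfg)
        assert "".join(poly.sequence) == "AABBB"
        assert count_substructure(poly.graph, FURAN_RING) == 2
        assert count_substructure(poly.graph, THIOPHENE_RING) == 3

    def test_zero_block_length_rejected(self, furan, thiophene):
        with pytest.raises(pf.TopologyError):
            pf.diblock_copolymer(furan, thiophene, 1, 0)

    def test_mismatched_placeholder_elements_rejected(self, furan, catalog):
        with pytest.raises(pf.TopologyError, match="placeholder"):
            pf.diblock_copolymer(furan, catalog["furan_pt"], 2, 2)


class TestRandomCopolymers:
    def test_ab_composition_is_count_exact(self, furan, thiophene, fast_cfg):
        poly = pf.random_ab_copolymer(furan, thiophene, 10, 0.4, fast_cfg)
        assert poly.sequence.count("A") == 4
        assert poly.sequence.count("B") == 6
        assert count_substructure(poly.graph, FURAN_RING) == 4
        assert count_substructure(poly.graph, THIOPHENE_RING) == 6

    def test_pa_one_is_the_homopolymer(self, furan, thiophene, fast_cfg):
        rand = pf.random_ab_copolymer(furan, thiophene, 4, 1.0, fast_cfg)
        homo = pf.linear_polymer(furan, 4, fast_cfg)
        assert canon(rand.graph) == canon(homo.graph)

    def test_probability_out_of_range_rejected(self, furan, thiophene):
        with pytest.raises(pf.ProbabilityError):
            pf.random_ab_copolymer(furan, thiophene, 5, 1.2)
        with pytest.raises(pf.ProbabilityError):
            pf.random_ab_copolymer(furan, thiophene, 5, -0.1)

    def test_identical_seed_reproduces_sequence(self, furan, thiophene):
        cfg = pf.BuildConfig(ff_iterations=0, seed=123)
        a = pf.random_ab_copolymer(furan, thiophene, 12, 0.5, cfg)
        b = pf.random_ab_copolymer(furan, thiophene, 12, 0.5, cfg)
        assert a.sequence == b.sequence
        assert a.seed_used == b.seed_used == 123

    def test_seeds_spread_over_multiset_permutations(self, furan, thiophene):
        seqs = set()
        for seed in range(60):
            cfg = pf.BuildConfig(ff_iterations=0, seed=seed)
            poly = pf.random_ab_copolymer(furan, thiophene, 6, 0.5, cfg)
            assert poly.sequence.count("A") == 3
            seqs.add(poly.sequence)
        # 6!/3!/3! = 20 distinct orders; 60 seeds must hit many of them
        assert len(seqs) > 10

    def test_abc_counts_match_stated_probabilities(
        self, furan, thiophene, benzene, fast_cfg
    ):
        poly = pf.random_abc_copolymer(
            furan, thiophene, benzene, 10, 0.4, 0.2, fast_cfg
        )
        counts = tuple(poly.sequence.count(x) for x in "ABC")
        assert counts == (4, 2, 4)

    def test_abc_zero_probabilities_give_homopolymer(
        self, furan, thiophene, benzene, fast_cfg
    ):
        poly = pf.random_abc_copolymer(
            furan, thiophene, benzene, 4, 0.0, 0.0, fast_cfg
        )
        assert poly.sequence == ("C",) * 4
        assert canon(poly.graph) == canon(
            pf.linear_polymer(benzene, 4, fast_cfg).graph
        )

    def test_abc_probability_sum_above_one_rejected(
        self, furan, thiophene, benzene
    ):
        with pytest.raises(pf.ProbabilityError):
            pf.random_abc_copolymer(furan, thiophene, benzene, 5, 0.7, 0.6)

    @given(
        pa=st.integers(0, 10),
        pb=st.integers(0, 10),
        length=st.integers(1, 20),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_abc_counts_always_sum_to_length(
        self, catalog, pa, pb, length, seed
    ):
        if pa + pb > 10:
            return
        cfg = pf.BuildConfig(ff_iterations=0, seed=seed)
        poly = pf.random_abc_copolymer(
            catalog["furan"],
            catalog["thiophene"],
            catalog["benzene"],
            length,
            pa / 10,
            pb / 10,
            cfg,
        )
        poly_counts = [poly.sequence.count(x) for x in "ABC"]
        assert sum(poly_counts) == length
        assert len(poly.sequence) == length


class TestRingPolymer:
    def test_benzene_ring_polymer_has_one_macrocycle(self, benzene, fast_cfg):
        poly = pf.ring_polymer(benzene, 5, fast_cfg)
        assert poly.topology == "ring"
        assert count_substructure(poly.graph, BENZENE_RING) == 5
        # 5 benzene rings + exactly 1 macrocycle
        assert poly.graph.cyclomatic_number() == 5 + 1

    def test_ring_conservation_arithmetic(self, furan, fast_cfg):
        a_mon, b_mon = furan.graph.n_atoms, furan.graph.n_bonds
        n = 6
        poly = pf.ring_polymer(furan, n, fast_cfg)
        assert poly.graph.n_atoms == n * (a_mon - 2)
        assert poly.graph.n_bonds == n * (b_mon - 1)

    def test_ring_exceeds_open_chain_cyclomatic_by_one(
        self, catalog, fast_cfg
    ):
        for name in ("furan", "thiophene", "benzene", "silanol"):
            m = catalog[name]
            for n in (3, 5):
                ring = pf.ring_polymer(m, n, fast_cfg)
                chain = pf.linear_polymer(m, n, fast_cfg)
                assert (
                    ring.graph.cyclomatic_number()
                    == chain.graph.cyclomatic_number() + 1
                )

    def test_too_short_ring_rejected(self, benzene):
        with pytest.raises(pf.TopologyError):
            pf.ring_polymer(benzene, 2)

    def test_diblock_chain_closes_into_copolymer_ring(
        self, benzene, thiophene, fast_cfg
    ):
        chain = tp.diblock_chain(benzene, thiophene, 2, 2, fast_cfg)
        ring = pf.ring_from_chain(chain, fast_cfg)
        assert ring.topology == "ring"
        assert "".join(ring.sequence) == "AABB"
        assert ring.graph.cyclomatic_number() == 4 + 1
        assert pf.find_placeholders(ring.graph, "Br") == []


class TestBranchedPolymer:
    def test_four_placeholder_core_gets_four_arms(self, catalog, fast_cfg):
        poly = pf.branched_polymer(
            catalog["ethylenediamine_core"], catalog["benzene_arm"], fast_cfg
        )
        assert poly.topology == "branched"
        assert poly.sequence == ("core",) + ("arm",) * 4
        assert count_substructure(poly.graph, BENZENE_RING) == 4
        assert pf.find_placeholders(poly.graph, "Br") == []

    def test_single_site_core_gives_two_unit_molecule(self, catalog, fast_cfg):
        poly = pf.branched_polymer(
            catalog["benzene_arm"], catalog["benzene_arm"], fast_cfg
        )
        assert canon(poly.graph) == canon("c1ccc(-c2ccccc2)cc1")

    def test_multivalent_arm_rejected(self, catalog, furan):
        with pytest.raises(pf.TopologyError):
            pf.branched_polymer(catalog["ethylenediamine_core"], furan)

    def test_oligomer_arm_from_linear_chain(self, catalog, furan, fast_cfg):
        chain = tp.linear_chain(furan, 2, fast_cfg)
        head = chain.sites[0]
        arm_graph = pf.cap_placeholders(chain.graph, "Br", indices=[head])
        arm = pf.Monomer(arm_graph, "Br", label="oligoarm")
        poly = pf.branched_polymer(
            catalog["ethylenediamine_core"], arm, fast_cfg
        )
        assert count_substructure(poly.graph, FURAN_RING) == 8


class TestPatternedPolymer:
    def test_pattern_maps_letters_to_monomer_list(
        self, furan, thiophene, benzene, fast_cfg
    ):
        spec = tp.PatternSpec("ABC", [thiophene, furan, benzene])
        poly = pf.patterned_polymer(spec, fast_cfg)
        assert poly.sequence == ("A", "B", "C")
        for ring in (FURAN_RING, THIOPHENE_RING, BENZENE_RING):
            assert count_substructure(poly.graph, ring) == 1

    def test_single_letter_pattern_is_capped_monomer(self, furan, fast_cfg):
        poly = pf.patterned_polymer(tp.PatternSpec("A", [furan]), fast_cfg)
        assert canon(poly.graph) == canon(FURAN_RING)

    def test_repeated_letters_count_correctly(
        self, furan, thiophene, benzene, fast_cfg
    ):
        spec = tp.PatternSpec("ABBACC", [furan, thiophene, benzene])
        poly = pf.patterned_polymer(spec, fast_cfg)
        assert "".join(poly.sequence) == "ABBACC"
        assert count_substructure(poly.graph, FURAN_RING) == 2
        assert count_substructure(poly.graph, THIOPHENE_RING) == 2
        assert count_substructure(poly.graph, BENZENE_RING) == 2

    def test_unmapped_letter_rejected(self, furan):
        with pytest.raises(pf.TopologyError, match="no monomer"):
            tp.PatternSpec("AB", [furan])

    def test_homopolymer_pattern_matches_linear_builder(
        self, furan, fast_cfg
    ):
        patterned = pf.patterned_polymer(
            tp.PatternSpec("AAAA", [furan]), fast_cfg
        )
        linear = pf.linear_polymer(furan, 4, fast_cfg)
        assert canon(patterned.graph) == canon(linear.graph)

    def test_patterned_chain_usable_as_monomer(self, furan, benzene, fast_cfg):
        chain = tp.patterned_chain(tp.PatternSpec("AB", [furan, benzene]),
                                   fast_cfg)
        poly = pf.linear_polymer(chain, 3, fast_cfg)
        assert count_substructure(poly.graph, FURAN_RING) == 3
        assert count_substructure(poly.graph, BENZENE_RING) == 3


class TestUniquePatternPermutations:
    def test_all_distinct_letters(self):
        perms = pf.unique_pattern_permutations("ABC")
        assert len(perms) == 6
        assert perms == sorted(set(perms))

    def test_multiset_collapse(self):
        assert pf.unique_pattern_permutations("AA") == ["AA"]

    @pytest.mark.parametrize("pattern", ["AAB", "AABB", "ABCA", "AAAB"])
    def test_matches_brute_force_dedup(self, pattern):
        expected = sorted(
            {"".join(p) for p in itertools.permutations(pattern)}
        )
        assert pf.unique_pattern_permutations(pattern) == expected

    @given(st.text(alphabet="ABC", min_size=1, max_size=6))
    def test_property_equals_brute_force(self, pattern):
        expected = sorted(
            {"".join(p) for p in itertools.permutations(pattern)}
        )
        assert pf.unique_pattern_permutations(pattern) == expected

    def test_empty_pattern_rejected(self):
        with pytest.raises(pf.TopologyError):
            pf.unique_pattern_permutations("")


class TestProductInvariants:
    def test_every_product_is_placeholder_free_and_valent(
        self, catalog, fast_cfg
    ):
        furan, thiophene = catalog["furan"], catalog["thiophene"]
        products = [
            pf.linear_polymer(furan, 3, fast_cfg),
            pf.diblock_copolymer(furan, thiophene, 2, 2, fast_cfg),
            pf.random_ab_copolymer(furan, thiophene, 5, 0.4, fast_cfg),
            pf.ring_polymer(furan, 4, fast_cfg),
            pf.branched_polymer(
                catalog["ethylenediamine_core"],
                catalog["benzene_arm"],
                fast_cfg,
            ),
            pf.patterned_polymer(
                tp.PatternSpec("ABA", [furan, thiophene]), fast_cfg
            ),
        ]
        for poly in products:
            assert pf.find_placeholders(poly.graph, "Br") == []
            pf.validate_valence(poly.graph)
            assert len(poly.sequence) >= 1
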