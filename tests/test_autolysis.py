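"""Site enumeration, fragment groups, masses, triad logic and ranking."""

import math

import networkx as nx
import numpy as np
import pytest

from psychrotryp.autolysis import (
    BandObservation,
    CleavagePattern,
    DisulfideTopology,
    ProteinChain,
    Tag,
    assess_site_lability,
    enumerate_candidate_sites,
    enumerate_cleavage_patterns,
    fragment_groups,
    group_mass,
    match_bands_and_rank,
    triad_disrupted,
)
from psychrotryp.constants import WATER_AVERAGE
from psychrotryp.structure import ContactAnnotation, ExposureProfile
from psychrotryp.synthetic import ProteinFixtureSpec, simulate_protein_fixture

WATER = WATER_AVERAGE


def groups_oracle(chain, pattern, ss):
    """Independent connected-components oracle (networkx graph traversal)."""
    bounds = [chain.first_residue_number - 1, *pattern.cut_after, chain.last_residue_number]
    intervals = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for a, b in ss.pairs:
        ia = next(i for i, (lo, hi) in enumerate(intervals) if lo <= a <= hi)
        ib = next(i for i, (lo, hi) in enumerate(intervals) if lo <= b <= hi)
        g.add_edge(ia, ib)
    return [sorted(c) for c in nx.connected_components(g)], intervals


class TestSiteEnumeration:
    def test_proline_rule_and_positions(self):
        sites = enumerate_candidate_sites(ProteinChain("AKGRPA"))
        assert [(s.residue_number, s.residue_type) for s in sites] == [(2, "K")]

    def test_permissive_mode_keeps_proline_flagged(self):
        sites = enumerate_candidate_sites(ProteinChain("AKGRPA"), "permissive")
        assert [(s.residue_number, s.followed_by_proline) for s in sites] == [
            (2, False), (4, True),
        ]

    def test_c_terminal_basic_residue_has_no_scissile_bond(self):
        assert enumerate_candidate_sites(ProteinChain("AAAK")) == []

    def test_numbering_offset_respected(self):
        sites = enumerate_candidate_sites(ProteinChain("AKGA", first_residue_number=95))
        assert [s.residue_number for s in sites] == [96]


class TestLability:
    def test_filters_applied_per_site(self):
        sites = enumerate_candidate_sites(ProteinChain("AKAAKAAKAA"))
        exposure = ExposureProfile.from_relative({2: 0.45, 5: 0.45, 8: 0.10})
        contacts = ContactAnnotation.from_flags([2, 5, 8], salt_bridged={5})
        assessed = assess_site_lability(sites, exposure, contacts)
        assert [s.labile for s in assessed] == [True, False, False]

    def test_missing_coverage_keeps_site_unassessed(self, caplog):
        sites = enumerate_candidate_sites(ProteinChain("AKA"))
        with caplog.at_level("WARNING"):
            assessed = assess_site_lability(
                sites, ExposureProfile.from_relative({}), ContactAnnotation.from_flags([])
            )
        assert assessed[0].unassessed and assessed[0].labile is None

    def test_kt1_style_annotation_single_primary_site(self):
        """Four basic sites; only the K96 analog is exposed and unstabilized."""
        seq = ["A"] * 236
        for pos in (96, 163, 197):
            seq[pos - 30] = "K"
        seq[230 - 30] = "R"
        chain = ProteinChain("".join(seq), first_residue_number=30)
        sites = enumerate_candidate_sites(chain)
        assert [s.residue_number for s in sites] == [96, 163, 197, 230]
        exposure = ExposureProfile.from_relative({96: 0.30, 163: 0.40, 197: 0.35, 230: 0.25})
        contacts = ContactAnnotation.from_flags(
            [96, 163, 197, 230], salt_bridged={163}, near_disulfide={197}
        )
        assessed = assess_site_lability(sites, exposure, contacts)
        assert [s.residue_number for s in assessed if s.labile] == [96]


class TestPatternEnumeration:
    def test_power_set_counts(self):
        sites = [2, 5]
        assert len(enumerate_cleavage_patterns(sites)) == 4
        assert len(enumerate_cleavage_patterns([1, 2, 3, 4], max_cuts=1)) == 5
        assert len(enumerate_cleavage_patterns([1, 2, 3, 4])) == 16

    def test_deterministic_order_and_empty_first(self):
        pats = enumerate_cleavage_patterns([3, 1])
        assert pats[0] == CleavagePattern(())
        assert [p.cut_after for p in pats] == [(), (1,), (3,), (1, 3)]

    def test_guard_against_blowup(self):
        with pytest.raises(ValueError, match="too many sites"):
            enumerate_cleavage_patterns(list(range(1, 15)))


class TestFragmentGroups:
    def test_plain_cut(self):
        chain = ProteinChain("G" * 10)
        groups = fragment_groups(chain, CleavagePattern((4,)), DisulfideTopology())
        assert [g.fragments for g in groups] == [((1, 4),), ((5, 10),)]

    def test_disulfide_links_fragments_into_one_group(self):
        chain = ProteinChain("GCGGGGGCGG")
        ss = DisulfideTopology(pairs=((2, 8),))
        groups = fragment_groups(chain, CleavagePattern((4,)), ss)
        assert len(groups) == 1
        assert groups[0].fragments == ((1, 4), (5, 10))

    def test_invalid_cut_rejected(self):
        with pytest.raises(ValueError, match="invalid cut"):
            fragment_groups(ProteinChain("GGGG"), CleavagePattern((9,)), DisulfideTopology())

    def test_kt1_like_tag_retention_and_triad(self):
        """Cut after the K96 analog: C-terminal group keeps the His-tag and
        the triad is split; cut after the R230 analog leaves the triad whole
        and the tag on a small fragment."""
        seq = ["A"] * 236
        for pos, aa in ((96, "K"), (163, "K"), (197, "K"), (230, "R")):
            seq[pos - 30] = aa
        for pos in (45, 61, 143, 210, 174, 189, 200, 228):
            seq[pos - 30] = "C"
        tag = Tag("6xHis", "C", 822.85)
        chain = ProteinChain("".join(seq), first_residue_number=30, tags=(tag,))
        ss = DisulfideTopology(pairs=((45, 61), (143, 210), (174, 189), (200, 228)))
        ss.validate_against(chain)
        triad = (72, 116, 209)

        g96 = fragment_groups(chain, CleavagePattern((96,)), ss, triad)
        assert len(g96) == 2
        assert g96[0].retains_tags == () and g96[1].retains_tags == ("6xHis",)
        assert triad_disrupted(g96, triad)

        g230 = fragment_groups(chain, CleavagePattern((230,)), ss, triad)
        assert len(g230) == 2
        assert not triad_disrupted(g230, triad)
        assert g230[1].retains_tags == ("6xHis",)  # tag on the small C-terminal piece

        for cut in (163, 197):
            groups = fragment_groups(chain, CleavagePattern((cut,)), ss, triad)
            assert len(groups) == 1  # bridged by disulfides: no band change
            assert not triad_disrupted(groups, triad)


class TestMasses:
    def test_dipeptide_mass_from_published_table(self):
        chain = ProteinChain("GG")
        g = fragment_groups(chain, CleavagePattern(()), DisulfideTopology())[0]
        assert group_mass(g, chain) == pytest.approx(132.12, abs=0.01)

    def test_hydrolysis_adds_one_water(self):
        chain = ProteinChain("GG")
        ss = DisulfideTopology()
        intact = group_mass(fragment_groups(chain, CleavagePattern(()), ss)[0], chain)
        cut = sum(group_mass(g, chain) for g in fragment_groups(chain, CleavagePattern((1,)), ss))
        assert cut == pytest.approx(intact + WATER, abs=1e-9)
        assert cut == pytest.approx(150.13, abs=0.01)

    def test_oxidized_mode_removes_two_hydrogens_per_internal_bond(self):
        chain = ProteinChain("GCGGGGGCGG")
        ss = DisulfideTopology(pairs=((2, 8),))
        g = fragment_groups(chain, CleavagePattern(()), ss)[0]
        red = group_mass(g, chain, ss, oxidized=False)
        ox = group_mass(g, chain, ss, oxidized=True)
        assert red - ox == pytest.approx(2.01565, abs=1e-9)

    def test_mass_conservation_property_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for seed in range(20):
            fx = simulate_protein_fixture(
                ProteinFixtureSpec(length=int(rng.integers(150, 301)),
                                   n_candidate_sites=2, n_labile=2,
                                   n_disulfides=int(rng.integers(0, 5)), seed=seed)
            )
            chain, ss = fx.chain, fx.disulfides
            intact = group_mass(
                fragment_groups(chain, CleavagePattern(()), ss)[0], chain
            )
            for pattern in enumerate_cleavage_patterns(list(fx.candidate_sites)):
                total = sum(
                    group_mass(g, chain, ss)
                    for g in fragment_groups(chain, pattern, ss)
                )
                assert total == pytest.approx(intact + len(pattern) * WATER, abs=1e-6)


class TestTriad:
    def test_cut_between_members_disrupts(self):
        chain = ProteinChain("G" * 10)
        groups = fragment_groups(chain, CleavagePattern((5,)), DisulfideTopology(), (3, 7, 9))
        assert triad_disrupted(groups, (3, 7, 9))

    def test_disulfide_bridge_preserves_triad(self):
        chain = ProteinChain("GCGGGGGCGG")
        ss = DisulfideTopology(pairs=((2, 8),))
        groups = fragment_groups(chain, CleavagePattern((5,)), ss, (3, 7, 9))
        assert not triad_disrupted(groups, (3, 7, 9))

    def test_invalid_triad_annotation(self):
        chain = ProteinChain("GGGG")
        with pytest.raises(ValueError, match="invalid triad annotation"):
            fragment_groups(chain, CleavagePattern(()), DisulfideTopology(), (99,))


class TestGroupStructureOracle:
    def test_union_find_matches_graph_traversal(self):
        rng = np.random.default_rng(3)
        for seed in range(25):
            fx = simulate_protein_fixture(
                ProteinFixtureSpec(length=250, n_candidate_sites=3, n_labile=3,
                                   n_disulfides=int(rng.integers(0, 5)), seed=seed)
            )
            for pattern in enumerate_cleavage_patterns(list(fx.candidate_sites)):
                groups = fragment_groups(fx.chain, pattern, fx.disulfides)
                comps, intervals = groups_oracle(fx.chain, pattern, fx.disulfides)
                got = sorted(
                    sorted(intervals.index(f) for f in g.fragments) for g in groups
                )
                assert got == sorted(comps)

    def test_spanning_disulfides_give_single_group(self):
        # (2,6) bridges any cut at 3; (4,8) bridges any cut at 7; together
        # they span every fragmentation over sites {3, 7}
        chain = ProteinChain("GCGCGCGCGG")
        ss = DisulfideTopology(pairs=((2, 6), (4, 8)))
        for pattern in enumerate_cleavage_patterns([3, 7]):
            assert len(fragment_groups(chain, pattern, ss)) == 1

    def test_no_disulfides_groups_equal_fragments(self):
        chain = ProteinChain("G" * 20)
        groups = fragment_groups(chain, CleavagePattern((5, 11)), DisulfideTopology())
        assert [g.fragments for g in groups] == [((1, 5),), ((6, 11),), ((12, 20),)]


class TestRanking:
    def test_planted_cut_ranks_first_against_exact_bands(self):
        fx = simulate_protein_fixture(ProteinFixtureSpec(seed=5, n_labile=1))
        chain, ss = fx.chain, fx.disulfides
        true_pattern = fx.planted_pattern
        bands = [
            BandObservation(mass=group_mass(g, chain, ss) / 1000.0, tolerance=0.2)
            for g in fragment_groups(chain, true_pattern, ss)
        ]
        patterns = enumerate_cleavage_patterns(list(fx.candidate_sites))
        ranked = match_bands_and_rank(patterns, chain, ss, fx.triad, bands)
        assert ranked[0].pattern == true_pattern

    def test_inconsistent_bands_explain_nothing(self):
        chain = ProteinChain("G" * 100)
        patterns = enumerate_cleavage_patterns([40, 60])
        bands = [BandObservation(mass=50.0, tolerance=0.01)]
        ranked = match_bands_and_rank(patterns, chain, DisulfideTopology(), (), bands)
        assert all(rp.score[0] == 0 for rp in ranked)

    def test_tag_positive_band_selects_tag_retaining_pattern(self):
        tag = Tag("6xHis", "C", 822.85)
        seq = ["A"] * 200
        seq[59], seq[139] = "K", "K"
        chain = ProteinChain("".join(seq), tags=(tag,))
        ss = DisulfideTopology()
        # tag-positive band matching only the C-terminal fragment of a cut at 140
        g140 = fragment_groups(chain, CleavagePattern((140,)), ss)
        c_term = next(g for g in g140 if g.retains_tags)
        bands = [
            BandObservation(mass=group_mass(c_term, chain, ss) / 1000.0,
                            tolerance=0.3, tag_positive=True)
        ]
        ranked = match_bands_and_rank(
            enumerate_cleavage_patterns([60, 140], max_cuts=1), chain, ss, (), bands
        )
        assert ranked[0].pattern == CleavagePattern((140,))

    def test_empty_band_list_rejected(self):
        chain = ProteinChain("G" * 10)
        with pytest.raises(ValueError, match="no observations"):
            match_bands_and_rank(
                enumerate_cleavage_patterns([5]), chain, DisulfideTopology(), (), []
            )
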