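import math

import pytest

from crosspep.orthology import (
    CleavageContexts,
    MappedMarker,
    OrthologMap,
    cleavage_contexts,
    compare_panels,
    map_markers,
    select_top_markers,
    tier_match,
)
from crosspep.seqqc import SequencedMarker

PROTEIN = "MKTPGKQGAKGEPG"


def make_marker(
    sequence,
    protein_id="ratP",
    start=1,
    stop=None,
    regulation="up",
    p_adjusted=0.01,
    mean_case=200.0,
    mean_control=100.0,
    protein_name="COL1A1",
):
    stop = stop if stop is not None else start + len(sequence) - 1
    return SequencedMarker(
        sequence=sequence,
        protein_id=protein_id,
        protein_name=protein_name,
        start=start,
        stop=stop,
        regulation=regulation,
        p_adjusted=p_adjusted,
        mean_amp_case=mean_case,
        mean_amp_control=mean_control,
    )


def mapped(marker, n_ctx, c_ctx, n_complete=True, c_complete=True):
    ctx = CleavageContexts(n_ctx, c_ctx, n_complete, c_complete)
    return MappedMarker(marker=marker, context=ctx, all_contexts=[ctx])


IDENTITY = OrthologMap([("ratP", "humP", 0)])


class TestCleavageContexts:
    def test_worked_example(self):
        ctx = cleavage_contexts(PROTEIN, 7, 11)
        assert ctx.n_context == "PGKQGA"  # matches the PGK><QGA junction motif
        assert ctx.c_context == "AKGEPG"
        assert ctx.n_complete and ctx.c_complete

    def test_n_terminal_fragment_incomplete(self):
        ctx = cleavage_contexts(PROTEIN, 1, 6)
        assert not ctx.n_complete
        assert ctx.n_context == "MKT"

    def test_length_three_peptide_serves_both_halves(self):
        ctx = cleavage_contexts(PROTEIN, 7, 9)
        assert ctx.n_context == "PGKQGA"
        assert ctx.c_context == "QGAKGE"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cleavage_contexts(PROTEIN, 0, 5)


class TestTierMatch:
    def test_tier1_identity(self):
        rat = mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")
        assert tier_match(rat, hum, IDENTITY) == 1

    def test_tier2_one_shared_context(self):
        rat = mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKGEP", "humP", 7), "PGKQGA", "GEPGXX")
        assert tier_match(rat, hum, IDENTITY) == 2

    def test_tier3_overlap_two_residues(self):
        rat = mapped(make_marker("A" * 21, "ratP", 100, 120), "XXXXXX", "YYYYYY")
        hum = mapped(make_marker("A" * 22, "humP", 119, 140), "AAAAAA", "BBBBBB")
        # intervals (100,120) and (119,140) share residues 119-120
        assert tier_match(rat, hum, IDENTITY) == 3

    def test_overlap_one_residue_no_match(self):
        rat = mapped(make_marker("A" * 21, "ratP", 100, 120), "XXXXXX", "YYYYYY")
        hum = mapped(make_marker("A" * 21, "humP", 120, 140), "AAAAAA", "BBBBBB")
        assert tier_match(rat, hum, IDENTITY) is None

    def test_regulation_gate(self):
        rat = mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(
            make_marker("QGAKG", "humP", 7, regulation="down"), "PGKQGA", "AKGEPG"
        )
        assert tier_match(rat, hum, IDENTITY) is None

    def test_unregulated_marker_excluded(self):
        rat = mapped(make_marker("QGAKG", "ratP", 7, regulation=None), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")
        assert tier_match(rat, hum, IDENTITY) is None

    def test_unpaired_proteins_no_match(self):
        rat = mapped(make_marker("QGAKG", "otherP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")
        assert tier_match(rat, hum, IDENTITY) is None

    def test_tier_monotonicity(self):
        # a tier-1 pair also satisfies the one-site and overlap conditions;
        # the reported tier is the highest one
        rat = mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")
        assert tier_match(rat, hum, IDENTITY) == 1
        # break the sequence identity only: falls to tier 2, not none
        hum2 = mapped(make_marker("QGAKGX", "humP", 7, stop=12), "PGKQGA", "AKGEPG")
        assert tier_match(rat, hum2, IDENTITY) == 2

    def test_offset_applied_to_rat_coordinates(self):
        omap = OrthologMap([("ratP", "humP", 10)])
        rat = mapped(make_marker("A" * 11, "ratP", 100, 110), "XXXXXX", "YYYYYY")
        hum = mapped(make_marker("A" * 11, "humP", 115, 125), "AAAAAA", "BBBBBB")
        # rat shifted to 110-120: overlap with 115-125 is 6 residues
        assert tier_match(rat, hum, omap) == 3

    def test_symmetry_under_map_inversion(self):
        rat = mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG")
        hum = mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")
        inverted = OrthologMap([("humP", "ratP", 0)])
        assert tier_match(rat, hum, IDENTITY) == tier_match(hum, rat, inverted)


class TestComparePanels:
    def test_reflexive_panel_all_tier1(self):
        markers = [
            mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG"),
            mapped(make_marker("KTPGK", "ratP", 2), "MKTPGK", "PGKQGA"),
        ]
        partner = [
            mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG"),
            mapped(make_marker("KTPGK", "humP", 2), "MKTPGK", "PGKQGA"),
        ]
        comparison = compare_panels(markers, partner, IDENTITY)
        assert comparison.tier_counts == {1: 2, 2: 0, 3: 0}

    def test_disjoint_proteins_zero_matches(self):
        rat = [mapped(make_marker("QGAKG", "ratX", 7), "PGKQGA", "AKGEPG")]
        hum = [mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG")]
        comparison = compare_panels(rat, hum, IDENTITY)
        assert comparison.tier_counts == {1: 0, 2: 0, 3: 0}

    def test_one_pair_per_tier(self):
        rat = [
            mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG"),
            mapped(make_marker("GAKGE", "ratP", 8), "GKQGAK", "KGEPGX"),
            mapped(make_marker("A" * 21, "ratP", 100, 120), "ZZZZZZ", "WWWWWW"),
        ]
        hum = [
            mapped(make_marker("QGAKG", "humP", 7), "PGKQGA", "AKGEPG"),  # tier 1
            mapped(make_marker("GAKGEP", "humP", 8, stop=13), "GKQGAK", "EPGXYZ"),  # tier 2
            mapped(make_marker("A" * 22, "humP", 119, 140), "QQQQQQ", "VVVVVV"),  # tier 3
        ]
        comparison = compare_panels(rat, hum, IDENTITY)
        assert comparison.tier_counts == {1: 1, 2: 1, 3: 1}

    def test_empty_panels(self):
        comparison = compare_panels([], [], IDENTITY)
        assert comparison.tier_counts == {1: 0, 2: 0, 3: 0}

    def test_regulation_summary(self):
        rat = [
            mapped(make_marker("QGAKG", "ratP", 7), "PGKQGA", "AKGEPG"),
            mapped(make_marker("GAKGE", "ratP", 8, regulation="down"), "AAAAAA", "BBBBBB"),
        ]
        comparison = compare_panels(rat, [], IDENTITY)
        assert comparison.regulation_summary[("rat", "COL1A1")] == (1, 1)


class TestMapMarkers:
    def test_maps_and_extracts_contexts(self):
        proteins = {"ratP": PROTEIN}
        markers = [make_marker("QGAKG", "ratP", 7)]
        mapped_list, failed = map_markers(markers, proteins)
        assert not failed
        assert mapped_list[0].context.n_context == "PGKQGA"

    def test_unmappable_reported(self):
        proteins = {"ratP": PROTEIN}
        markers = [make_marker("WWWWW", "ratP", 1)]
        mapped_list, failed = map_markers(markers, proteins)
        assert not mapped_list and len(failed) == 1

    def test_repeat_occurrences_deduplicated_contexts(self):
        proteins = {"ratP": "AGPGAGPGA"}
        markers = [make_marker("GPG", "ratP", 2, 4)]
        mapped_list, _ = map_markers(markers, proteins)
        # two occurrences, distinct context strings retained separately
        assert len(mapped_list[0].all_contexts) == 2


class TestSelectTop:
    def test_small_panel_returned_whole(self):
        panel = [make_marker("AAA", p_adjusted=p) for p in (0.1, 0.2, 0.3)]
        assert len(select_top_markers(panel, n=50)) == 3

    def test_n_smallest(self):
        panel = [
            make_marker(f"SEQ{i}", p_adjusted=p)
            for i, p in enumerate([0.5, 0.01, 0.3, 0.02])
        ]
        top = select_top_markers(panel, n=2)
        assert [m.p_adjusted for m in top] == [0.01, 0.02]

    def test_deterministic_tie_break(self):
        panel = [
            make_marker("BBB", p_adjusted=0.01, mean_case=150, mean_control=100),
            make_marker("AAA", p_adjusted=0.01, mean_case=400, mean_control=100),
            make_marker("CCC", p_adjusted=0.01, mean_case=150, mean_control=100),
        ]
        top1 = select_top_markers(panel, n=2)
        top2 = select_top_markers(list(reversed(panel)), n=2)
        assert [m.sequence for m in top1] == [m.sequence for m in top2] == ["AAA", "BBB"]


def test_ortholog_map_rejects_duplicates():
    with pytest.raises(ValueError):
        OrthologMap([("r1", "h1", 0), ("r1", "h2", 0)])
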