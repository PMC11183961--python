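import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_pathway_status
from ironmeta.abundance import SampleAbundanceProfile
from ironmeta.errors import ParseError, ValidationError
from ironmeta.functions import SYNTHESIS
from ironmeta.pathways import (
    PathwayDefinitionRow,
    PathwayNetwork,
    PathwayStatus,
    call_all_pathways,
    classify_pathway,
    detected_cogs,
    quantify_synthesis,
    read_pathway_table,
)


def net_from(triples, ambiguous=()):
    rows = [
        PathwayDefinitionRow(p, g, c, ambiguous=c in ambiguous) for p, g, c in triples
    ]
    return PathwayNetwork.from_rows(rows)


def profile(cog_coverage, median=2.0, sample="s"):
    return SampleAbundanceProfile(
        sample_id=sample,
        orf_coverage={},
        cog_coverage=cog_coverage,
        marker_median=median,
    )


class TestNetworkConstruction:
    def test_shared_cog_single_node(self):
        net = net_from([("P1", "gA", "C1"), ("P1", "gB", "C2"), ("P2", "gC", "C2")])
        assert net.cog_pathways["C2"] == {"P1", "P2"}
        assert net.unique_cogs == {"C1"}

    def test_gene_with_two_cogs(self):
        """A dhbE-like gene assigned to two COGs is one gene with two edges."""
        net = net_from([("P1", "dhbE", "C0318"), ("P1", "dhbE", "C1021")])
        assert net.pathways["P1"] == {"dhbE"}
        assert net.gene_cogs[("P1", "dhbE")] == {"C0318", "C1021"}

    def test_duplicate_triple_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            net_from([("P1", "g", "C1"), ("P1", "g", "C1")])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("pathway_id\tgene_id\tcog_id\tambiguous_flag\n")
        with pytest.raises(ValidationError, match="no pathways"):
            read_pathway_table(path)

    def test_bad_flag_rejected(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("P1\tg\tC1\tmaybe\n")
        with pytest.raises(ParseError, match="boolean"):
            read_pathway_table(path)

    def test_ambiguous_never_unique(self):
        net = net_from([("P1", "g", "C1")], ambiguous={"C1"})
        assert net.unique_cogs == set()
        assert not net.ambiguous_cogs & net.unique_cogs

    def test_bundled_network_shape(self, network):
        assert len(network.pathways) == 12
        assert "COG0318" in network.ambiguous_cogs
        # the promiscuous NRPS-adjacent COGs appear in many pathways
        assert len(network.cog_pathways["COG0318"]) == 9


class TestClassify:
    def test_one_missing_gene_is_absent(self):
        """Amphibactin-like case: every gene found but one -> whole pathway absent."""
        net = net_from(
            [("amp", "gA", "C1"), ("amp", "gB", "C2"), ("amp", "gC", "C3")]
        )
        call = classify_pathway("amp", net, {"C1", "C2"})
        assert call.status == PathwayStatus.ABSENT
        assert call.missing_genes == {"gC"}

    def test_all_shared_is_maybe(self):
        """Ferrioxamine-like case: complete but nothing unique -> MAYBE."""
        net = net_from(
            [
                ("fox", "gA", "C1"), ("fox", "gB", "C2"),
                ("other", "gX", "C1"), ("other", "gY", "C2"),
            ]
        )
        call = classify_pathway("fox", net, {"C1", "C2"})
        assert call.status == PathwayStatus.MAYBE
        assert call.supporting_unique_cogs == frozenset()

    def test_unique_unambiguous_is_present(self):
        net = net_from([("P1", "gA", "C1"), ("P1", "gB", "C2"), ("P2", "gX", "C2")])
        call = classify_pathway("P1", net, {"C1", "C2"})
        assert call.status == PathwayStatus.PRESENT
        assert call.supporting_unique_cogs == {"C1"}

    def test_ambiguous_counts_for_presence_not_uniqueness(self):
        net = net_from([("P1", "gA", "C1"), ("P1", "gB", "C2")], ambiguous={"C1"})
        call = classify_pathway("P1", net, {"C1", "C2"})
        # complete (C1 satisfies gA) and C2 unique -> PRESENT via C2 only
        assert call.status == PathwayStatus.PRESENT
        assert call.supporting_unique_cogs == {"C2"}
        # with only the ambiguous COG detected, gB is missing -> ABSENT
        assert classify_pathway("P1", net, {"C1"}).status == PathwayStatus.ABSENT

    def test_unknown_pathway(self):
        net = net_from([("P1", "g", "C1")])
        with pytest.raises(ValidationError, match="unknown pathway"):
            classify_pathway("P9", net, set())

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_detected_cogs(self, data):
        """Adding a detected COG never demotes a pathway's status."""
        net = net_from(
            [
                ("P1", "gA", "C1"), ("P1", "gA", "C2"), ("P1", "gB", "C3"),
                ("P2", "gX", "C3"), ("P2", "gY", "C4"),
                ("P3", "gZ", "C5"), ("P3", "gW", "C2"),
            ],
            ambiguous={"C2"},
        )
        universe = sorted(net.all_cogs)
        present = set(data.draw(st.lists(st.sampled_from(universe), unique=True)))
        extra = data.draw(st.sampled_from(universe))
        for pid in net.pathways:
            before = classify_pathway(pid, net, present).status
            after = classify_pathway(pid, net, present | {extra}).status
            assert after >= before

    def test_exhaustive_oracle_small_network(self):
        net = net_from(
            [
                ("P1", "gA", "C1"), ("P1", "gA", "C2"), ("P1", "gB", "C3"),
                ("P2", "gX", "C3"), ("P2", "gY", "C4"),
            ],
            ambiguous={"C1"},
        )
        universe = sorted(net.all_cogs)
        for r in range(len(universe) + 1):
            for subset in itertools.combinations(universe, r):
                present = set(subset)
                for pid in net.pathways:
                    assert (
                        classify_pathway(pid, net, present).status
                        == brute_force_pathway_status(pid, net, present)
                    )


class TestDetection:
    def test_floor_strict(self):
        prof = profile({"COG1629": 3.0, "COG0609": 0.0})
        assert detected_cogs(prof) == {"COG1629"}
        assert detected_cogs(prof, min_coverage=2.9) == {"COG1629"}
        assert detected_cogs(prof, min_coverage=3.0) == set()

    def test_empty_profile(self):
        assert detected_cogs(profile({})) == set()


class TestQuantifySynthesis:
    def test_ambiguous_only_signal_is_zero(self, network, catalog):
        prof = profile({"COG0318": 5.0})
        assert quantify_synthesis(prof, network, catalog) == 0.0
        # ...while the same COG still counts for gene presence (criterion 1)
        present = detected_cogs(prof)
        call = classify_pathway("enterobactin", network, present)
        assert "entE" not in call.missing_genes

    def test_single_unambiguous_term(self, network, catalog):
        prof = profile({"COG1535": 5.0}, median=2.0)
        assert quantify_synthesis(prof, network, catalog) == pytest.approx(2.5)

    def test_mixture_hand_summed(self, network, catalog):
        # 4-COG mixture: unambiguous 3.0 + 1.0; ambiguous 5.0 + 2.0 excluded
        prof = profile(
            {"COG1535": 3.0, "COG1819": 1.0, "COG0318": 5.0, "COG1020": 2.0},
            median=2.0,
        )
        assert quantify_synthesis(prof, network, catalog) == pytest.approx(2.0)

    def test_never_exceeds_full_category_cn(self, network, catalog):
        prof = profile(
            {"COG1535": 3.0, "COG0318": 5.0, "COG1629": 4.0}, median=2.0
        )
        full = (
            sum(
                v
                for c, v in prof.cog_coverage.items()
                if c in catalog and catalog[c].category == SYNTHESIS
            )
            / prof.marker_median
        )
        assert quantify_synthesis(prof, network, catalog) <= full


class TestCallAllPathways:
    def test_study_level_best_status(self):
        net = net_from([("P1", "gA", "C1"), ("P1", "gB", "C2")])
        p_absent = profile({"C1": 1.0}, sample="s1")
        p_present = profile({"C1": 1.0, "C2": 1.0}, sample="s2")
        table = call_all_pathways(net, [p_absent, p_present])
        assert table.loc["s1", "P1"] == "ABSENT"
        assert table.loc["s2", "P1"] == "PRESENT"
        assert table.loc["study", "P1"] == "PRESENT"

    def test_absent_everywhere(self):
        net = net_from([("P1", "gA", "C1")])
        table = call_all_pathways(net, [profile({}, sample="s1")])
        assert table.loc["study", "P1"] == "ABSENT"

    def test_empty_profiles(self, network):
        assert call_all_pathways(network, []).empty
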