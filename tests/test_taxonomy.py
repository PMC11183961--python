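"""Unit and property tests of valid-hit selection, LCA, consensus and
read-fraction aggregation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mk_hit
from ironmeta.errors import UnknownTaxonError, ValidationError
from ironmeta.taxonomy import (
    ConsensusParams,
    LcaParams,
    OrfTaxonomy,
    assign_orf_lca,
    consensus_contig_taxonomy,
    select_valid_hits,
    taxon_read_fractions,
)
from ironmeta.taxtree import UNCLASSIFIED, rank_depth


class TestSelectValidHits:
    def test_bitscore_window_boundary(self):
        hits = [mk_hit(bitscore=b, identity=60.0) for b in (100.0, 85.0, 79.0)]
        kept = select_valid_hits(hits)
        assert [h.bitscore for h in kept] == [100.0, 85.0]

    def test_bitscore_exactly_80_percent_is_retained(self):
        hits = [mk_hit(bitscore=100.0), mk_hit(bitscore=80.0)]
        assert len(select_valid_hits(hits)) == 2

    def test_evalue_cutoff(self):
        assert select_valid_hits([mk_hit(evalue=1e-2)]) == []
        assert len(select_valid_hits([mk_hit(evalue=1e-3)])) == 1  # boundary kept

    def test_relative_identity_window_boundary(self):
        best = mk_hit(identity=60.0, bitscore=100.0)
        at = mk_hit(identity=6.0, bitscore=95.0)
        below = mk_hit(identity=5.9, bitscore=95.0)
        kept = select_valid_hits([best, at, below])
        assert at in kept and below not in kept

    def test_absolute_identity_window(self):
        params = LcaParams(identity_mode="absolute")
        best = mk_hit(identity=60.0, bitscore=100.0)
        near = mk_hit(identity=50.0, bitscore=95.0)
        far = mk_hit(identity=49.9, bitscore=95.0)
        kept = select_valid_hits([best, near, far], params)
        assert near in kept and far not in kept

    def test_empty_in_empty_out(self):
        assert select_valid_hits([]) == []

    def test_best_hit_tie_breaks_deterministic(self):
        a = mk_hit(identity=90.0, bitscore=100.0, evalue=1e-30)
        b = mk_hit(identity=95.0, bitscore=100.0, evalue=1e-40)
        from ironmeta.io import best_hit

        assert best_hit([a, b]) is b  # lower e-value wins the tie


class TestAssignOrfLca:
    def test_single_species_hit_high_identity(self, toy_tree):
        result = assign_orf_lca("o", [mk_hit(taxon="s1", identity=90.0)], toy_tree)
        assert (result.assigned_taxon, result.assigned_rank) == ("s1", "species")

    def test_nine_of_ten_support_boundary(self, toy_tree):
        hits = [mk_hit(taxon="s1", identity=70.0) for _ in range(9)]
        hits.append(mk_hit(taxon="s3", identity=70.0))  # other genus, same family
        result = assign_orf_lca("o", hits, toy_tree)
        # 9/10 = 90% support at genus g1; identity 70 >= genus floor 60
        assert (result.assigned_taxon, result.assigned_rank) == ("g1", "genus")
        # 8/10 fails: falls to family where 10/10 agree
        hits[8] = mk_hit(taxon="s3", identity=70.0)
        result = assign_orf_lca("o", hits, toy_tree)
        assert (result.assigned_taxon, result.assigned_rank) == ("f1", "family")

    def test_identity_floor_truncates_to_phylum(self, toy_tree):
        hits = [mk_hit(taxon="s1", identity=45.0) for _ in range(3)]
        result = assign_orf_lca("o", hits, toy_tree)
        # unanimous at species but 45 < 46 (class floor) and >= 42 (phylum floor)
        assert (result.assigned_taxon, result.assigned_rank) == ("p1", "phylum")

    def test_identity_exactly_at_floor_assigns_that_rank(self, toy_tree):
        result = assign_orf_lca("o", [mk_hit(taxon="s1", identity=60.0)], toy_tree)
        assert result.assigned_rank == "genus"

    def test_below_superkingdom_floor_is_unclassified(self, toy_tree):
        result = assign_orf_lca("o", [mk_hit(taxon="s1", identity=39.0)], toy_tree)
        assert not result.classified

    def test_unlabeled_hits_count_in_denominator(self, toy_tree):
        hits = [mk_hit(taxon="s1", identity=90.0)] + [
            mk_hit(taxon="", identity=90.0) for _ in range(9)
        ]
        result = assign_orf_lca("o", hits, toy_tree)
        assert not result.classified  # 1/10 support everywhere

    def test_unknown_taxon_raises(self, toy_tree):
        with pytest.raises(UnknownTaxonError, match="ghost"):
            assign_orf_lca("o", [mk_hit(taxon="ghost")], toy_tree)

    def test_no_hits_unclassified(self, toy_tree):
        result = assign_orf_lca("o", [], toy_tree)
        assert not result.classified and result.n_valid_hits == 0

    @given(
        identities=st.lists(
            st.floats(min_value=40, max_value=100, allow_nan=False), min_size=1, max_size=6
        ),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_support_monotonicity(self, toy_tree, identities, data):
        """Raising the support fraction never deepens the assigned rank."""
        taxa = data.draw(
            st.lists(
                st.sampled_from(["s1", "s2", "s3", "s4", ""]),
                min_size=len(identities),
                max_size=len(identities),
            )
        )
        hits = [mk_hit(taxon=t, identity=i) for t, i in zip(taxa, identities)]
        lo = assign_orf_lca("o", hits, toy_tree, LcaParams(support_fraction=0.5))
        hi = assign_orf_lca("o", hits, toy_tree, LcaParams(support_fraction=0.95))
        depth = lambda r: rank_depth(r.assigned_rank) if r.classified else -1  # noqa: E731
        assert depth(hi) <= depth(lo)

    @given(
        best=st.floats(min_value=40, max_value=100, allow_nan=False),
        drop=st.floats(min_value=0.5, max_value=30),
        taxon=st.sampled_from(["s1", "s3", "s4"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identity_monotonicity(self, toy_tree, best, drop, taxon):
        """Lowering the best identity never deepens the assigned rank."""
        high = assign_orf_lca("o", [mk_hit(taxon=taxon, identity=best)], toy_tree)
        lower = max(best - drop, 0.0)
        low = assign_orf_lca("o", [mk_hit(taxon=taxon, identity=lower)], toy_tree)
        depth = lambda r: rank_depth(r.assigned_rank) if r.classified else -1  # noqa: E731
        assert depth(low) <= depth(high)


def ot(taxon, i=[0]):
    i[0] += 1
    return OrfTaxonomy(f"orf{i[0]}", taxon, None if taxon is None else "any", 90.0, 1)


class TestConsensus:
    def test_unanimity(self, toy_tree):
        taxon, rank = consensus_contig_taxonomy([ot("g1") for _ in range(4)], toy_tree)
        assert (taxon, rank) == ("g1", "genus")

    def test_boundary_thresholds_met(self, toy_tree):
        orfs = [ot("p1")] * 5 + [ot("p2")] * 1 + [ot(None)] * 4
        taxon, rank = consensus_contig_taxonomy(orfs, toy_tree)
        # 5/10 = 50% of all, 5/6 ~ 83% of annotated at phylum
        assert (taxon, rank) == ("p1", "phylum")

    def test_fraction_of_all_fails(self, toy_tree):
        orfs = [ot("p1")] * 4 + [ot(None)] * 6
        assert consensus_contig_taxonomy(orfs, toy_tree) == (None, None)

    def test_parent_consistency_limits_descent(self, toy_tree):
        # 6 ORFs agree at phylum p1; below, g1 has only 3 of 6 annotated
        orfs = [ot("s1")] * 3 + [ot("s3")] * 3
        taxon, rank = consensus_contig_taxonomy(orfs, toy_tree)
        assert (taxon, rank) == ("f1", "family")  # splits between g1/g2 below

    def test_empty_collection_rejected(self, toy_tree):
        with pytest.raises(ValidationError):
            consensus_contig_taxonomy([], toy_tree)

    @given(data=st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_consensus_containment_and_oracle(self, toy_tree, data):
        """The consensus satisfies the thresholds along its whole ancestor
        chain (checked against a node-by-node oracle), so the taxon at any
        shallower rank is always its ancestor."""
        from _oracles import brute_force_consensus

        choices = ["s1", "s2", "s3", "s4", "g1", "p1", "p2", "k_bac", None]
        taxa = data.draw(st.lists(st.sampled_from(choices), min_size=1, max_size=10))
        orfs = [ot(t) for t in taxa]
        params = ConsensusParams()
        result = consensus_contig_taxonomy(orfs, toy_tree, params)
        assert result == brute_force_consensus(orfs, toy_tree, params)


class TestReadFractions:
    def test_direct_proportion(self, toy_tree):
        result = taxon_read_fractions(
            {"A": "p1", "B": "p2"}, {"A": 70, "B": 30}, toy_tree, "phylum"
        )
        assert result == {"p1": 0.7, "p2": 0.3}

    def test_unclassified_bucket(self, toy_tree):
        result = taxon_read_fractions(
            {"A": "p1", "B": None}, {"A": 90, "B": 10}, toy_tree, "phylum"
        )
        assert result[UNCLASSIFIED] == pytest.approx(0.10)

    def test_lineage_rollup_hand_summed(self, toy_tree):
        # five contigs, classified at mixed depths; hand-summed phylum totals:
        # p1: A(10 via g1) + B(20 via s2) + C(5 at p1) = 35; p2: D(40 via s4);
        # unclassified: E(25, classified only at superkingdom -> no phylum)
        contigs = {"A": "g1", "B": "s2", "C": "p1", "D": "s4", "E": "k_bac"}
        reads = {"A": 10, "B": 20, "C": 5, "D": 40, "E": 25}
        result = taxon_read_fractions(contigs, reads, toy_tree, "phylum")
        assert result == pytest.approx(
            {"p1": 0.35, "p2": 0.40, UNCLASSIFIED: 0.25}
        )

    def test_zero_reads_rejected(self, toy_tree):
        with pytest.raises(ValidationError):
            taxon_read_fractions({"A": "p1"}, {"A": 0}, toy_tree, "phylum")

    @given(
        reads=st.lists(st.integers(0, 1000), min_size=1, max_size=8),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fractions_sum_to_one(self, toy_tree, reads, data):
        if sum(reads) == 0:
            return
        taxa = data.draw(
            st.lists(
                st.sampled_from(["s1", "s3", "s4", "g1", "p2", None]),
                min_size=len(reads),
                max_size=len(reads),
            )
        )
        contigs = {f"c{i}": t for i, t in enumerate(taxa)}
        counts = {f"c{i}": r for i, r in enumerate(reads)}
        result = taxon_read_fractions(contigs, counts, toy_tree, "phylum")
        assert sum(result.values()) == pytest.approx(1.0, abs=1e-9)
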