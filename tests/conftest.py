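import pytest

from ironmeta import HitRecord, TaxonomyNode, TaxonomyTree
from ironmeta.functions import bundled_iron_catalog
from ironmeta.pathways import bundled_pathway_network


def make_tree(edges):
    """Build a tree from (taxon_id, parent_id, rank) triples."""
    return TaxonomyTree(TaxonomyNode(t, p, r, t) for t, p, r in edges)


@pytest.fixture(scope="session")
def toy_tree():
    """Two superkingdoms, full 7-rank ladders, with sibling species/genera.

    Bact: k_bac > p1 > c1 > o1 > f1 > (g1 > s1, s2; g2 > s3) and
          k_bac > p2 > c2 > o2 > f2 > g3 > s4
    Arch: k_arc > p3 > c3 > o3 > f3 > g4 > s5
    """
    edges = [
        ("root", "", "norank"),
        ("k_bac", "root", "superkingdom"),
        ("k_arc", "root", "superkingdom"),
        ("p1", "k_bac", "phylum"),
        ("p2", "k_bac", "phylum"),
        ("p3", "k_arc", "phylum"),
        ("c1", "p1", "class"),
        ("c2", "p2", "class"),
        ("c3", "p3", "class"),
        ("o1", "c1", "order"),
        ("o2", "c2", "order"),
        ("o3", "c3", "order"),
        ("f1", "o1", "family"),
        ("f2", "o2", "family"),
        ("f3", "o3", "family"),
        ("g1", "f1", "genus"),
        ("g2", "f1", "genus"),
        ("g3", "f2", "genus"),
        ("g4", "f3", "genus"),
        ("s1", "g1", "species"),
        ("s2", "g1", "species"),
        ("s3", "g2", "species"),
        ("s4", "g3", "species"),
        ("s5", "g4", "species"),
    ]
    return make_tree(edges)


@pytest.fixture(scope="session")
def catalog():
    return bundled_iron_catalog()


@pytest.fixture(scope="session")
def network():
    return bundled_pathway_network()


_counter = 0


def mk_hit(
    taxon="",
    identity=90.0,
    bitscore=100.0,
    evalue=1e-20,
    cog="",
    query="orf1",
    subject=None,
):
    global _counter
    _counter += 1
    return HitRecord(
        query_id=query,
        subject_id=subject or f"subj{_counter}",
        percent_identity=identity,
        alignment_length=100,
        bitscore=bitscore,
        evalue=evalue,
        subject_taxon=taxon,
        subject_cog=cog,
    )
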