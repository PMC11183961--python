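"""Classify one ORF's homology hits with the rank-floored LCA and build a
contig consensus.

Ten hits, nine of them from the same genus, exercise the 90% support rule;
the best identity (70%) clears the genus floor (60%) but not the species
floor (85%), so the call lands at genus even though every hit is a species.
"""

from ironmeta import (
    HitRecord,
    TaxonomyNode,
    TaxonomyTree,
    assign_orf_lca,
    consensus_contig_taxonomy,
    select_valid_hits,
)

tree = TaxonomyTree(
    TaxonomyNode(t, p, r, t)
    for t, p, r in [
        ("root", "", "norank"),
        ("Bacteria", "root", "superkingdom"),
        ("Bacteroidetes", "Bacteria", "phylum"),
        ("Flavobacteriia", "Bacteroidetes", "class"),
        ("Flavobacteriales", "Flavobacteriia", "order"),
        ("Flavobacteriaceae", "Flavobacteriales", "family"),
        ("Polaribacter", "Flavobacteriaceae", "genus"),
        ("P_irgensii", "Polaribacter", "species"),
        ("P_dokdonensis", "Polaribacter", "species"),
    ]
)

hits = [
    HitRecord("orf1", f"ref{i}", 70.0, 150, 200.0 - i, 1e-40, "P_irgensii")
    for i in range(9)
]
hits.append(HitRecord("orf1", "ref9", 68.0, 150, 185.0, 1e-38, "P_dokdonensis"))

valid = select_valid_hits(hits)
result = assign_orf_lca("orf1", valid, tree)
print(f"valid hits: {len(valid)} of {len(hits)}")
print(f"ORF assigned to {result.assigned_taxon} at rank {result.assigned_rank} "
      f"(best identity {result.best_identity:.0f}%)")

taxon, rank = consensus_contig_taxonomy([result] * 4, tree)
print(f"contig of four such ORFs -> consensus {taxon} at {rank}")
print()
print(
    "9/10 support fails at species (each species has <90%), succeeds at genus "
    "(10/10); identity 70% then truncates nothing further since 70 >= 60."
)
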