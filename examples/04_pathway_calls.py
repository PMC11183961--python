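"""Call siderophore biosynthesis pathways from a detected-COG profile.

Uses the bundled 12-pathway network. With the producer's full synthesis
complement detected, eight pathways are PRESENT and four ABSENT (amphibactin
misses exactly one gene). A ferrioxamine-like pair whose genes are all shared
between the two pathways shows the third outcome: complete but not provably
present, so MAYBE.
"""

from ironmeta import bundled_pathway_network, classify_pathway
from ironmeta.pathways import PathwayDefinitionRow, PathwayNetwork
from ironmeta.simulate import default_genomes
from ironmeta.abundance import default_marker_set

network = bundled_pathway_network()
producer = next(
    g for g in default_genomes(default_marker_set().cog_ids) if g.role == "producer"
)
detected = set(producer.gene_complement)

print(f"{'pathway':20s} status   (missing genes / unique support)")
for pid in sorted(network.pathways):
    call = classify_pathway(pid, network, detected)
    extra = (
        f"missing: {sorted(call.missing_genes)}"
        if call.missing_genes
        else f"unique: {sorted(call.supporting_unique_cogs)}"
    )
    print(f"{pid:20s} {call.status.name:8s} {extra}")

# two pathways sharing every COG: complete, but neither is provable
fox = PathwayNetwork.from_rows(
    [
        PathwayDefinitionRow(p, g, c)
        for p, g, c in [
            ("ferrioxamine_B", "desA", "COGF1"), ("ferrioxamine_B", "desD", "COGF2"),
            ("ferrioxamine_E", "desA", "COGF1"), ("ferrioxamine_E", "desD", "COGF2"),
        ]
    ]
)
call = classify_pathway("ferrioxamine_B", fox, {"COGF1", "COGF2"})
print(f"\nferrioxamine_B, all genes found but all shared -> {call.status.name}")
print(
    "\nPRESENT needs completeness plus a COG unique to the pathway; ambiguous "
    "COGs (e.g. COG0318) count toward completeness but never toward uniqueness."
)
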