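"""Independent brute-force oracles for the rule-based operations.

These evaluate the written rules node by node / subset by subset, without
sharing code paths with the implementations they check: the LCA oracle tests
every tree node by lineage membership, the consensus oracle tests every node
with full ancestor-chain qualification, and the pathway oracle is a literal
transcription of the three presence criteria.
"""

from fractions import Fraction

from ironmeta.io import best_hit
from ironmeta.pathways import PathwayStatus
from ironmeta.taxtree import RANKS, rank_depth


def _F(x):
    return Fraction(str(x))


def brute_force_lca(valid_hits, tree, params):
    """Node-by-node evaluation of the support + identity-floor rules.

    Returns (taxon, rank) or (None, None).
    """
    n = len(valid_hits)
    if n == 0:
        return None, None
    identity = best_hit(list(valid_hits)).percent_identity
    need = _F(params.support_fraction) * n
    supported = []
    for node in tree:
        rank = tree.rank_of(node)
        if rank not in RANKS:
            continue
        count = sum(
            1
            for h in valid_hits
            if h.subject_taxon and node in tree.lineage(h.subject_taxon)
        )
        if Fraction(count) >= need:
            supported.append((rank_depth(rank), node))
    if not supported:
        return None, None
    depth, node = max(supported)
    # deepest rank at or above the candidate whose floor the identity clears
    for anc in reversed(tree.lineage(node)):
        r = tree.rank_of(anc)
        if r not in RANKS or rank_depth(r) > depth:
            continue
        floor = params.rank_floors.get(r)
        if floor is not None and _F(identity) >= _F(floor):
            return anc, r
    return None, None


def brute_force_consensus(orf_taxonomies, tree, params):
    """Deepest node whose whole ancestor chain satisfies the 50%/70% rule.

    A node qualifies at its rank when it covers >= min_fraction_all of all
    ORFs and >= min_fraction_annotated of the ORFs annotated at that rank
    (by lineage membership). The consensus is the deepest ladder-rank node
    that qualifies and whose every ladder-rank ancestor, at ranks where any
    ORF is annotated, also qualifies.
    """
    total = len(orf_taxonomies)
    f_all = _F(params.min_fraction_all)
    f_ann = _F(params.min_fraction_annotated)

    lineages = [
        set(tree.lineage(ot.assigned_taxon)) if ot.classified else set()
        for ot in orf_taxonomies
    ]

    def annotated_at(rank):
        return sum(
            1
            for lin in lineages
            if any(tree.rank_of(t) == rank for t in lin)
        )

    def qualifies(node):
        rank = tree.rank_of(node)
        ann = annotated_at(rank)
        if ann == 0:
            return False
        count = sum(1 for lin in lineages if node in lin)
        return Fraction(count, total) >= f_all and Fraction(count, ann) >= f_ann

    best = (None, None)
    best_depth = -1
    for node in tree:
        rank = tree.rank_of(node)
        if rank not in RANKS or not qualifies(node):
            continue
        chain_ok = True
        for anc in tree.lineage(node)[:-1]:
            r = tree.rank_of(anc)
            if r not in RANKS:
                continue
            if annotated_at(r) == 0:
                continue  # skipped rank
            if not qualifies(anc):
                chain_ok = False
                break
        if chain_ok and rank_depth(rank) > best_depth:
            best = (node, rank)
            best_depth = rank_depth(rank)
    return best


def brute_force_pathway_status(pathway_id, network, present_cogs):
    """Literal transcription of the three presence criteria."""
    genes = network.pathways[pathway_id]
    # criterion 3 / 1: every gene must be present
    for gene in genes:
        if not any(c in present_cogs for c in network.gene_cogs[(pathway_id, gene)]):
            return PathwayStatus.ABSENT
    # criterion 2: at least one detected gene unique to this pathway
    for gene in genes:
        for cog in network.gene_cogs[(pathway_id, gene)]:
            if cog not in present_cogs or cog in network.ambiguous_cogs:
                continue
            in_pathways = {
                pid
                for (pid, _g), cogs in network.gene_cogs.items()
                if cog in cogs
            }
            if in_pathways == {pathway_id}:
                return PathwayStatus.PRESENT
    return PathwayStatus.MAYBE
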