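"""Ranked taxonomy tree: the substrate for LCA and consensus calls.

The tree uses the seven-rank ladder superkingdom > phylum > class > order >
family > genus > species. Nodes whose rank is outside the ladder are stored
as ``norank``; they participate in lineages but are never the level at which
an assignment is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import TaxonomyStructureError

#: Rank ladder from root-most to leaf-most.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NORANK = "norank"

#: Strings accepted in the parent_id column to mark the root node.
ROOT_MARKERS = frozenset({"", "."})

#: Label used for the explicit unclassified bucket in read-fraction tables.
UNCLASSIFIED = "Unclassified"


def rank_depth(rank: str) -> int:
    """Position of a rank in the ladder (0 = superkingdom); -1 for norank."""
    try:
        return RANKS.index(rank)
    except ValueError:
        return -1


@dataclass(frozen=True, slots=True)
class TaxonomyNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str = ""


class TaxonomyTree:
    """A validated, single-rooted ranked taxonomy.

    Construction checks the three structural invariants: exactly one root,
    acyclic parent links, and every node reachable from the root. Ranks
    outside the ladder are coerced to ``norank``.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyStructureError(
                    f"duplicate taxon_id {node.taxon_id!r}"
                )
            rank = node.rank if node.rank in RANKS else NORANK
            if rank != node.rank:
                node = TaxonomyNode(node.taxon_id, node.parent_id, rank, node.name)
            self._nodes[node.taxon_id] = node
        self.root_id = self._validate()
        self._lineage_cache: dict[str, tuple[str, ...]] = {}

    def _validate(self) -> str:
        roots = [
            t for t, n in self._nodes.items() if n.parent_id in ROOT_MARKERS
        ]
        if len(roots) == 0:
            raise TaxonomyStructureError("no root node (empty parent_id) found")
        if len(roots) > 1:
            raise TaxonomyStructureError(f"multiple roots: {sorted(roots)}")
        root = roots[0]
        # walk every node to the root, detecting cycles and orphans
        state: dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self._nodes:
            path = []
            cur = start
            while True:
                if state.get(cur) == 1:
                    break
                if state.get(cur) == 0:
                    raise TaxonomyStructureError(
                        f"cycle in parent links involving {cur!r}"
                    )
                state[cur] = 0
                path.append(cur)
                parent = self._nodes[cur].parent_id
                if parent in ROOT_MARKERS:
                    break
                if parent not in self._nodes:
                    raise TaxonomyStructureError(
                        f"taxon {cur!r} names missing parent {parent!r}"
                    )
                cur = parent
            for t in path:
                state[t] = 1
        return root

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def node(self, taxon_id: str) -> TaxonomyNode:
        return self._nodes[taxon_id]

    def rank_of(self, taxon_id: str) -> str:
        return self._nodes[taxon_id].rank

    def name_of(self, taxon_id: str) -> str:
        return self._nodes[taxon_id].name or taxon_id

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        """Taxon identifiers from the root down to ``taxon_id`` (inclusive)."""
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return cached
        if taxon_id not in self._nodes:
            raise KeyError(taxon_id)
        chain = []
        cur = taxon_id
        while True:
            chain.append(cur)
            parent = self._nodes[cur].parent_id
            if parent in ROOT_MARKERS:
                break
            cur = parent
        result = tuple(reversed(chain))
        self._lineage_cache[taxon_id] = result
        return result

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """The lineage member of ``taxon_id`` at ``rank``, or None if absent."""
        for t in self.lineage(taxon_id):
            if self._nodes[t].rank == rank:
                return t
        return None

    def lineage_string(self, taxon_id: str | None, sep: str = ";") -> str:
        """Human-readable lineage over ladder ranks, for report tables."""
        if taxon_id is None or taxon_id not in self._nodes:
            return UNCLASSIFIED
        parts = []
        for t in self.lineage(taxon_id):
            node = self._nodes[t]
            if node.rank in RANKS:
                parts.append(f"{node.rank[0]}_{node.name or t}")
        return sep.join(parts) if parts else UNCLASSIFIED
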