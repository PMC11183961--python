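"""ORF and contig taxonomic assignment from protein homology hits.

The per-ORF procedure mirrors the published LCA protocol for metagenomic
ORFs searched against a comprehensive protein reference:

1. discard hits with e-value above a cutoff (default 1e-3);
2. keep "valid hits": bitscore at least 80% of the best hit's and identity
   within a window of the best hit's identity;
3. report, per rank from species up to superkingdom, the taxon shared by at
   least 90% of the valid hits, taking the deepest supported rank;
4. truncate the assignment to the deepest rank whose minimum-identity floor
   (85/60/55/50/46/42/40% for species..superkingdom) the best hit's identity
   clears.

Contigs then receive a consensus taxonomy: walking ranks from superkingdom
downward, a taxon is accepted when it covers >= 50% of all ORFs on the contig
and >= 70% of the ORFs annotated at that rank, consistently with the taxon
chosen at the parent rank.

All threshold comparisons use exact decimal arithmetic (``Fraction``), so
boundary cases — 9 of 10 hits supporting a taxon, a bitscore exactly 80% of
the best, an identity exactly at a rank floor — behave exactly as written.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .errors import UnknownTaxonError, ValidationError
from .io import HitRecord, best_hit
from .taxtree import RANKS, UNCLASSIFIED, TaxonomyTree


def _frac(x) -> Fraction:
    """Exact decimal value of a float/str, e.g. 0.9 -> 9/10 (not the binary float)."""
    return Fraction(str(x))


#: Minimum percent identity of the best valid hit required to report an
#: assignment at each rank.
DEFAULT_RANK_FLOORS: dict[str, float] = {
    "species": 85.0,
    "genus": 60.0,
    "family": 55.0,
    "order": 50.0,
    "class": 46.0,
    "phylum": 42.0,
    "superkingdom": 40.0,
}


@dataclass(frozen=True, slots=True)
class LcaParams:
    """Tunables of valid-hit selection and the rank-floored LCA.

    ``identity_mode`` selects how the identity window around the best hit is
    read: ``"relative"`` keeps hits with identity >= identity_fraction x best
    identity (the literal reading of "no smaller than 10% of the identity of
    the best hit"); ``"absolute"`` keeps hits within
    100 x identity_fraction percentage points of the best identity, a stricter
    alternative for the same sentence.

    ``floor_identity`` selects which identity is compared against the rank
    floors: the best valid hit's (``"best"``) or the median over valid hits
    (``"median"``).
    """

    evalue_cutoff: float = 1e-3
    bitscore_fraction: float = 0.80
    identity_fraction: float = 0.10
    support_fraction: float = 0.90
    rank_floors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_FLOORS)
    )
    identity_mode: str = "relative"
    floor_identity: str = "best"

    def __post_init__(self):
        for name in ("bitscore_fraction", "identity_fraction", "support_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if self.identity_mode not in ("relative", "absolute"):
            raise ValidationError(f"identity_mode {self.identity_mode!r}")
        if self.floor_identity not in ("best", "median"):
            raise ValidationError(f"floor_identity {self.floor_identity!r}")
        floors = [self.rank_floors[r] for r in RANKS[::-1] if r in self.rank_floors]
        if any(a < b for a, b in zip(floors, floors[1:])):
            raise ValidationError("rank_floors must not increase from species up")


@dataclass(frozen=True, slots=True)
class ConsensusParams:
    """Thresholds of the contig consensus rule."""

    min_fraction_all: float = 0.50
    min_fraction_annotated: float = 0.70

    def __post_init__(self):
        for name in ("min_fraction_all", "min_fraction_annotated"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name}={v} outside (0, 1]")


@dataclass(frozen=True, slots=True)
class OrfTaxonomy:
    """Result of the LCA procedure for one ORF."""

    orf_id: str
    assigned_taxon: str | None
    assigned_rank: str | None
    best_identity: float
    n_valid_hits: int

    @property
    def classified(self) -> bool:
        return self.assigned_taxon is not None


def select_valid_hits(
    hits: Sequence[HitRecord], params: LcaParams = LcaParams()
) -> list[HitRecord]:
    """Valid hits: within the e-value cutoff and the bitscore/identity windows.

    The best hit (maximal bitscore after e-value filtering; ties broken by
    lower e-value, then higher identity, then input order) is always included.
    Empty input yields an empty list.
    """
    kept = [h for h in hits if _frac(h.evalue) <= _frac(params.evalue_cutoff)]
    if not kept:
        return []
    best = best_hit(kept)
    bit_floor = _frac(params.bitscore_fraction) * _frac(best.bitscore)
    if params.identity_mode == "relative":
        id_floor = _frac(params.identity_fraction) * _frac(best.percent_identity)
    else:
        id_floor = _frac(best.percent_identity) - 100 * _frac(params.identity_fraction)
    return [
        h
        for h in kept
        if _frac(h.bitscore) >= bit_floor and _frac(h.percent_identity) >= id_floor
    ]


def _floor_identity(valid_hits: Sequence[HitRecord], params: LcaParams) -> float:
    if params.floor_identity == "median":
        ids = sorted(h.percent_identity for h in valid_hits)
        mid = len(ids) // 2
        return ids[mid] if len(ids) % 2 else (ids[mid - 1] + ids[mid]) / 2
    return best_hit(list(valid_hits)).percent_identity


def assign_orf_lca(
    orf_id: str,
    valid_hits: Sequence[HitRecord],
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
) -> OrfTaxonomy:
    """Rank-floored, support-thresholded LCA over one ORF's valid hits.

    Hits with empty taxon labels count in the support denominator (they are
    valid hits that support no taxon). A hit naming a taxon absent from the
    tree raises :class:`~ironmeta.errors.UnknownTaxonError`.
    """
    n = len(valid_hits)
    if n == 0:
        return OrfTaxonomy(orf_id, None, None, 0.0, 0)
    for h in valid_hits:
        if h.subject_taxon and h.subject_taxon not in tree:
            raise UnknownTaxonError(
                f"hit {h.subject_id!r} names unknown taxon {h.subject_taxon!r}"
            )
    identity = _floor_identity(valid_hits, params)
    support_needed = _frac(params.support_fraction) * n

    candidate: tuple[str, str] | None = None  # (taxon, rank)
    for rank in reversed(RANKS):  # species first
        counts: Counter[str] = Counter()
        for h in valid_hits:
            if not h.subject_taxon:
                continue
            anc = tree.ancestor_at_rank(h.subject_taxon, rank)
            if anc is not None:
                counts[anc] += 1
        if not counts:
            continue
        taxon, count = counts.most_common(1)[0]
        if Fraction(count) >= support_needed:
            candidate = (taxon, rank)
            break
    if candidate is None:
        return OrfTaxonomy(orf_id, None, None, identity, n)

    taxon, rank = candidate
    # truncate to the deepest rank at or above the candidate whose identity
    # floor the (best/median) identity clears
    for r in RANKS[RANKS.index(rank)::-1]:
        floor = params.rank_floors.get(r)
        if floor is None or _frac(identity) < _frac(floor):
            continue
        anc = tree.ancestor_at_rank(taxon, r)
        if anc is not None:
            return OrfTaxonomy(orf_id, anc, r, identity, n)
    return OrfTaxonomy(orf_id, None, None, identity, n)


def classify_orfs(
    grouped_hits: Mapping[str, Sequence[HitRecord]],
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
) -> dict[str, OrfTaxonomy]:
    """Run valid-hit selection + LCA for every query in a grouped hit table."""
    return {
        orf: assign_orf_lca(orf, select_valid_hits(hits, params), tree, params)
        for orf, hits in grouped_hits.items()
    }


def consensus_contig_taxonomy(
    orf_taxonomies: Sequence[OrfTaxonomy],
    tree: TaxonomyTree,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[str | None, str | None]:
    """Consensus (taxon, rank) for one contig, or (None, None) if unclassified.

    Walking ranks from superkingdom downward, a taxon is accepted at a rank
    when it covers >= min_fraction_all of all ORFs and >= min_fraction_annotated
    of the ORFs annotated at that rank, and descends from the taxon accepted at
    the previous rank. Unclassified ORFs count toward the total but never
    toward the annotated count. Ranks at which no ORF is annotated are skipped.
    """
    if not orf_taxonomies:
        raise ValidationError("consensus over an empty ORF collection")
    total = len(orf_taxonomies)
    f_all = _frac(params.min_fraction_all)
    f_ann = _frac(params.min_fraction_annotated)
    chosen: tuple[str, str] | None = None
    for rank in RANKS:
        counts: Counter[str] = Counter()
        annotated = 0
        for ot in orf_taxonomies:
            if not ot.classified:
                continue
            anc = tree.ancestor_at_rank(ot.assigned_taxon, rank)
            if anc is None:
                continue
            annotated += 1
            counts[anc] += 1
        if annotated == 0:
            continue  # rank absent from every lineage: skip, do not terminate
        winner = None
        for taxon, count in counts.most_common():
            if chosen is not None:
                parent = tree.ancestor_at_rank(taxon, chosen[1])
                if parent != chosen[0]:
                    continue
            if Fraction(count, total) >= f_all and Fraction(count, annotated) >= f_ann:
                winner = taxon
                break
        if winner is None:
            break
        chosen = (winner, rank)
    if chosen is None:
        return None, None
    return chosen


def taxon_read_fractions(
    contig_taxa: Mapping[str, str | None],
    read_counts: Mapping[str, float],
    tree: TaxonomyTree,
    rank: str,
) -> dict[str, float]:
    """Per-taxon fraction of mapped reads at a target rank, with an
    explicit unclassified bucket; fractions sum to 1.

    Contigs classified below the target rank are rolled up along their
    lineage; contigs unclassified, or classified only above the target rank,
    fall into the unclassified bucket.
    """
    total = sum(read_counts.values())
    if total <= 0:
        raise ValidationError("total mapped reads is zero")
    sums: dict[str, float] = {}
    for contig, reads in read_counts.items():
        taxon = contig_taxa.get(contig)
        bucket = UNCLASSIFIED
        if taxon is not None:
            anc = tree.ancestor_at_rank(taxon, rank)
            if anc is not None:
                bucket = anc
        sums[bucket] = sums.get(bucket, 0.0) + reads
    return {t: v / total for t, v in sums.items()}
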