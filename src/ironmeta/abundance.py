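"""Copy-number normalization against universal single-copy marker genes.

Per-gene coverages (mean aligned depth) are converted to average gene copies
per genome by dividing by the median aggregate coverage of 10 universal
single-copy marker genes (USiCGs). Because every genome carries each marker
exactly once, the marker median estimates "genomes per sample"; a feature's
coverage divided by it reads as copies per genome in the community, a
quantity unaffected by the fraction of mapped or annotated reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .errors import NormalizationError, ValidationError
from .functions import CatalogEntry, OrfFunction
from .taxonomy import OrfTaxonomy, taxon_read_fractions
from .taxtree import UNCLASSIFIED, TaxonomyTree


@dataclass(frozen=True, slots=True)
class MarkerSet:
    """The 10 single-copy marker COGs used for normalization.

    The membership is a configuration input; the bundled default is the set
    of 10 universal single-copy housekeeping COGs commonly used to normalize
    shotgun metagenomes.
    """

    cog_ids: frozenset[str]

    def __post_init__(self):
        if len(self.cog_ids) != 10:
            raise ValidationError(
                f"marker set must contain exactly 10 COGs, got {len(self.cog_ids)}"
            )

    @classmethod
    def from_iterable(cls, cogs: Iterable[str]) -> "MarkerSet":
        return cls(frozenset(cogs))


def default_marker_set() -> MarkerSet:
    ref = resources.files("ironmeta.data") / "marker_cogs.txt"
    cogs = [line.strip() for line in ref.read_text().splitlines() if line.strip()]
    return MarkerSet.from_iterable(cogs)


def aggregate_cog_coverage(
    orf_coverage: Mapping[str, float],
    orf_functions: Mapping[str, OrfFunction],
) -> dict[str, float]:
    """Sum per-ORF coverages into per-COG aggregates (ORFs without a COG are skipped)."""
    out: dict[str, float] = {}
    for orf, cov in orf_coverage.items():
        fn = orf_functions.get(orf)
        if fn is None or fn.cog_id is None:
            continue
        out[fn.cog_id] = out.get(fn.cog_id, 0.0) + cov
    return out


def marker_median(
    orf_coverage: Mapping[str, float],
    orf_functions: Mapping[str, OrfFunction],
    markers: MarkerSet,
    aggregate: str = "sum",
) -> float:
    """Median of the 10 per-marker aggregate coverages.

    Each marker's aggregate is the sum (default; ``aggregate="mean"`` averages
    instead) of the coverages of ORFs annotated to that marker COG; markers
    with no ORFs contribute 0. With an even count the median is the mean of
    the two central values. An all-zero profile cannot be normalized and
    raises :class:`~ironmeta.errors.NormalizationError`.
    """
    if aggregate not in ("sum", "mean"):
        raise ValidationError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    sums = {c: 0.0 for c in markers.cog_ids}
    counts = {c: 0 for c in markers.cog_ids}
    for orf, cov in orf_coverage.items():
        fn = orf_functions.get(orf)
        if fn is not None and fn.cog_id in sums:
            sums[fn.cog_id] += cov
            counts[fn.cog_id] += 1
    values = [
        sums[c] / counts[c] if aggregate == "mean" and counts[c] else sums[c]
        for c in sorted(markers.cog_ids)
    ]
    med = float(np.median(values))
    if med <= 0:
        raise NormalizationError(
            "median marker coverage is zero; profile cannot be normalized"
        )
    return med


def copy_number(target_coverage: float, marker_median_value: float) -> float:
    """Copies per genome: coverage of the target divided by the marker median."""
    if marker_median_value <= 0:
        raise NormalizationError(f"marker median {marker_median_value} <= 0")
    return target_coverage / marker_median_value


@dataclass(slots=True)
class SampleAbundanceProfile:
    """All per-sample normalized quantities derived from one coverage table."""

    sample_id: str
    orf_coverage: Mapping[str, float]
    cog_coverage: Mapping[str, float]
    marker_median: float
    cn_by_cog: dict[str, float] = field(default_factory=dict)
    cn_by_category: dict[str, float] = field(default_factory=dict)


def build_profile(
    sample_id: str,
    orf_coverage: Mapping[str, float],
    orf_functions: Mapping[str, OrfFunction],
    markers: MarkerSet,
    catalog: Mapping[str, CatalogEntry],
    aggregate: str = "sum",
) -> SampleAbundanceProfile:
    """Normalize one sample: marker median, per-COG and per-category copy numbers."""
    med = marker_median(orf_coverage, orf_functions, markers, aggregate)
    cog_cov = aggregate_cog_coverage(orf_coverage, orf_functions)
    cn_by_cog = {c: copy_number(v, med) for c, v in cog_cov.items()}
    cn_by_category: dict[str, float] = {}
    for cog, cn in cn_by_cog.items():
        entry = catalog.get(cog)
        if entry is not None:
            cn_by_category[entry.category] = cn_by_category.get(entry.category, 0.0) + cn
    return SampleAbundanceProfile(
        sample_id=sample_id,
        orf_coverage=dict(orf_coverage),
        cog_coverage=cog_cov,
        marker_median=med,
        cn_by_cog=cn_by_cog,
        cn_by_category=cn_by_category,
    )


def category_breakdown(
    category_orfs: Iterable[str],
    orf_taxonomies: Mapping[str, OrfTaxonomy],
    orf_coverage: Mapping[str, float],
    tree: TaxonomyTree,
    rank: str,
) -> dict[str, float]:
    """Per-taxon share of a category's coverage, rolled up to a target rank.

    ORFs unclassified (or classified above the rank) land in the unclassified
    bucket. Shares sum to 1 unless the category total is 0 (empty result).
    """
    sums: dict[str, float] = {}
    total = 0.0
    for orf in category_orfs:
        cov = orf_coverage.get(orf, 0.0)
        if cov == 0.0:
            continue
        ot = orf_taxonomies.get(orf)
        bucket = UNCLASSIFIED
        if ot is not None and ot.classified:
            anc = tree.ancestor_at_rank(ot.assigned_taxon, rank)
            if anc is not None:
                bucket = anc
        sums[bucket] = sums.get(bucket, 0.0) + cov
        total += cov
    if total == 0.0:
        return {}
    return {t: v / total for t, v in sums.items()}


__all__ = [
    "MarkerSet",
    "SampleAbundanceProfile",
    "aggregate_cog_coverage",
    "build_profile",
    "category_breakdown",
    "copy_number",
    "default_marker_set",
    "marker_median",
    "taxon_read_fractions",
]
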