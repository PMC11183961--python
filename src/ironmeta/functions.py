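"""Best-hit COG assignment and the iron-function catalog.

Each ORF receives at most one COG: the best hit (maximal bitscore within the
e-value cutoff) against a COG-labeled reference. COGs are then mapped to the
nine iron-function categories used throughout the study: ferrous iron ABC
transporters, TonB-dependent outer-membrane ferric-siderophore transporters,
cell-membrane ferric-siderophore ABC transporters, divalent-cation ABC
transporters, dicitrate-bound iron transport, heme-bound iron transport, iron
storage (ferritins), regulators of iron metabolism, and siderophore synthesis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError
from .io import HitRecord, best_hit

#: Closed category vocabulary.
CATEGORIES: tuple[str, ...] = (
    "Fe(II)",
    "Fe(III)-OM",
    "Fe(III)-CM",
    "divalent_cation",
    "dicitrate",
    "heme",
    "storage",
    "regulators",
    "siderophore_synthesis",
)

SYNTHESIS = "siderophore_synthesis"

#: Key of the implicit pool of ORFs whose COG is not in the catalog.
NON_IRON = "non_iron"

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


@dataclass(frozen=True, slots=True)
class CatalogEntry:
    cog_id: str
    category: str
    gene_examples: str = ""
    ambiguous_synthesis: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for {self.cog_id}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True, slots=True)
class OrfFunction:
    orf_id: str
    cog_id: str | None
    category: str | None = None


IronCatalog = dict  # cog_id -> CatalogEntry; plain mapping is the container


def assign_cog(
    hits: Sequence[HitRecord], evalue_cutoff: float = 1e-3
) -> str | None:
    """COG of the best qualifying hit, or None when no hit qualifies.

    Hits without a COG label cannot assign a function and are ignored; ties
    on bitscore break by lower e-value, then higher identity, then input
    order, as in the taxonomy stage.
    """
    kept = [h for h in hits if h.subject_cog and h.evalue <= evalue_cutoff]
    if not kept:
        return None
    return best_hit(kept).subject_cog


def annotate_orfs(
    grouped_hits: Mapping[str, Sequence[HitRecord]],
    catalog: Mapping[str, CatalogEntry],
    evalue_cutoff: float = 1e-3,
) -> dict[str, OrfFunction]:
    """Best-hit COG for every query, with the catalog category joined on."""
    out = {}
    for orf, hits in grouped_hits.items():
        cog = assign_cog(hits, evalue_cutoff)
        entry = catalog.get(cog) if cog else None
        out[orf] = OrfFunction(orf, cog, entry.category if entry else None)
    return out


def _parse_bool(value: str, path, lineno: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ParseError(f"expected boolean, got {value!r}", path, lineno)


def load_iron_catalog(path) -> IronCatalog:
    """Load a catalog TSV (cog_id, category, gene_examples, ambiguous_synthesis).

    Unknown categories and duplicate cog_ids are errors: each COG belongs to
    exactly one category of the closed vocabulary.
    """
    catalog: IronCatalog = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0] == "cog_id":
                continue
            if len(row) < 2:
                raise ParseError("expected cog_id and category columns", path, lineno)
            cog = row[0]
            if cog in catalog:
                raise ValidationError(f"duplicate cog_id {cog!r} in catalog")
            genes = row[2] if len(row) > 2 else ""
            ambiguous = _parse_bool(row[3], path, lineno) if len(row) > 3 else False
            try:
                catalog[cog] = CatalogEntry(cog, row[1], genes, ambiguous)
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
    return catalog


def bundled_iron_catalog() -> IronCatalog:
    """The reduced catalog shipped with the package (~25 COGs over all 9
    categories); the full curated catalog of a real study is user-supplied."""
    ref = resources.files("ironmeta.data") / "iron_catalog.tsv"
    with resources.as_file(ref) as path:
        return load_iron_catalog(path)


def categorize_orfs(
    orf_functions: Iterable[OrfFunction] | Mapping[str, OrfFunction],
    catalog: Mapping[str, CatalogEntry],
) -> dict[str, set[str]]:
    """Partition ORFs into category -> ORF-id sets.

    ORFs whose COG is absent from the catalog (or that have no COG) fall into
    the implicit ``non_iron`` pool, so category sizes plus the pool always sum
    to the number of ORFs.
    """
    if isinstance(orf_functions, Mapping):
        orf_functions = orf_functions.values()
    out: dict[str, set[str]] = {}
    for fn in orf_functions:
        entry = catalog.get(fn.cog_id) if fn.cog_id else None
        key = entry.category if entry else NON_IRON
        out.setdefault(key, set()).add(fn.orf_id)
    return out
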