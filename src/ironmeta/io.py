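"""Readers and writers for the pipeline's tabular formats.

Alignment input is the de facto 12-column tabular layout produced by
BLAST/DIAMOND (``--outfmt 6``): query, subject, pident, length, mismatches,
gapopens, qstart, qend, sstart, send, evalue, bitscore. Subject-to-taxon and
subject-to-COG lookups are separate two-column TSVs, because taxonomy and
function are resolved from different reference searches. All outputs are TSV
with a header line and ``.`` for missing values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ParseError
from .taxtree import TaxonomyNode, TaxonomyTree

#: Column names of the 12-column tabular alignment format.
ALIGNMENT_COLUMNS = (
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Missing-value token used in every TSV this package writes.
MISSING = "."


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One query-subject alignment row, with joined reference labels.

    ``subject_taxon`` / ``subject_cog`` are empty strings when the subject is
    absent from the corresponding lookup; such rows are kept, not dropped.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: float
    subject_taxon: str = ""
    subject_cog: str = ""

    def __post_init__(self):
        if not self.query_id:
            raise ValueError("query_id must be nonempty")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")
        if self.bitscore < 0:
            raise ValueError(f"bitscore {self.bitscore} < 0")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length {self.alignment_length} < 1")


@dataclass(frozen=True, slots=True)
class SubjectMap:
    """Subject-id lookups joining reference labels onto alignment rows."""

    taxon: Mapping[str, str]
    cog: Mapping[str, str]

    def labels(self, subject_id: str) -> tuple[str, str]:
        return self.taxon.get(subject_id, ""), self.cog.get(subject_id, "")


EMPTY_SUBJECT_MAP = SubjectMap(taxon={}, cog={})


def read_two_column_map(path) -> dict[str, str]:
    """Read a headerless two-column TSV into a dict (first column is the key)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError("expected 2 tab-separated columns", path, lineno)
            out[row[0]] = row[1]
    return out


def _hit_from_row(row: list[str], subject_map: SubjectMap, path, lineno: int) -> HitRecord:
    if len(row) != len(ALIGNMENT_COLUMNS):
        raise ParseError(
            f"expected {len(ALIGNMENT_COLUMNS)} tab-separated columns, got {len(row)}",
            path, lineno,
        )
    try:
        pident = float(row[2])
        length = int(row[3])
        evalue = float(row[10])
        bitscore = float(row[11])
    except ValueError as exc:
        raise ParseError(f"non-numeric field: {exc}", path, lineno) from None
    taxon, cog = subject_map.labels(row[1])
    try:
        return HitRecord(
            query_id=row[0],
            subject_id=row[1],
            percent_identity=pident,
            alignment_length=length,
            bitscore=bitscore,
            evalue=evalue,
            subject_taxon=taxon,
            subject_cog=cog,
        )
    except ValueError as exc:
        raise ParseError(str(exc), path, lineno) from None


def read_alignment_table(
    path, subject_map: SubjectMap = EMPTY_SUBJECT_MAP
) -> dict[str, list[HitRecord]]:
    """Read a 12-column alignment table grouped by query, preserving row order.

    Returns an insertion-ordered mapping query_id -> hits in file order.
    An empty file yields an empty mapping. Malformed rows raise
    :class:`~ironmeta.errors.ParseError` naming the offending line.
    """
    groups: dict[str, list[HitRecord]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            hit = _hit_from_row(row, subject_map, path, lineno)
            groups.setdefault(hit.query_id, []).append(hit)
    return groups


def best_hit(hits: list[HitRecord]) -> HitRecord:
    """Best hit: maximal bitscore; ties by lower e-value, higher identity, input order."""
    if not hits:
        raise ValueError("best_hit of an empty hit list")
    best = hits[0]
    for h in hits[1:]:
        if (h.bitscore, -h.evalue, h.percent_identity) > (
            best.bitscore, -best.evalue, best.percent_identity
        ):
            best = h
    return best


def read_taxonomy_table(path) -> TaxonomyTree:
    """Read a taxonomy TSV (taxon_id, parent_id, rank, name) into a validated tree.

    A header row starting with ``taxon_id`` is accepted and skipped. Ranks
    outside the ladder are stored as ``norank``. Structural problems (cycles,
    multiple roots, missing parents) raise
    :class:`~ironmeta.errors.TaxonomyStructureError`.
    """
    nodes = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0] == "taxon_id":
                continue
            if len(row) < 3:
                raise ParseError(
                    "expected columns taxon_id, parent_id, rank[, name]", path, lineno
                )
            name = row[3] if len(row) > 3 else ""
            parent = "" if row[1] == MISSING else row[1]
            nodes.append(TaxonomyNode(row[0], parent, row[2], name))
    return TaxonomyTree(nodes)


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    """Write a DataFrame as TSV with ``.`` for missing values.

    Floats are rendered with ``%.10g`` so repeated runs of the same pipeline
    produce byte-identical files.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", na_rep=MISSING, index=index, float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tsv`."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING], index_col=index_col)
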