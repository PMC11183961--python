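"""Siderophore pathway network, presence classification, and quantitation.

Pathway gene content is complicated in two directions: one COG may cover
genes from many pathways (and even enzymes unrelated to siderophores), and
one gene may be assigned to several COGs. The network holds the full
pathway -> gene -> COG multi-map plus a per-COG ambiguity flag (shared with
non-siderophore functions). Presence calls follow three strict criteria:

1. a pathway MAY BE present when every one of its genes is present
   (a gene is present when at least one of its COGs is detected);
2. a pathway IS present when, additionally, at least one detected gene is
   unique to that pathway (operationalized at COG level: a COG occurring in
   exactly one pathway and not flagged ambiguous);
3. a pathway with at least one absent gene is called absent.

Ambiguous COGs count toward gene presence but are excluded from both
uniqueness and quantitation, which makes the reported synthesis copy number a
deliberate underestimate.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .abundance import SampleAbundanceProfile, copy_number
from .errors import ParseError, ValidationError
from .functions import SYNTHESIS, CatalogEntry

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


class PathwayStatus(enum.IntEnum):
    """Ordered presence call: ABSENT < MAYBE < PRESENT."""

    ABSENT = 0
    MAYBE = 1
    PRESENT = 2

    def __str__(self) -> str:  # used in TSV output
        return self.name


@dataclass(frozen=True, slots=True)
class PathwayDefinitionRow:
    pathway_id: str
    gene_id: str
    cog_id: str
    ambiguous: bool = False

    def __post_init__(self):
        if not (self.pathway_id and self.gene_id and self.cog_id):
            raise ValidationError("pathway_id, gene_id and cog_id must be nonempty")


@dataclass
class PathwayNetwork:
    """Bipartite pathway->gene and (pathway, gene)->COG multi-map.

    ``unique_cogs`` is always derived from the current maps, never stored, so
    it cannot go stale when the network is built incrementally.
    """

    pathways: dict[str, set[str]] = field(default_factory=dict)
    gene_cogs: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    ambiguous_cogs: set[str] = field(default_factory=set)

    @classmethod
    def from_rows(cls, rows: Iterable[PathwayDefinitionRow]) -> "PathwayNetwork":
        net = cls()
        seen: set[tuple[str, str, str]] = set()
        for row in rows:
            triple = (row.pathway_id, row.gene_id, row.cog_id)
            if triple in seen:
                raise ValidationError(f"duplicate pathway definition row {triple}")
            seen.add(triple)
            net.pathways.setdefault(row.pathway_id, set()).add(row.gene_id)
            net.gene_cogs.setdefault((row.pathway_id, row.gene_id), set()).add(row.cog_id)
            if row.ambiguous:
                net.ambiguous_cogs.add(row.cog_id)
        if not net.pathways:
            raise ValidationError("pathway definition contains no pathways")
        for pid, genes in net.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has zero genes")
        return net

    # -- derived views -------------------------------------------------------

    @property
    def cog_pathways(self) -> dict[str, set[str]]:
        """COG -> set of pathways in which it appears."""
        out: dict[str, set[str]] = {}
        for (pid, _gene), cogs in self.gene_cogs.items():
            for c in cogs:
                out.setdefault(c, set()).add(pid)
        return out

    @property
    def unique_cogs(self) -> set[str]:
        """COGs occurring in exactly one pathway and not flagged ambiguous."""
        return {
            c
            for c, pids in self.cog_pathways.items()
            if len(pids) == 1 and c not in self.ambiguous_cogs
        }

    @property
    def all_cogs(self) -> set[str]:
        return set(self.cog_pathways)

    def pathway_cogs(self, pathway_id: str) -> set[str]:
        return {
            c
            for (pid, _g), cogs in self.gene_cogs.items()
            if pid == pathway_id
            for c in cogs
        }


def read_pathway_table(path) -> PathwayNetwork:
    """Read a pathway TSV (pathway_id, gene_id, cog_id[, ambiguous_flag]).

    The optional boolean column flags COGs shared with non-siderophore
    functions. Uniqueness flags are always recomputed from the network, never
    read from the file.
    """
    rows = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if lineno == 1 and raw[0] == "pathway_id":
                continue
            if len(raw) < 3:
                raise ParseError(
                    "expected pathway_id, gene_id, cog_id columns", path, lineno
                )
            ambiguous = False
            if len(raw) > 3:
                v = raw[3].strip().lower()
                if v in _TRUE:
                    ambiguous = True
                elif v not in _FALSE:
                    raise ParseError(f"expected boolean flag, got {raw[3]!r}", path, lineno)
            try:
                rows.append(PathwayDefinitionRow(raw[0], raw[1], raw[2], ambiguous))
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return PathwayNetwork.from_rows(rows)


def bundled_pathway_network() -> PathwayNetwork:
    """The 12-pathway network shipped with the package (8 present / 4 absent
    under the default simulated community); a real study supplies its own."""
    ref = resources.files("ironmeta.data") / "pathway_network.tsv"
    with resources.as_file(ref) as path:
        return read_pathway_table(path)


@dataclass(frozen=True, slots=True)
class PathwayCall:
    pathway_id: str
    status: PathwayStatus
    missing_genes: frozenset[str]
    supporting_unique_cogs: frozenset[str]


def detected_cogs(
    profile: SampleAbundanceProfile | Mapping[str, float],
    min_coverage: float = 0.0,
) -> set[str]:
    """COGs with aggregate coverage strictly above the detection floor."""
    if min_coverage < 0:
        raise ValidationError(f"min_coverage {min_coverage} < 0")
    cov = profile.cog_coverage if isinstance(profile, SampleAbundanceProfile) else profile
    return {c for c, v in cov.items() if v > min_coverage}


def classify_pathway(
    pathway_id: str,
    network: PathwayNetwork,
    present_cogs: set[str],
) -> PathwayCall:
    """Apply the three presence criteria to one pathway.

    A gene is present when any of its COGs is in ``present_cogs`` (multi-COG
    membership is treated as alternative signatures of the same gene).
    """
    if pathway_id not in network.pathways:
        raise ValidationError(f"unknown pathway {pathway_id!r}")
    missing = {
        gene
        for gene in network.pathways[pathway_id]
        if not (network.gene_cogs[(pathway_id, gene)] & present_cogs)
    }
    unique = network.unique_cogs
    supporting = network.pathway_cogs(pathway_id) & unique & present_cogs
    if missing:
        status = PathwayStatus.ABSENT
    elif supporting:
        status = PathwayStatus.PRESENT
    else:
        status = PathwayStatus.MAYBE
    return PathwayCall(pathway_id, status, frozenset(missing), frozenset(supporting))


def quantify_synthesis(
    profile: SampleAbundanceProfile,
    network: PathwayNetwork,
    catalog: Mapping[str, CatalogEntry],
) -> float:
    """Copy number of siderophore synthesis, excluding ambiguous COGs.

    Sums the coverage of synthesis-category COGs that are neither flagged
    ambiguous in the catalog nor in the network, then normalizes by the
    sample's marker median. Because ambiguous COGs also harbor genuine
    synthesis genes, this value is a documented underestimate.
    """
    excluded = network.ambiguous_cogs | {
        c for c, e in catalog.items() if e.ambiguous_synthesis
    }
    total = sum(
        cov
        for cog, cov in profile.cog_coverage.items()
        if cog in catalog
        and catalog[cog].category == SYNTHESIS
        and cog not in excluded
    )
    return copy_number(total, profile.marker_median)


def call_all_pathways(
    network: PathwayNetwork,
    profiles: Sequence[SampleAbundanceProfile],
    min_coverage: float = 0.0,
) -> pd.DataFrame:
    """Samples x pathways status matrix, plus a study-level best-status row.

    The study row takes the best status across samples
    (PRESENT > MAYBE > ABSENT), covering both the per-sample and the pooled
    reading of presence.
    """
    pathway_ids = sorted(network.pathways)
    rows = {}
    for profile in profiles:
        present = detected_cogs(profile, min_coverage)
        rows[profile.sample_id] = {
            pid: classify_pathway(pid, network, present).status for pid in pathway_ids
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=pathway_ids)
    if not frame.empty:
        frame.loc["study"] = frame.max(axis=0)
        frame = frame.map(lambda s: str(PathwayStatus(s)))
    return frame
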