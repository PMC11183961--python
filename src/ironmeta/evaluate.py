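"""Recovery metrics: how well a pipeline run reproduces its simulated truth.

Used by benchmark scripts and the test suite to quantify, per replicate, the
agreement between the analysis of a simulated study and the ground truth the
simulator exported: taxon read fractions, copy numbers of known-copy genes,
and the attribution of category coverage to the producer and cheater clades.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .functions import SYNTHESIS, CatalogEntry, bundled_iron_catalog
from .report import StudyReport, analyze_study
from .simulate import (
    CommunityScenario,
    GenomeModel,
    SimulatedStudy,
    default_scenario,
    simulate_study,
)
from .taxtree import TaxonomyTree


def rollup_fractions(
    fractions: pd.DataFrame, tree: TaxonomyTree, rank: str
) -> pd.DataFrame:
    """Roll truth fractions (samples x leaf taxa) up to a target rank."""
    out: dict[str, pd.Series] = {}
    for taxon in fractions.columns:
        anc = tree.ancestor_at_rank(taxon, rank) or taxon
        out[anc] = out.get(anc, 0.0) + fractions[taxon]
    return pd.DataFrame(out)


def fraction_errors(
    study: SimulatedStudy, report: StudyReport, rank: str = "phylum"
) -> pd.DataFrame:
    """Absolute error (in fraction units) of recovered vs true read fractions."""
    truth = rollup_fractions(study.fractions, study.tree, rank)
    est = report.fractions_by_rank[rank]
    cols = truth.columns.union(est.columns)
    truth = truth.reindex(columns=cols, fill_value=0.0)
    est = est.reindex(columns=cols, fill_value=0.0).drop(
        columns=[c for c in cols if c == "Unclassified"], errors="ignore"
    )
    return (est - truth.reindex(columns=est.columns, fill_value=0.0)).abs()


def true_category_shares(
    fractions: pd.DataFrame,
    genomes: Sequence[GenomeModel],
    catalog: Mapping[str, CatalogEntry],
    tree: TaxonomyTree,
    category: str,
    rank: str,
) -> pd.DataFrame:
    """Expected per-taxon share of a category's coverage at a rank.

    The taxon's expected contribution is fraction x (copies of the category's
    COGs in its genome); shares are normalized per sample.
    """
    copies = {}
    for g in genomes:
        total = sum(
            n
            for cog, n in g.gene_complement.items()
            if cog in catalog and catalog[cog].category == category
        )
        anc = tree.ancestor_at_rank(g.taxon_id, rank) or g.taxon_id
        copies[g.taxon_id] = (anc, total)
    out: dict[str, pd.Series] = {}
    for taxon in fractions.columns:
        anc, n = copies[taxon]
        if n == 0:
            continue
        contrib = fractions[taxon] * n
        out[anc] = out.get(anc, 0.0) + contrib
    frame = pd.DataFrame(out)
    return frame.div(frame.sum(axis=1), axis=0)


def producer_synthesis_share(
    study: SimulatedStudy,
    report: StudyReport,
    rank: str = "class",
    producer_clade: str | None = None,
) -> float:
    """Coverage-weighted share of synthesis-category signal attributed to the
    producer clade, pooled over all samples."""
    if producer_clade is None:
        producers = [g.taxon_id for g in study.genomes if g.role == "producer"]
        if not producers:
            raise ValueError("study has no producer genome")
        producer_clade = study.tree.ancestor_at_rank(producers[0], rank)
    breakdown = report.breakdowns[SYNTHESIS]
    weights = report.cn_by_category.get(SYNTHESIS)
    if breakdown.empty or weights is None:
        return 0.0
    share = breakdown.get(producer_clade, pd.Series(0.0, index=breakdown.index))
    total = weights.sum()
    return float((share * weights).sum() / total) if total > 0 else 0.0


def replicate_recovery(
    seed: int,
    scenario: CommunityScenario | None = None,
    catalog: Mapping[str, CatalogEntry] | None = None,
    transporter_cog: str = "COG0803",
    cheater_category: str = "Fe(III)-OM",
) -> dict[str, float]:
    """Run one simulated replicate end to end and score the recovery.

    Returns, per replicate:

    - ``max_fraction_error_pp``: worst phylum read-fraction error over all
      samples and phyla, in percentage points;
    - ``transporter_cn``: time-averaged copy number of a transporter carried
      at exactly one copy by every genome (truth = 1.0);
    - ``producer_synthesis_share``: pooled share of synthesis coverage
      attributed to the producer clade (truth = 1.0 when only the producer
      carries synthesis genes);
    - ``cheater_share_error_pp``: mean over samples, in percentage points, of
      the error of the cheater clade's share of the Fe(III)-OM breakdown
      against its simulated share.
    """
    if scenario is None:
        scenario = default_scenario(seed=seed)
    else:
        from dataclasses import replace

        scenario = replace(scenario, seed=seed)
    if catalog is None:
        catalog = bundled_iron_catalog()
    study = simulate_study(scenario)
    # class-rank breakdowns separate the producer (a gammaproteobacterial
    # class) from its non-producing sister class within the same phylum
    report = analyze_study(study, catalog=catalog, breakdown_rank="class")

    errors = fraction_errors(study, report, rank="phylum")
    max_frac_err = float(errors.to_numpy().max())

    cn = report.cn_by_cog.get(transporter_cog)
    transporter_cn = float(cn.mean()) if cn is not None else float("nan")

    producer_share = producer_synthesis_share(study, report)

    cheaters = [g.taxon_id for g in study.genomes if g.role == "cheater"]
    cheater_err = float("nan")
    if cheaters:
        clade = study.tree.ancestor_at_rank(cheaters[0], "class")
        truth = true_category_shares(
            study.fractions, study.genomes, catalog, study.tree,
            cheater_category, "class",
        )
        est = report.breakdowns[cheater_category]
        t = truth.get(clade, pd.Series(0.0, index=truth.index))
        e = est.get(clade, pd.Series(0.0, index=est.index)).reindex(t.index).fillna(0.0)
        cheater_err = float((e - t).abs().mean())

    return {
        "max_fraction_error_pp": 100.0 * max_frac_err,
        "transporter_cn": transporter_cn,
        "producer_synthesis_share": producer_share,
        "cheater_share_error_pp": 100.0 * cheater_err,
    }
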