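"""End-to-end orchestration: simulate -> classify -> annotate -> normalize ->
call pathways, and render the study-level trajectory tables and figures.

The pipeline is deterministic given its inputs and seed; every table in the
report carries the parameter fingerprint that produced it. Figures are
decorative summaries of the TSV content — nothing downstream depends on them.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .abundance import (
    MarkerSet,
    SampleAbundanceProfile,
    build_profile,
    category_breakdown,
    default_marker_set,
)
from .functions import (
    CATEGORIES,
    CatalogEntry,
    OrfFunction,
    bundled_iron_catalog,
    categorize_orfs,
)
from .io import write_tsv
from .pathways import (
    PathwayNetwork,
    bundled_pathway_network,
    call_all_pathways,
    quantify_synthesis,
)
from .simulate import (
    CommunityScenario,
    SimulatedStudy,
    default_scenario,
    export_ground_truth,
    simulate_study,
    write_study,
)
from .taxonomy import (
    ConsensusParams,
    LcaParams,
    OrfTaxonomy,
    classify_orfs,
    consensus_contig_taxonomy,
    taxon_read_fractions,
)
from .taxtree import TaxonomyTree

logger = logging.getLogger("ironmeta")

#: Ranks at which community composition tables are reported.
REPORT_RANKS = ("phylum", "class", "order")


@dataclass(slots=True)
class StudyReport:
    """All study-level outputs of one pipeline run."""

    fractions_by_rank: dict[str, pd.DataFrame]  # rank -> samples x taxa
    cn_by_category: pd.DataFrame  # samples x categories
    cn_by_cog: pd.DataFrame  # samples x COGs
    synthesis_cn: pd.Series  # ambiguity-excluded synthesis CN per sample
    breakdowns: dict[str, pd.DataFrame]  # category -> samples x taxa shares
    pathway_status: pd.DataFrame  # samples (+study row) x pathways
    orf_taxonomies: dict[str, OrfTaxonomy]
    contig_taxa: dict[str, str | None]
    orf_functions: dict[str, OrfFunction]
    profiles: list[SampleAbundanceProfile]
    metadata: dict = field(default_factory=dict)


def _log_stage(name: str, t0: float, **counts) -> None:
    extras = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s done in %.2fs (%s)", name, time.perf_counter() - t0, extras)


def analyze_study(
    study: SimulatedStudy,
    catalog: Mapping[str, CatalogEntry] | None = None,
    network: PathwayNetwork | None = None,
    markers: MarkerSet | None = None,
    lca_params: LcaParams = LcaParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    breakdown_rank: str = "phylum",
) -> StudyReport:
    """Run every analysis stage on an in-memory (simulated or loaded) study."""
    if catalog is None:
        catalog = bundled_iron_catalog()
    if network is None:
        network = bundled_pathway_network()
    if markers is None:
        markers = default_marker_set()
    tree = study.tree

    t0 = time.perf_counter()
    orf_taxa = classify_orfs(study.hits, tree, lca_params)
    _log_stage("classify-taxa", t0, orfs=len(orf_taxa))

    t0 = time.perf_counter()
    by_contig: dict[str, list[OrfTaxonomy]] = {}
    for orf, contig in study.contig_map.items():
        by_contig.setdefault(contig, []).append(
            orf_taxa.get(orf, OrfTaxonomy(orf, None, None, 0.0, 0))
        )
    contig_taxa = {
        contig: consensus_contig_taxonomy(orfs, tree, consensus_params)[0]
        for contig, orfs in by_contig.items()
    }
    _log_stage("consensus", t0, contigs=len(contig_taxa))

    t0 = time.perf_counter()
    orf_functions = {
        orf: OrfFunction(
            orf,
            cog := _best_cog(study.hits.get(orf, ()), lca_params.evalue_cutoff),
            catalog[cog].category if cog in catalog else None,
        )
        for orf in study.contig_map
    }
    category_sets = categorize_orfs(orf_functions, catalog)
    _log_stage("annotate", t0, orfs=len(orf_functions))

    t0 = time.perf_counter()
    profiles = [
        build_profile(s.sample_id, s.orf_coverage, orf_functions, markers, catalog)
        for s in study.samples
    ]
    fractions_by_rank = {
        rank: pd.DataFrame.from_dict(
            {
                s.sample_id: taxon_read_fractions(
                    contig_taxa, s.read_counts, tree, rank
                )
                for s in study.samples
            },
            orient="index",
        ).fillna(0.0)
        for rank in REPORT_RANKS
    }
    cn_by_category = pd.DataFrame.from_dict(
        {p.sample_id: p.cn_by_category for p in profiles}, orient="index"
    ).reindex(columns=list(CATEGORIES)).fillna(0.0)
    cn_by_cog = pd.DataFrame.from_dict(
        {p.sample_id: p.cn_by_cog for p in profiles}, orient="index"
    ).fillna(0.0)
    cn_by_cog = cn_by_cog[sorted(cn_by_cog.columns)]
    synthesis_cn = pd.Series(
        {p.sample_id: quantify_synthesis(p, network, catalog) for p in profiles},
        name="synthesis_cn",
    )
    _log_stage("abundances", t0, samples=len(profiles))

    t0 = time.perf_counter()
    breakdowns = {}
    for category in CATEGORIES:
        orfs = category_sets.get(category, set())
        frame = pd.DataFrame.from_dict(
            {
                s.sample_id: category_breakdown(
                    orfs, orf_taxa, s.orf_coverage, tree, breakdown_rank
                )
                for s in study.samples
            },
            orient="index",
        ).fillna(0.0)
        breakdowns[category] = frame
    pathway_status = call_all_pathways(network, profiles)
    _log_stage("pathways", t0, pathways=len(network.pathways))

    metadata = {
        "version": __version__,
        "seed": study.scenario.seed,
        "n_samples": study.scenario.n_samples,
        "reads_per_sample": study.scenario.reads_per_sample,
        "noise_cv": study.scenario.noise_cv,
        "evalue_cutoff": lca_params.evalue_cutoff,
        "bitscore_fraction": lca_params.bitscore_fraction,
        "support_fraction": lca_params.support_fraction,
        "consensus_min_all": consensus_params.min_fraction_all,
        "consensus_min_annotated": consensus_params.min_fraction_annotated,
        "breakdown_rank": breakdown_rank,
    }
    return StudyReport(
        fractions_by_rank=fractions_by_rank,
        cn_by_category=cn_by_category,
        cn_by_cog=cn_by_cog,
        synthesis_cn=synthesis_cn,
        breakdowns=breakdowns,
        pathway_status=pathway_status,
        orf_taxonomies=orf_taxa,
        contig_taxa=contig_taxa,
        orf_functions=orf_functions,
        profiles=profiles,
        metadata=metadata,
    )


def _best_cog(hits, evalue_cutoff: float) -> str | None:
    from .functions import assign_cog

    return assign_cog(list(hits), evalue_cutoff)


def write_report(report: StudyReport, tree: TaxonomyTree, out_dir) -> dict[str, Path]:
    """Write every report table as TSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fingerprint = pd.DataFrame(
        sorted(report.metadata.items()), columns=["key", "value"]
    )
    paths["metadata"] = out / "run_metadata.tsv"
    fingerprint.to_csv(paths["metadata"], sep="\t", index=False)

    for rank, frame in report.fractions_by_rank.items():
        name = f"fractions_{rank}"
        paths[name] = out / f"{name}.tsv"
        write_tsv(frame[sorted(frame.columns)], paths[name])
    paths["cn_by_category"] = out / "cn_by_category.tsv"
    write_tsv(report.cn_by_category, paths["cn_by_category"])
    paths["cn_by_cog"] = out / "cn_by_cog.tsv"
    write_tsv(report.cn_by_cog, paths["cn_by_cog"])
    paths["synthesis_cn"] = out / "synthesis_cn.tsv"
    write_tsv(report.synthesis_cn.to_frame(), paths["synthesis_cn"])
    for category, frame in report.breakdowns.items():
        safe = (
            category.replace("(", "").replace(")", "").replace("-", "_").lower()
        )
        name = f"breakdown_{safe}"
        paths[name] = out / f"{name}.tsv"
        write_tsv(frame[sorted(frame.columns)], paths[name])
    paths["pathway_status"] = out / "pathway_status.tsv"
    write_tsv(report.pathway_status, paths["pathway_status"])

    orf_rows = pd.DataFrame(
        [
            (
                ot.orf_id,
                ot.assigned_taxon or ".",
                ot.assigned_rank or ".",
                ot.best_identity,
                ot.n_valid_hits,
                tree.lineage_string(ot.assigned_taxon),
            )
            for ot in report.orf_taxonomies.values()
        ],
        columns=["orf_id", "taxon", "rank", "best_identity", "n_valid_hits", "lineage"],
    )
    paths["orf_taxonomy"] = out / "orf_taxonomy.tsv"
    orf_rows.to_csv(paths["orf_taxonomy"], sep="\t", index=False, float_format="%.10g")

    contig_rows = pd.DataFrame(
        [
            (contig, taxon or ".", tree.lineage_string(taxon))
            for contig, taxon in sorted(report.contig_taxa.items())
        ],
        columns=["contig_id", "taxon", "lineage"],
    )
    paths["contig_taxonomy"] = out / "contig_taxonomy.tsv"
    contig_rows.to_csv(paths["contig_taxonomy"], sep="\t", index=False)

    fn_rows = pd.DataFrame(
        [
            (fn.orf_id, fn.cog_id or ".", fn.category or ".")
            for fn in report.orf_functions.values()
        ],
        columns=["orf_id", "cog_id", "category"],
    )
    paths["orf_functions"] = out / "orf_functions.tsv"
    fn_rows.to_csv(paths["orf_functions"], sep="\t", index=False)
    return paths


def run_pipeline(
    scenario: CommunityScenario | None = None,
    out_dir=None,
    catalog=None,
    network=None,
    markers: MarkerSet | None = None,
    lca_params: LcaParams = LcaParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    write_inputs: bool = True,
) -> tuple[SimulatedStudy, StudyReport]:
    """Simulate a study and run the full analysis; optionally write all TSVs.

    Deterministic given the scenario (which carries the seed): rerunning with
    the same scenario produces byte-identical output files.
    """
    if scenario is None:
        scenario = default_scenario()
    if network is None:
        network = bundled_pathway_network()
    study = simulate_study(scenario)
    report = analyze_study(
        study,
        catalog=catalog,
        network=network,
        markers=markers,
        lca_params=lca_params,
        consensus_params=consensus_params,
    )
    if out_dir is not None:
        out = Path(out_dir)
        if write_inputs:
            write_study(study, out / "inputs")
        export_ground_truth(study, network, out / "truth")
        write_report(report, study.tree, out / "report")
    return study, report


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def plot_trajectories(report: StudyReport, out_dir, rank: str = "phylum") -> list[Path]:
    """One stacked-composition figure for the community and one per category
    (taxon shares as bars, the category copy number as a line on a second
    axis). Empty categories are skipped with a logged notice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frame = report.fractions_by_rank[rank]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    frame.plot(kind="bar", stacked=True, ax=ax, width=0.85, colormap="tab20")
    ax.set_ylabel(f"fraction of reads ({rank})")
    ax.set_xlabel("sample")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = out / "community_composition.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    for category, breakdown in report.breakdowns.items():
        if breakdown.empty or not breakdown.to_numpy().any():
            logger.info("category %s has no signal; figure skipped", category)
            continue
        safe = category.replace("(", "").replace(")", "").replace("-", "_").lower()
        fig, ax = plt.subplots(figsize=(9, 4.5))
        breakdown.plot(kind="bar", stacked=True, ax=ax, width=0.85, colormap="tab20")
        ax2 = ax.twinx()
        cn = report.cn_by_category.get(category)
        if cn is not None:
            ax2.plot(range(len(cn)), cn.to_numpy(), "k-o", ms=3)
            ax2.set_ylabel("copies per genome")
        ax.set_ylabel("share of category coverage")
        ax.set_title(category)
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        path = out / f"category_{safe}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def configure_logging(verbose: bool = True) -> None:
    """Per-stage timing and row counts on stderr, for auditability of filters."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
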