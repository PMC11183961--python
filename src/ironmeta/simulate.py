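"""Ground-truthed mock study generator.

Emulates the community dynamics the pipeline was built to analyze: a
13-sample under-ice-to-summer time series in which a Bacteroidetes-like
phylum blooms from ~9% to ~55% of the reads while proteobacterial classes
hold or decline and an archaeal lineage almost disappears. Genomes realize
the producer/cheater split: one gammaproteobacterial clade carries the
siderophore-synthesis genes, a Bacteroidetes clade carries only
siderophore-transport genes. From stated parameters and a seed the module
emits every table the other stages consume — homology hit tables, per-ORF
coverages, per-contig read counts — plus the ground truth they should
recover.

Coverage noise is lognormal (strictly positive, heavy-ish tail, one
coefficient-of-variation parameter). Hit identities are drawn above the
identity floor of the intended assignment rank, with one within-genus sister
hit (so support breaks at species and the LCA lands at genus) and one
out-of-phylum decoy below the bitscore window (so the valid-hit filter is
exercised).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .functions import SYNTHESIS, CatalogEntry
from .io import HitRecord, write_tsv
from .pathways import PathwayNetwork, PathwayStatus, classify_pathway
from .taxtree import TaxonomyNode, TaxonomyTree


@dataclass(frozen=True, slots=True)
class TaxonTrajectory:
    """Read-fraction trajectory of one community member across the series."""

    taxon_id: str
    initial_fraction: float
    final_fraction: float
    trajectory: str = "linear"  # "linear" | "logistic"

    def __post_init__(self):
        for v in (self.initial_fraction, self.final_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"fraction {v} outside [0, 1]")
        if self.trajectory not in ("linear", "logistic"):
            raise ValidationError(f"unknown trajectory {self.trajectory!r}")


@dataclass(frozen=True, slots=True)
class CommunityScenario:
    """All stated parameters of a simulated study.

    ``reads_per_sample`` and ``noise_cv`` set the statistical difficulty;
    ``base_depth`` is the coverage of a single-copy gene in a genome at
    fraction 1. With ``exact_reads`` the multinomial read sampling is replaced
    by expected counts, for noise-free fidelity checks.
    """

    taxa: tuple[TaxonTrajectory, ...]
    n_samples: int = 13
    reads_per_sample: int = 100_000
    seed: int = 0
    noise_cv: float = 0.1
    base_depth: float = 100.0
    orfs_per_genome: int = 60
    orfs_per_contig: int = 6
    orf_length: int = 900
    hits_per_orf: int = 4
    exact_reads: bool = False

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not self.taxa:
            raise ValidationError("scenario needs at least one taxon")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]


@dataclass(frozen=True, slots=True)
class GenomeModel:
    """Gene complement (COG -> integer copies per genome) of one taxon."""

    taxon_id: str
    gene_complement: Mapping[str, int]
    role: str = "neither"  # "producer" | "cheater" | "neither"

    def __post_init__(self):
        if self.role not in ("producer", "cheater", "neither"):
            raise ValidationError(f"unknown role {self.role!r}")
        for cog, copies in self.gene_complement.items():
            if copies < 1:
                raise ValidationError(f"{self.taxon_id}: {cog} has copies < 1")


def validate_genomes(
    genomes: Sequence[GenomeModel],
    catalog: Mapping[str, CatalogEntry],
    marker_cogs: frozenset[str],
    ambiguous_cogs: set[str] | frozenset[str] = frozenset(),
) -> None:
    """Enforce the role invariants against a catalog and marker set.

    Producers carry >= 1 unambiguous synthesis COG; cheaters carry no
    synthesis COG and >= 1 outer-membrane ferric-siderophore transporter;
    every genome carries each marker exactly once.
    """
    for g in genomes:
        comp = g.gene_complement
        for m in marker_cogs:
            if comp.get(m, 0) != 1:
                raise ValidationError(
                    f"{g.taxon_id}: marker {m} must have exactly 1 copy"
                )
        synthesis = {
            c for c in comp if c in catalog and catalog[c].category == SYNTHESIS
        }
        if g.role == "producer":
            unamb = {
                c
                for c in synthesis
                if not catalog[c].ambiguous_synthesis and c not in ambiguous_cogs
            }
            if not unamb:
                raise ValidationError(
                    f"producer {g.taxon_id} lacks unambiguous synthesis COGs"
                )
        elif g.role == "cheater":
            if synthesis:
                raise ValidationError(
                    f"cheater {g.taxon_id} carries synthesis COGs {sorted(synthesis)}"
                )
            if not any(
                c in catalog and catalog[c].category == "Fe(III)-OM" for c in comp
            ):
                raise ValidationError(
                    f"cheater {g.taxon_id} lacks Fe(III)-OM transporter COGs"
                )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

_LINEAGES: dict[str, list[tuple[str, str]]] = {
    # species taxon_id -> (rank, taxon_id) chain below the root
    "Polaribacter_irgensii": [
        ("superkingdom", "Bacteria"),
        ("phylum", "Bacteroidetes"),
        ("class", "Flavobacteriia"),
        ("order", "Flavobacteriales"),
        ("family", "Flavobacteriaceae"),
        ("genus", "Polaribacter"),
        ("species", "Polaribacter_irgensii"),
    ],
    "Pelagibacter_ubique": [
        ("superkingdom", "Bacteria"),
        ("phylum", "Proteobacteria"),
        ("class", "Alphaproteobacteria"),
        ("order", "Pelagibacterales"),
        ("family", "Pelagibacteraceae"),
        ("genus", "Pelagibacter"),
        ("species", "Pelagibacter_ubique"),
    ],
    "Thioglobus_singularis": [
        ("superkingdom", "Bacteria"),
        ("phylum", "Proteobacteria"),
        ("class", "Gammaproteobacteria"),
        ("order", "Thiomicrospirales"),
        ("family", "Thioglobaceae"),
        ("genus", "Thioglobus"),
        ("species", "Thioglobus_singularis"),
    ],
    "Nitrosopumilus_maritimus": [
        ("superkingdom", "Archaea"),
        ("phylum", "Thaumarchaeota"),
        ("class", "Nitrososphaeria"),
        ("order", "Nitrosopumilales"),
        ("family", "Nitrosopumilaceae"),
        ("genus", "Nitrosopumilus"),
        ("species", "Nitrosopumilus_maritimus"),
    ],
    "Aquiluna_rubra": [
        ("superkingdom", "Bacteria"),
        ("phylum", "Actinobacteria"),
        ("class", "Actinomycetia"),
        ("order", "Micrococcales"),
        ("family", "Microbacteriaceae"),
        ("genus", "Aquiluna"),
        ("species", "Aquiluna_rubra"),
    ],
    "Rubritalea_marina": [
        ("superkingdom", "Bacteria"),
        ("phylum", "Verrucomicrobia"),
        ("class", "Verrucomicrobiae"),
        ("order", "Verrucomicrobiales"),
        ("family", "Rubritaleaceae"),
        ("genus", "Rubritalea"),
        ("species", "Rubritalea_marina"),
    ],
}

#: Sister species (same genus) used as near-miss hit subjects.
_SISTERS: dict[str, str] = {
    "Polaribacter_irgensii": "Polaribacter_dokdonensis",
    "Pelagibacter_ubique": "Pelagibacter_bermudensis",
    "Thioglobus_singularis": "Thioglobus_autotrophicus",
    "Nitrosopumilus_maritimus": "Nitrosopumilus_adriaticus",
    "Aquiluna_rubra": "Aquiluna_borealis",
    "Rubritalea_marina": "Rubritalea_sabuli",
}


def default_taxonomy() -> TaxonomyTree:
    """A ~50-node taxonomy covering the six default lineages plus sister species."""
    nodes: dict[str, TaxonomyNode] = {
        "root": TaxonomyNode("root", "", "norank", "cellular organisms")
    }
    for chain in _LINEAGES.values():
        parent = "root"
        for rank, taxon in chain:
            if taxon not in nodes:
                nodes[taxon] = TaxonomyNode(taxon, parent, rank, taxon)
            parent = taxon
    for species, sister in _SISTERS.items():
        genus = _LINEAGES[species][-2][1]
        nodes[sister] = TaxonomyNode(sister, genus, "species", sister)
    return TaxonomyTree(nodes.values())


def default_scenario(seed: int = 0, **overrides) -> CommunityScenario:
    """The default 13-sample bloom scenario.

    One Bacteroidetes genus rises from 9% to 55% of the reads; the
    alphaproteobacterial and archaeal members decline, the
    gammaproteobacterial producer holds roughly steady. Fractions sum to 1 at
    both endpoints, so the stated values are also the renormalized truth.
    """
    taxa = (
        TaxonTrajectory("Polaribacter_irgensii", 0.09, 0.55),
        TaxonTrajectory("Pelagibacter_ubique", 0.36, 0.21),
        TaxonTrajectory("Thioglobus_singularis", 0.20, 0.18),
        TaxonTrajectory("Nitrosopumilus_maritimus", 0.12, 0.005),
        TaxonTrajectory("Aquiluna_rubra", 0.04, 0.02),
        TaxonTrajectory("Rubritalea_marina", 0.19, 0.035),
    )
    return CommunityScenario(taxa=taxa, seed=seed, **overrides)


def _padded(complement: dict[str, int], tag: str, target: int) -> dict[str, int]:
    """Pad a complement with single-copy non-iron background COGs to a fixed
    genome size, so read fractions equal cell fractions."""
    total = sum(complement.values())
    if total > target:
        raise ValidationError(f"complement of {tag} exceeds {target} ORFs")
    out = dict(complement)
    for i in range(target - total):
        out[f"COGX{tag}{i:03d}"] = 1
    return out


def default_genomes(
    marker_cogs: frozenset[str], orfs_per_genome: int = 60
) -> list[GenomeModel]:
    """Six genomes realizing the producer/cheater split.

    The gammaproteobacterial producer carries the full synthesis complement of
    the eight bundled present pathways; the Bacteroidetes cheater carries only
    siderophore-transport genes. Every genome carries the divalent-cation
    transporter COG0803 at exactly one copy (a convenient 1-copy truth for
    copy-number recovery checks) and each marker once.
    """
    markers = {m: 1 for m in sorted(marker_cogs)}
    producer_synthesis = {
        c: 1
        for c in (
            "COG1169", "COG0318", "COG1021", "COG1020", "COG0031", "COG1535",
            "COG1819", "COG3161", "COG3486", "COG4362", "COG4264", "COG3475",
            "COG4947", "COG3182", "COG3962",
        )
    }
    n = orfs_per_genome
    return [
        GenomeModel(
            "Polaribacter_irgensii",
            _padded(
                {**markers, "COG1629": 3, "COG4771": 1, "COG0614": 1,
                 "COG0370": 1, "COG0803": 1, "COG0735": 2, "COG4772": 1},
                "bct", n,
            ),
            role="cheater",
        ),
        GenomeModel(
            "Pelagibacter_ubique",
            _padded({**markers, "COG0370": 1, "COG0803": 1, "COG0735": 1}, "alp", n),
        ),
        GenomeModel(
            "Thioglobus_singularis",
            _padded(
                {**markers, **producer_synthesis, "COG1629": 1, "COG0803": 1,
                 "COG0735": 1, "COG4772": 1, "COG1178": 1},
                "gam", n,
            ),
            role="producer",
        ),
        GenomeModel(
            "Nitrosopumilus_maritimus",
            _padded({**markers, "COG0803": 1, "COG1108": 1, "COG1528": 1}, "tha", n),
        ),
        GenomeModel(
            "Aquiluna_rubra",
            _padded(
                {**markers, "COG4774": 1, "COG4558": 1, "COG0803": 1, "COG1321": 1},
                "act", n,
            ),
        ),
        GenomeModel(
            "Rubritalea_marina",
            _padded({**markers, "COG0370": 1, "COG0803": 1, "COG2193": 1}, "ver", n),
        ),
    ]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_community(scenario: CommunityScenario) -> pd.DataFrame:
    """Ground-truth per-sample taxon read fractions (samples x taxa).

    Trajectories interpolate initial -> final fractions (linearly or along a
    logistic ramp) and each time point is renormalized to sum to 1.
    """
    n = scenario.n_samples
    cols = {}
    for tt in scenario.taxa:
        t = np.linspace(0.0, 1.0, n)
        if tt.trajectory == "logistic":
            k = 10.0
            raw = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
            lo, hi = raw[0], raw[-1]
            t = (raw - lo) / (hi - lo)
        cols[tt.taxon_id] = tt.initial_fraction + (
            tt.final_fraction - tt.initial_fraction
        ) * t
    frame = pd.DataFrame(cols, index=scenario.sample_ids)
    sums = frame.sum(axis=1)
    if (sums <= 0).any():
        raise ValidationError("taxon fractions sum to zero at some time point")
    return frame.div(sums, axis=0)


@dataclass(frozen=True, slots=True)
class OrfSpec:
    orf_id: str
    contig_id: str
    taxon_id: str
    cog_id: str
    length: int


def build_orf_layout(
    genomes: Sequence[GenomeModel], scenario: CommunityScenario
) -> list[OrfSpec]:
    """Deterministic ORF/contig layout: one ORF per gene copy, contigs of
    ``orfs_per_contig`` consecutive ORFs within each genome."""
    layout: list[OrfSpec] = []
    for g in genomes:
        orfs = []
        for cog, copies in g.gene_complement.items():
            orfs.extend([cog] * copies)
        for i, cog in enumerate(orfs):
            contig = f"{g.taxon_id}_c{i // scenario.orfs_per_contig + 1:02d}"
            layout.append(
                OrfSpec(
                    orf_id=f"{contig}_orf{i % scenario.orfs_per_contig + 1}",
                    contig_id=contig,
                    taxon_id=g.taxon_id,
                    cog_id=cog,
                    length=scenario.orf_length,
                )
            )
    return layout


def simulate_hits(
    layout: Sequence[OrfSpec],
    tree: TaxonomyTree,
    scenario: CommunityScenario,
    rng: np.random.Generator,
    sisters: Mapping[str, str] | None = None,
    decoy_taxon: str | None = None,
) -> dict[str, list[HitRecord]]:
    """Per-ORF homology hit tables recoverable at genus rank by the default LCA.

    Each ORF gets ``hits_per_orf`` valid hits — the best and all but one from
    the true species, one from a sister species of the same genus — plus one
    out-of-lineage decoy whose bitscore falls below the 80% window.
    """
    if sisters is None:
        sisters = _SISTERS
    hits: dict[str, list[HitRecord]] = {}
    taxa = sorted({o.taxon_id for o in layout})
    for orf in layout:
        best_identity = float(rng.uniform(62.0, 97.0))
        best_bitscore = float(rng.uniform(180.0, 240.0))
        records = [
            HitRecord(
                query_id=orf.orf_id,
                subject_id=f"{orf.orf_id}_h0",
                percent_identity=round(best_identity, 1),
                alignment_length=orf.length // 3,
                bitscore=round(best_bitscore, 1),
                evalue=1e-40,
                subject_taxon=orf.taxon_id,
                subject_cog=orf.cog_id,
            )
        ]
        n_extra = max(scenario.hits_per_orf - 1, 1)
        for k in range(1, n_extra + 1):
            if k == n_extra:  # last valid hit comes from a within-genus sister
                taxon = sisters.get(orf.taxon_id, orf.taxon_id)
            else:
                taxon = orf.taxon_id
            records.append(
                HitRecord(
                    query_id=orf.orf_id,
                    subject_id=f"{orf.orf_id}_h{k}",
                    percent_identity=round(
                        max(best_identity - float(rng.uniform(0.0, 5.0)), 40.0), 1
                    ),
                    alignment_length=orf.length // 3,
                    bitscore=round(best_bitscore * float(rng.uniform(0.85, 0.999)), 1),
                    evalue=1e-35,
                    subject_taxon=taxon if taxon in tree else orf.taxon_id,
                    subject_cog=orf.cog_id,
                )
            )
        # decoy below the bitscore window, from a different lineage
        other = decoy_taxon or next(
            (t for t in taxa if t != orf.taxon_id), orf.taxon_id
        )
        records.append(
            HitRecord(
                query_id=orf.orf_id,
                subject_id=f"{orf.orf_id}_decoy",
                percent_identity=round(best_identity * 0.5, 1),
                alignment_length=orf.length // 3,
                bitscore=round(best_bitscore * 0.5, 1),
                evalue=1e-10,
                subject_taxon=other,
                subject_cog="",
            )
        )
        hits[orf.orf_id] = records
    return hits


@dataclass(slots=True)
class SampleTables:
    sample_id: str
    orf_coverage: dict[str, float]
    read_counts: dict[str, float]


def simulate_sample_tables(
    fractions: Mapping[str, float],
    layout: Sequence[OrfSpec],
    scenario: CommunityScenario,
    rng: np.random.Generator,
    sample_id: str = "s01",
) -> SampleTables:
    """Coverage and read-count tables for one sample.

    Per-ORF coverage is base_depth x taxon fraction, perturbed by lognormal
    noise with the scenario's coefficient of variation; per-contig read counts
    are multinomial over contigs with probabilities proportional to
    coverage x length (or expected counts when ``exact_reads``).
    """
    cov: dict[str, float] = {}
    if scenario.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=len(layout))
    else:
        noise = np.ones(len(layout))
    contig_weight: dict[str, float] = {}
    for orf, eps in zip(layout, noise):
        c = scenario.base_depth * float(fractions.get(orf.taxon_id, 0.0)) * float(eps)
        cov[orf.orf_id] = c
        contig_weight[orf.contig_id] = (
            contig_weight.get(orf.contig_id, 0.0) + c * orf.length
        )
    contigs = list(contig_weight)
    weights = np.array([contig_weight[c] for c in contigs], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValidationError("all coverages are zero in this sample")
    probs = weights / total
    if scenario.exact_reads:
        counts = probs * scenario.reads_per_sample
    else:
        counts = rng.multinomial(scenario.reads_per_sample, probs).astype(float)
    return SampleTables(
        sample_id=sample_id,
        orf_coverage=cov,
        read_counts=dict(zip(contigs, counts)),
    )


@dataclass(slots=True)
class SimulatedStudy:
    """Everything one simulated study produces, plus its ground truth."""

    scenario: CommunityScenario
    tree: TaxonomyTree
    genomes: list[GenomeModel]
    layout: list[OrfSpec]
    hits: dict[str, list[HitRecord]]
    fractions: pd.DataFrame  # truth, samples x taxa
    samples: list[SampleTables]

    @property
    def contig_map(self) -> dict[str, str]:
        return {o.orf_id: o.contig_id for o in self.layout}

    @property
    def true_cogs(self) -> dict[str, str]:
        return {o.orf_id: o.cog_id for o in self.layout}

    @property
    def true_taxa(self) -> dict[str, str]:
        return {o.orf_id: o.taxon_id for o in self.layout}


def simulate_study(
    scenario: CommunityScenario,
    tree: TaxonomyTree | None = None,
    genomes: Sequence[GenomeModel] | None = None,
    marker_cogs: frozenset[str] | None = None,
) -> SimulatedStudy:
    """Generate a complete study: deterministic given the scenario and seed."""
    if tree is None:
        tree = default_taxonomy()
    if genomes is None:
        if marker_cogs is None:
            from .abundance import default_marker_set

            marker_cogs = default_marker_set().cog_ids
        genomes = default_genomes(marker_cogs, scenario.orfs_per_genome)
    missing = {tt.taxon_id for tt in scenario.taxa} - {g.taxon_id for g in genomes}
    if missing:
        raise ValidationError(f"no genome model for taxa {sorted(missing)}")
    rng = np.random.default_rng(scenario.seed)
    layout = build_orf_layout(list(genomes), scenario)
    hits = simulate_hits(layout, tree, scenario, rng)
    fractions = simulate_community(scenario)
    samples = [
        simulate_sample_tables(fractions.loc[sid], layout, scenario, rng, sid)
        for sid in scenario.sample_ids
    ]
    return SimulatedStudy(
        scenario=scenario,
        tree=tree,
        genomes=list(genomes),
        layout=layout,
        hits=hits,
        fractions=fractions,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def true_copy_numbers(
    fractions: pd.DataFrame, genomes: Sequence[GenomeModel]
) -> pd.DataFrame:
    """True community copy number of every COG per sample.

    With all genomes the same size and every marker single-copy, the marker
    median equals the total cell density, so the true CN of COG x in sample s
    is sum_t fraction[t, s] * copies_t(x).
    """
    cogs = sorted({c for g in genomes for c in g.gene_complement})
    by_taxon = {g.taxon_id: g.gene_complement for g in genomes}
    data = {
        cog: fractions.mul(
            [by_taxon[t].get(cog, 0) for t in fractions.columns], axis=1
        ).sum(axis=1)
        for cog in cogs
    }
    return pd.DataFrame(data, index=fractions.index)


def true_pathway_statuses(
    fractions: pd.DataFrame,
    genomes: Sequence[GenomeModel],
    network: PathwayNetwork,
) -> pd.DataFrame:
    """Noise-free pathway statuses per sample plus the study-level best status."""
    by_taxon = {g.taxon_id: set(g.gene_complement) for g in genomes}
    pathway_ids = sorted(network.pathways)
    rows = {}
    for sid, row in fractions.iterrows():
        present: set[str] = set()
        for taxon, frac in row.items():
            if frac > 0:
                present |= by_taxon[taxon]
        rows[sid] = {
            pid: classify_pathway(pid, network, present).status for pid in pathway_ids
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=pathway_ids)
    frame.loc["study"] = frame.max(axis=0)
    return frame.map(lambda s: str(PathwayStatus(s)))


def export_ground_truth(
    study: SimulatedStudy, network: PathwayNetwork, out_dir=None
) -> dict[str, pd.DataFrame]:
    """Truth tables recovery tests compare against; optionally written as TSV."""
    truth = {
        "true_fractions": study.fractions,
        "true_copy_numbers": true_copy_numbers(study.fractions, study.genomes),
        "true_pathway_status": true_pathway_statuses(
            study.fractions, study.genomes, network
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        for name, frame in truth.items():
            write_tsv(frame, out / f"{name}.tsv")
    return truth


# ---------------------------------------------------------------------------
# TSV export of the simulated inputs (the dialects the other modules read)
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, out_dir) -> dict[str, Path]:
    """Write hit/coverage/read-count/taxonomy tables in the pipeline's input
    dialects; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    hit_rows, tax_rows, cog_rows = [], [], []
    for orf_hits in study.hits.values():
        for h in orf_hits:
            hit_rows.append(
                (
                    h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
                    0, 0, 1, h.alignment_length, 1, h.alignment_length,
                    h.evalue, h.bitscore,
                )
            )
            if h.subject_taxon:
                tax_rows.append((h.subject_id, h.subject_taxon))
            if h.subject_cog:
                cog_rows.append((h.subject_id, h.subject_cog))
    paths["hits"] = out / "hits.tsv"
    pd.DataFrame(hit_rows).to_csv(
        paths["hits"], sep="\t", header=False, index=False, float_format="%.10g"
    )
    paths["subject_taxon"] = out / "subject_taxon.tsv"
    pd.DataFrame(tax_rows).to_csv(
        paths["subject_taxon"], sep="\t", header=False, index=False
    )
    paths["subject_cog"] = out / "subject_cog.tsv"
    pd.DataFrame(cog_rows).to_csv(
        paths["subject_cog"], sep="\t", header=False, index=False
    )

    tree = study.tree
    tax_table = pd.DataFrame(
        [
            (t, tree.node(t).parent_id or ".", tree.node(t).rank, tree.node(t).name)
            for t in tree
        ],
        columns=["taxon_id", "parent_id", "rank", "name"],
    )
    paths["taxonomy"] = out / "taxonomy.tsv"
    tax_table.to_csv(paths["taxonomy"], sep="\t", index=False)

    coverage = pd.DataFrame(
        {s.sample_id: s.orf_coverage for s in study.samples}
    ).rename_axis("orf_id")
    paths["coverage"] = out / "coverage.tsv"
    write_tsv(coverage, paths["coverage"])

    reads = pd.DataFrame(
        {s.sample_id: s.read_counts for s in study.samples}
    ).rename_axis("contig_id")
    paths["read_counts"] = out / "read_counts.tsv"
    write_tsv(reads, paths["read_counts"])

    contig_map = pd.DataFrame(
        sorted(study.contig_map.items()), columns=["orf_id", "contig_id"]
    )
    paths["contig_map"] = out / "contig_map.tsv"
    contig_map.to_csv(paths["contig_map"], sep="\t", index=False)
    return paths
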