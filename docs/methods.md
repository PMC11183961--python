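# Methods

This note documents the models and procedures `ironmeta` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the written rules left room.

## 1. Taxonomic assignment

### Per-ORF LCA

Input: the homology hits of one ORF against a taxon-labeled protein
reference, as 12-column tabular alignments. The procedure:

1. **E-value filter.** Hits with e-value > `evalue_cutoff` (default 1e-3)
   are discarded.
2. **Valid-hit window.** The best hit maximizes bitscore (ties broken by
   lower e-value, then higher identity, then input order — a total,
   deterministic order). Valid hits have bitscore ≥ `bitscore_fraction`
   (default 0.80) of the best bitscore and identity within a window of the
   best identity.
3. **Support.** For each rank from species up to superkingdom, each valid
   hit votes for its lineage ancestor at that rank; a taxon supported by
   ≥ `support_fraction` (default 0.90) of the valid hits at the deepest such
   rank is the candidate. Hits without a taxon label stay in the
   denominator: they are valid hits that support nothing, which keeps a
   single labeled hit among many unlabeled ones from producing a deep call.
4. **Identity floors.** The candidate is truncated to the deepest rank whose
   minimum identity the best valid hit's identity meets:
   species 85, genus 60, family 55, order 50, class 46, phylum 42,
   superkingdom 40 (percent). Below 40% the ORF is unclassified.

Support is evaluated per rank independently (a taxon can be supported at
genus even when no single species reaches support). Note that with the
default 0.9 support no two taxa can be supported at the same rank, so the
procedure is deterministic without a tie-break at that stage.

**Identity window reading.** "Identity no smaller than 10% of the best hit's
identity" is implemented literally as relative (≥ 0.1 × best identity),
which is a weak filter; `LcaParams(identity_mode="absolute")` switches to
the stricter reading (≥ best identity − 10 percentage points). The identity
compared against the rank floors is the best valid hit's
(`floor_identity="median"` uses the median of valid-hit identities instead).

**Exact thresholds.** All comparisons convert operands through
`Fraction(str(x))`, i.e. exact decimal arithmetic. This makes boundary cases
behave exactly as written — 9 of 10 hits pass the 90% rule, a bitscore at
exactly 80% of the best is retained, an identity exactly at a floor reports
that rank — instead of depending on binary float rounding (e.g. in floats,
`0.9 * 10 > 9`).

### Contig consensus

Walking ranks from superkingdom downward, a taxon is accepted at a rank when
it covers ≥ 50% of all ORFs on the contig (`min_fraction_all`) and ≥ 70% of
the ORFs annotated at that rank (`min_fraction_annotated`), and descends
from the taxon accepted at the previous rank. The consensus is the deepest
accepted taxon; failing at the first evaluated rank leaves the contig
unclassified. Unclassified ORFs count toward the total but never toward the
annotated count, and a rank at which no ORF carries any taxon (a lineage gap)
is skipped rather than terminating the walk. Both thresholds together
guarantee a unique winner per rank (two taxa cannot both hold > half of the
annotated ORFs), so no tie-break is needed.

Contig taxonomies weight read counts for community composition; ORF
taxonomies attribute the coverage of individual functions (the per-category
breakdowns).

## 2. Functional annotation and the iron catalog

Each ORF receives at most one COG: the best qualifying hit (same e-value
cutoff and tie-breaks as above) against a COG-labeled reference. COGs map to
nine iron-function categories (ferrous iron, Fe(III)-OM = TonB-dependent
outer-membrane ferric-siderophore receptors, Fe(III)-CM = cell-membrane
ferric ABC transporters, divalent cations, dicitrate, heme, storage,
regulators, siderophore synthesis); the vocabulary is closed and each COG
belongs to exactly one category. ORFs whose COG is uncatalogued form an
implicit non-iron pool, so category sizes always partition the ORF set.

The bundled catalog (41 COGs) is a reduced working set spanning all nine
categories, intended for fixtures and the simulator; a real analysis supplies
its own curated catalog in the same four-column TSV. Gene names in the
catalog are examples, not exhaustive membership.

## 3. Copy-number normalization

Coverage is consumed as precomputed per-ORF mean aligned depth (aligned
bases / ORF length); producing it (read mapping) is out of scope. Per-COG
aggregate coverage is the sum over that COG's ORFs. The normalizer is the
median of the 10 per-marker aggregates of universal single-copy marker genes
(USiCGs): housekeeping genes present exactly once in essentially all
prokaryotic genomes, so their median coverage estimates "genomes of sequence"
per sample. Copy number = aggregate coverage / marker median, interpreted as
average copies per genome in the community. Properties (all tested): a marker
aggregate equal to the median has CN exactly 1; CNs are invariant under
global coverage rescaling; category CN is the sum over member COGs.

The marker list is configuration; the bundled default is the widely used set
of 10 universal single-copy COGs (COG0012, 0016, 0018, 0172, 0215, 0495,
0525, 0533, 0541, 0552). Markers with no ORFs contribute 0 to the median; a
profile whose median is 0 cannot be normalized and is an error rather than a
silent NaN. Per-marker aggregation is a sum over that marker's ORFs
(`aggregate="mean"` available).

## 4. Siderophore pathway calling and quantitation

The pathway network is a pathway → gene → COG multi-map: one COG may appear
in many pathways (and may also cover enzymes unrelated to siderophores —
the *ambiguous* flag), and one gene may map to several COGs (e.g. a
2,3-dihydroxybenzoate-AMP ligase assigned to both a promiscuous
acyl-adenylate COG and a specific one). Uniqueness (COG in exactly one
pathway, not ambiguous) is always derived from the current network, never
stored.

Presence, per sample, from the set of detected COGs (aggregate coverage
above a floor; default floor 0, i.e. any evidence):

1. all genes detected (a gene is detected when **any** of its COGs is) →
   **MAYBE**;
2. additionally ≥ 1 detected COG unique to the pathway → **PRESENT**;
3. any gene undetected → **ABSENT**.

Uniqueness is operationalized at COG level because detection is COG-based; a
gene-level reading cannot be evaluated from COG profiles. Ambiguous COGs
count toward completeness (criterion 1) but never toward uniqueness or
quantitation. Statuses are monotone under adding detected COGs
(ABSENT → MAYBE → PRESENT).

Quantitation sums the coverage of synthesis-category COGs that are not
flagged ambiguous (in the catalog or the network) and divides by the marker
median. Because ambiguous COGs also contain genuine synthesis genes, this is
a documented underestimate.

Presence is reported per sample **and** as a study-level best status
(PRESENT > MAYBE > ABSENT across samples), covering both the per-sample and
the pooled reading of "present in the study".

The bundled network defines 12 pathways with 8 present / 4 absent under the
default simulated community, including a pathway missing exactly one gene
(called ABSENT despite being otherwise complete). Beyond the multi-COG and
shared-COG structure described above, its gene-to-COG assignments are
synthetic-but-plausible working content for fixtures and the simulator; a
real analysis supplies its own curated network in the same TSV schema.

## 5. The synthetic community generator

The generator encodes the study conditions every recovery test runs under:

- **Community.** Six lineages across five bacterial phyla (two
  proteobacterial classes) and one archaeal phylum, 13 samples. Read
  fractions interpolate linearly (or along a logistic ramp) between stated
  endpoints and are renormalized to sum to 1 per sample. The default
  trajectory: a Bacteroidetes genus blooms 9% → 55%; an
  alphaproteobacterial lineage declines 36% → 21%; the gammaproteobacterial
  producer holds 20% → 18%; the archaeon declines 12% → 0.5%;
  the remaining lineages decline. Endpoints sum to 1, so the stated values
  are also the truth after renormalization.
- **Genomes.** Integer COG copy numbers; every genome carries each of the 10
  markers exactly once, and all genomes are padded with single-copy non-iron
  background COGs to the same size (default 60 ORFs) so read fractions equal
  cell fractions. Roles are enforced invariants: the *producer*
  (gammaproteobacterial) carries ≥ 1 unambiguous synthesis COG (in the
  default, the full complement of the 8 present pathways); the *cheater*
  (Bacteroidetes) carries no synthesis COG but 4 outer-membrane
  ferric-siderophore receptor copies. Every genome carries one copy of the
  same divalent-cation transporter, giving a known community CN of exactly 1
  for recovery checks.
- **Coverage.** Per-ORF coverage = base depth (100×) × taxon fraction ×
  gene copies-as-ORFs, perturbed by lognormal noise with coefficient of
  variation `noise_cv` (default 0.1). Lognormal because coverage noise is
  strictly positive with a heavy-ish tail and one cv parameter suffices.
- **Reads.** Contigs are runs of 6 consecutive ORFs; per-contig read counts
  are multinomial (default 10⁵ reads/sample) with probabilities proportional
  to coverage × length. `exact_reads=True` replaces sampling with expected
  counts for noise-free fidelity checks.
- **Hits.** Per ORF: a best hit and two more from the true species, one from
  a sister species of the same genus (so support breaks at species and the
  default LCA lands exactly at genus), and one out-of-lineage decoy below
  the bitscore window (so the valid-hit filter is exercised). Identities are
  drawn uniformly in [62, 97]: above the genus floor, crossing the species
  floor.

Determinism: all randomness flows from one `numpy` generator seeded by the
scenario, and all writers format floats with `%.10g`, so identical scenario +
seed ⇒ byte-identical output files.

**What the simulator does not emulate:** sequence-level effects (assembly
errors, chimeric contigs, ORF-calling mistakes), database mislabeling and
horizontal transfer (hits are honest up to the built-in sister/decoy
structure), genome-size variation between taxa, strain-level diversity,
length/GC coverage bias, and unmapped or non-prokaryotic reads. Passing the
recovery tests therefore shows the *inference rules* are implemented
correctly and statistically well-behaved under honest noise — not that any
real dataset meets these assumptions.

## 6. Problem sizes and numerical choices

- Exhaustive oracle checks run on toy problems sized for seconds: LCA over a
  24-node tree, ≤ 6 hits, the best identity swept across every rank floor
  ± 1 (≈ 9,700 cases); consensus over all compositions of ≤ 10 ORFs from 7
  annotation choices (≈ 19,000 cases); pathway calls over every subset of an
  8-COG universe on a 3-pathway network.
- Statistical recovery uses 100 seeded replicates of the default scenario
  (360 ORFs, 13 samples, 10⁵ reads/sample, cv 0.1) — about 15 s total. The
  recovery criteria: worst-case phylum fraction error ≤ 2 percentage points;
  time-averaged CN of the known 1-copy transporter within ± 10% of 1;
  ≥ 95% of synthesis coverage attributed to the producer clade; mean error
  of the cheater clade's Fe(III)-OM share ≤ 5 points — each required in
  ≥ 95% of replicates.
- Degenerate inputs fail loudly: empty pathway tables, all-zero marker
  profiles, zero total reads, cycles or multiple roots in the taxonomy, and
  unknown taxa referenced by hits are all errors, not warnings.
- Missing values in TSVs are `.`; fractions are reported in [0, 1] in tables
  and converted to percentages only in user-facing summaries.

## 7. Known limitations

- One COG per ORF (best hit), although pathway definitions map genes to
  several COGs; the network side handles multi-COG genes, the annotation
  side deliberately does not.
- The ambiguity flags on COGs are *inputs* (they encode external curation
  against a protein knowledge base) and cannot be recomputed here.
- Synthesis quantitation is an underestimate by construction; comparing it
  across studies requires the same ambiguity curation.
- The consensus walk stops at the first failing rank; a taxon deeper in the
  lineage that would qualify in isolation is never reported without its
  qualifying ancestor chain.
- Per-marker aggregation uses the coverage sum over a marker's ORFs; where a
  marker family is badly fragmented across many partial ORFs this can
  overweight it relative to a mean-based aggregate (`aggregate="mean"`).
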