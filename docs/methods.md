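# Methods

This note documents the models, conventions and numerical choices behind the
pipeline, what the synthetic generator does and does not emulate, and the
known limitations.

## Classification model

### Clade assignment (nearest anchor)

Large Ni-CODH surveys assign clades by building a multiple alignment and an
approximate-ML tree. This package deliberately replaces that workflow with
**nearest-anchor scoring**: each query is globally aligned (Needleman–Wunsch,
BLOSUM62, affine gaps) against one reference anchor per clade A–G and takes
the clade of its best score. This is a declared stand-in, not a
re-implementation of tree inference: near clade boundaries the two methods
can disagree, so the call carries the top-two score margin and an
`ambiguous` flag (margin < 5 score units, configurable). Exact ties resolve
to the alphabetically first clade and are always flagged. Ambiguous calls
are reported, never silently forced.

Alignment conventions, fixed because they differ between tools:

* substitution table: BLOSUM62 with the `X` row/column zeroed (unknown
  residues are neutral);
* affine gaps: a gap of length L costs 11 + 1·(L−1), i.e. a single-residue
  gap costs 11; end gaps are penalized like internal ones;
* empty input: defined as the all-gap alignment with the same cost formula;
* traceback: the aligner's first optimal path, which is deterministic.

### Anchor profiles and position mapping

An `AnchorProfile` records, on the anchor sequence, the D-region span, the
four B-cluster Cys, the six C-cluster sites, the acid–base pair, E-/F-cluster
positions (clade A only) and the core boundaries (`core_start`/`core_end`)
separating the aligned core from the N-/C-terminal extension regions. All
coordinates are 1-based inclusive. Mapping a query against the anchor gives,
for every anchor position, either the aligned query coordinate or "absent"
(deletion). Region reads (D-region, terminal extensions, insertion spans)
take the min–max query span of the mapped columns, so query insertions
inside a region are included.

### Signature extraction

* **D-region**: the mapped span widened by 5 residues on each side (the
  published analysis reads the region from alignment blocks whose exact
  boundaries are unstated; the widened-span convention is this package's).
  Pattern precedence is I > III > II — most specific first; regions with one
  or no Cys type as "none". The type II spacer range is 7–13 residues.
* **Terminal Cys motifs**: maximal Cys count within any 20-residue window of
  the extension region, reported when ≥ 2 and capped at 4. The source
  description ("two to four Cys") names no window; 20 residues comfortably
  covers the described motifs while ignoring isolated distant Cys.
* **His-rich extensions**: ≥ 4 His in the region plus at least two mutually
  overlapping `H-x-H` matches (observed natural repeats run 4–48 His; the
  upper bound is observational and not enforced).
* **Insertions**: a C-cluster insertion is ≥ 4 Cys strictly between the
  acid–base His-site column and the C-cluster His column; E/F-region
  insertions are counted as disjoint ≤ 30-residue windows holding ≥ 4 Cys,
  greedily left to right (window size is a package choice; the described A-5
  insertions are two tandem Cys×4 blocks).
* **Fusion**: query longer than anchor + 200 residues. The original fusion
  search was manual; this is a conservative automatic proxy.

### Decision table

The 24 signature rows live in `nicodh.classify.STRUCTURAL_GROUPS`; the
decision chain applies them per clade exactly as printed (e.g. clade B
requires type II D + His/Lys catalysts and splits on Cys2 ∈ {C, D, E} and
His-rich termini; clade C requires Tyr/Gln catalysts; single-member clade G
keeps its own label G-1). Any unmatched combination — including incomplete
B-clusters — returns "others"; the function is total. Two "incomplete"
D-region states (a single Cys vs none) collapse to d_type "none", matching
how the published table prints both as "–".

## Curation rules

* Hit filter: keep iff bit score ≥ 200 **and** length ≥ 550 (printed as
  strict `<` exclusions, so boundary values are retained).
* Non-redundancy is by identifier; one identifier with two different
  sequences is a data-integrity error. Identical sequences under different
  identifiers are both kept (nr-database semantics).
* Completeness: a query is dropped when any D-/B-/C-cluster or acid–base
  position maps to a deletion; substitutions pass.
* Genome selection: within a species, one genome per distinct CODH-id set,
  priority reference > representative > complete assembly > draft (all
  non-complete levels rank equally as draft), ties to the smallest genome
  id. The tie-break is a package choice; the source names only the four
  tiers.

## Genomic context

* Intergenic gap = `next.start − current.end − 1`; overlapping genes count
  as gap 0. "Within 300 bp" is read as ≤ 300 and pinned by tests.
* Directons extend from the CODH gene while same-strand, gap ≤ 300 bp, and
  at most 15 genes per side. Only non-pseudo CDS rows participate.
* Context expansion adds flanking genes carrying ≥ 1 enriched COG, any
  strand, any distance, stopping at the first flank without one. No
  distance or count cap is applied because none is stated.
* Loci are **per CODH gene**: two CODH genes in one directon give two loci
  with identical directon gene sets.

## Enrichment and network

* Contingency unit: protein-coding genes across all CODH-encoding genomes,
  inside any CODH directon vs outside. The background universe is not
  stated explicitly in the source analysis; this reading matches "enriched
  within the directons". A gene carrying a COG multiple times counts once.
* The test is the one-sided (enrichment) Fisher exact test, computed as the
  hypergeometric upper tail via log-factorial sums (checked against exact
  integer enumeration to < 1e-12 for all tables with total ≤ 40, and
  against scipy). Whether the original test was one- or two-sided is
  unstated; one-sided is the biologically posed question and is declared
  here. Zero-margin tables give p = 1.
* BH control via statsmodels; a COG is enriched iff p < 0.05 and q < 0.05
  (both stated conditions; under BH the q condition dominates). COG1151 and
  COG1152 — the CODH COGs themselves — are never tested.
* Annotation rows with an e-value column are pre-filtered at < 1e-6.
* Feature matrix columns are namespaced (`COG:`, `SG:`, `FAM:`); taxonomy
  features are family-level, with phylum kept as metadata. The ≥ 25-locus
  floor applies to COG columns only (scoped by the source's parenthetical);
  group and taxonomy columns always remain. Feature pairs with an empty
  locus set are skipped, not scored 0.

## Synthetic generator

The generator plants known structure so recovery is measurable:

* **Scaffolds**: per-clade i.i.d. sequences of length 650 over an
  18-residue alphabet excluding Cys and His, so planted Cys/His motifs are
  unambiguous. 650 is a choice within the ≥ 550 length regime of real
  Ni-CODHs (no empirical length law is published).
* **Templates**: each of the 24 groups is a motif recipe (D pattern, B/C/E/F
  Cys, catalysts, accessory motifs) planted at fixed layout positions on
  its clade scaffold. Mutation applies per-site substitutions from the same
  Cys/His-free alphabet, never touching planted motif residues when
  protection is on (default rate 0.05).
* **Genomes**: one replicon per genome, 60 genes by default, bounded-uniform
  gene lengths (300–1500 bp) and intergenic gaps (50–200 bp, always within
  the directon threshold so directons are broken by strand flips only);
  strand flips at 0.2 per adjacent pair, except in a protected ±3-gene
  window around the CODH gene, which guarantees a plantable directon.
  Enriched COGs land on a uniformly chosen protected-window gene with their
  stated probability; background COGs are sprinkled per-gene at their
  genome-wide frequency; CODH genes are annotated COG1151 to exercise the
  exclusion rule. Protein ids are `SYN_<genome>_<index>`.

What the generator does **not** emulate: realistic amino-acid substitution
processes (mutations are uniform over a reduced alphabet), nucleotide
sequences, real length/gap distributions, overlapping genes, paralog
structure within genomes, or phylogenetic correlation between genomes.
Passing tests therefore demonstrate correctness of the rules and robustness
to uniform background noise — not classifier performance on real, divergent
sequences, where clade-boundary ambiguity and alignment error matter more.

## Problem sizes and determinism

Test and acceptance experiments use deliberately modest sizes chosen as
sufficient for their statistical purpose: 24 noise-free round-trips, 200
mutation replicates at 5 %, exhaustive Fisher enumeration to table total 40,
100 random octamer pairs against the alignment oracle, 1000 random replicons
against the directon oracle, and a 50-genome end-to-end experiment with 3
planted COGs (co-occurrence 0.9) over 200 background COGs. All randomness
flows from explicit integer seeds; identical seeds give byte-identical
fixture bundles and pipeline outputs.

## Known limitations

* Nearest-anchor clade calls can disagree with tree-based assignment near
  clade boundaries; flagged, not resolved.
* The anchor set is synthetic by default. For real data, users supply their
  own anchor sidecar (curated representative sequences with verified
  cluster positions); classification quality is bounded by anchor quality.
* The decision table encodes the published signature rows; proteins with
  novel signatures land in "others" rather than forcing a nearest group.
* Fusion detection by length excess is a proxy; domain-level evidence would
  be required for a real call.
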