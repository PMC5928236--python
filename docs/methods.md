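# Methods

## Abundance model

A contig's **coverage** is its mean per-base read depth over *all*
positions, zero-depth positions included.  This is the natural quantity
produced by a samtools-depth-style parser, and it makes the additivity
identity exact: an ORF spanning the whole contig has exactly the contig's
coverage.  ORF coverage is the same mean restricted to the ORF's 1-based
inclusive start–stop window and is strand-independent.

**Normalization.** Coverage is divided by the giga base pairs of reads
recruited to the assembly, giving *coverage per Gbp recruited*.  One
recruitment total per sample is shared by contig and ORF normalization.
The recruited-base total counts, per primary mapped alignment, the bases
of reference consumed by the CIGAR string (M/D/N/=/X).  Counting aligned
bases rather than full read lengths keeps soft-clipped tails out of the
denominator; a `count_full_read_length` flag switches to full read lengths
for pipelines that prefer the read-based denominator.  Secondary and
supplementary alignments are excluded everywhere, so each read is
recruited at most once.  Normalization by a zero-Gbp recruitment is an
error rather than a zero or NaN.  `log2_abundance` (log2 of abundance plus
a pseudocount, default 1e-12 of the maximum abundance when used through
the plotting path) is presentational only and sits outside every
downstream computation.

## Taxonomy and function by summed bit score

Per contig, bit scores of **all** E-value-qualifying (E ≤ 1e-3,
inclusive), taxid-annotated hits of all the contig's ORFs are summed per
taxid; the largest sum wins.  Summing all hits — not one best hit per
ORF — is the default because multiple independent homologies to one taxon
are accumulating evidence; a `best_hit_only` flag (single best HSP per
ORF×taxid) is available for sensitivity analysis.  Multiple HSPs of one
ORF–subject pair are summed as given, with no deduplication.  Ties are
broken deterministically toward the smallest taxid and flagged, so reruns
are bit-identical and tied calls are auditable.  A contig is *viral* when
the winning taxid's parent chain reaches a designated viral root in the
supplied offline nodes table (taxid, parent, rank, name, viral-root flag);
no live taxonomy service is consulted, which keeps runs reproducible.
Assigned fractions are reported both by contig count and by abundance
mass, since the two framings answer different questions.

ORF subsystems use the same maximum-sum rule over subsystem labels, with
lexicographic tie-breaks.  "Functions associated with viral hits" is
enforced in **strict** mode by default: per ORF, sums are recomputed over
viral-subject hits only, so a cellular homolog can never carry a
subsystem to the top.  A **lenient** mode instead keeps the original
winner whenever at least one viral hit contributed to it.  A per-contig
mode (keep ORFs on virally assigned contigs) would be a third reading; it
is not implemented because it couples the functional profile to the
taxonomy call.  Rollups sum normalized abundance per top-level category
from a two-column subsystem→category table and conserve the assigned
abundance mass exactly (checked to 1e-9 relative).

## Pol I residue-762 lifestyle classification

Candidates need one hit to the Pol I reference set at E ≤ 1e-5 and a
peptide length ≥ 100 aa (both cutoffs inclusive).  Each candidate is
aligned to a single reference Pol I by deterministic pairwise
**semi-global** alignment: the peptide is aligned end-to-end, reference
overhang is free, substitution matrix BLOSUM62, affine gaps with the
BLAST 11/1 convention (a gap of length k costs 11 + k).  Pairwise
alignment replaces a joint MSA here because only reference-coordinate
mapping is needed for the residue call, and a pairwise alignment is
deterministic and unit-testable; the ROI-restricted alignment (one row
per spanning peptide, in reference coordinates, insertions relative to
the reference dropped) is still exported as FASTA for external tree
building.  Among co-optimal tracebacks the aligner's canonical first one
is used, which is deterministic for a fixed library version; near-indel
edge cases could in principle differ from an MSA column reading, and the
test suite cross-checks alignment scores against an independent
quadratic-DP implementation.

A peptide **spans the region of interest** when it has non-gap residues
aligned at both ROI endpoints (reference positions 547 and 923).
Endpoint coverage is the implemented definition of "spanning"; interior
gaps do not disqualify a peptide, but a gap over position 762 yields an
unclassified call.  The lifestyle rule is: F or Y at 762 ⇒ virulent,
L ⇒ temperate, any other residue or a gap ⇒ unclassified; lifestyle is
undefined (None) for non-spanning peptides, and the three classes
partition the spanning set by construction.  The reference's three
anchor residues (I547, F762, N923) are validated when a `RoiSpec` is
built, so a mis-indexed reference fails fast; classifying the reference
itself must return spans=true, residue F, virulent.  The online
conserved-domain confirmation step of a production run is represented by
an optional user-supplied keep-list of confirmed ids.

## OTU operations

Shannon diversity is reported in **bits** (log base 2), matching the
convention of the QIIME-lineage tooling this mirrors; base-e is a common
alternative, so the unit is stated everywhere it appears.  Rarefaction
draws a multivariate hypergeometric sample (subsampling without
replacement) per sample; samples below the requested depth are dropped
and reported, and retained totals equal the depth exactly.  The >1 %
display filter keeps taxa whose maximum relative abundance is *strictly*
greater than the threshold.  Taxonomy collapse joins the first *r*
lineage fields and groups OTUs unclassified at rank *r* under their
deepest named ancestor; counts are conserved.  Core membership uses
presence (count > 0) on raw counts, not normalized values — normalization
cannot create or destroy presence — and the shared/unique core algebra is
plain set intersection/difference over per-group 100 %-prevalence cores.
Bray–Curtis uses the standard sum-of-absolute-differences form and
refuses a pair of all-zero samples rather than defining 0/0.  CSS or
other externally normalized tables pass through untouched; relative
abundance is the only in-package normalization.  Downstream inferential
statistics (ordination, ANOSIM, Tukey HSD, correlations) are deliberately
left to external statistics environments; this module emits the tidy
tables they consume.

## Synthetic data: what it emulates, and what it does not

`generate_community` plants a Caudovirales-dominated virome:
per-taxon contig sets with uniform planted coverage, perfect-match
fixed-length reads (150 bp) placed uniformly, one planted hit per ORF
(correct taxid, subsystem and viral flag) plus decoy hits at a fixed
bit-score fraction < 1, with decoy taxids and decoy subsystems distinct
per ORF so the planted label's summed bit score strictly wins at both the
contig and the ORF level.  Uniform read placement is the default because
depth-recovery tests need genuine sampling noise; a tiled mode gives
exact integer depth for exactness tests.  With n = round(c·L/150) reads
the realized mean depth equals the planted coverage up to rounding, well
inside 5 % for contigs ≥ 5 kb.  The default community mirrors the study
system's family mixture (Siphoviridae > Myoviridae > Podoviridae plus a
minor bacterial component).

`generate_pola_set` defaults to the study's class structure — 17 Phe, 27
Tyr, 184 Leu spanning peptides — with 5 % substitutions at non-anchor
sites and no truncation; substitutions only (no indels), so planted
residues are exactly recoverable.  The surrogate reference is a fixed
seeded random peptide of length 1,000 carrying the I547/F762/N923 anchor
contract, so no real sequence ships with the package.

`generate_otu_table` defaults to the study scale: 7,489 OTUs across two
filter fractions (1 µm, 0.2 µm) × three months × four replicates at
60,000 reads per sample, with 277 shared-core, 152 and 147
fraction-unique core OTUs whose phylum breakdowns follow the emulated
pond community, a log-normal abundance profile, multinomial sampling, a
guaranteed count ≥ 1 for core OTUs in their defining group, forced
absences that keep unique-core and sporadic OTUs out of the other cores,
and a default negative temporal trend on Cyanobacteria (a late-season
decline).  Because core membership is guaranteed by construction, core
recovery is exact, not statistical.

None of the generators model sequencing error, quality scores, chimeras,
uneven read lengths, paired-end structure, or homology noise beyond the
decoy scheme.  Passing recovery tests therefore demonstrates that the
*computations* are correct on data matching their assumptions — not that
the upstream assembly, mapping or clustering of real pond water would be
this clean.

## Numerical and scale choices

All on-disk coordinates are 1-based inclusive (SAM, samtools depth,
MetaGene convention); any half-open arithmetic is internal.  Depth files
may omit zero-depth positions; the reader zero-fills to full contig
length.  Readers are strict (duplicate ids, malformed numbers, wrong
column counts and out-of-range positions raise with line numbers) and
deterministic.  All generator randomness flows through one seeded numpy
Generator per call — no global state — and identical spec + seed gives
byte-identical files.  Test and acceptance problem sizes (20 contigs of
5–20 kb, 228 Pol I peptides, a 24 × 7,489 OTU table, 10³ random oracle
instances) were chosen to exercise every code path at the study's shape
while keeping a full run in the order of seconds.

## Known limitations

Multi-mapped reads are counted once via their primary alignment; whether
a production recruitment should count every alignment is a judgment call
the primary-only default makes explicit.  Whether the Gbp denominator
should count aligned bases or full read lengths is similarly exposed as a
flag (default: aligned).  BAM input is out of scope (SAM text only), as
are OTU clustering, chimera checking, UniFrac/phylogenetic diversity,
ordination and tree inference — the package exports the tables and
alignments those tools consume.
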