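# Methods

This note records the conventions, parameter choices, and limitations behind
`conseq`'s annotation model, in the package's own terms.

## Coordinates and variant representation

Internal coordinates are 1-based and fully closed.  VCF anchor bases around
unbalanced substitutions are stripped at parse time, so a deletion `TA>T` at
POS 100 is held as `start=101, end=101, ref=A, alt=-` and an insertion
`T>TG` as `start=101, end=100, ref=-, alt=G`; insertions always satisfy
`start = end + 1` and overlap only features that contain the insertion
point (both flanking bases).  Indels are deliberately **not** left-aligned:
preserving the input coordinates keeps output traceable to input and avoids
clashing with HGVS, which right-normalises relative to the transcript.
Left-alignment, when wanted, belongs in a pre-processing step with a
dedicated normaliser (e.g. `bcftools norm`).  An optional `--minimise` mode
strips shared 5′ bases (advancing the start), then shared 3′ bases, to the
minimal representation; it is off by default because it changes input
positions.

Variants whose affected span or insertion length exceeds 50 bp, or that
declare `SVTYPE`/`END` or symbolic alleles, are handled as structural
variants.

Quality control checks coordinate sanity, allele characters, allele-length
vs span consistency, and the reference allele against the genome; a failing
variant is skipped and logged to the warnings file (tab-delimited: input
line, code, message) rather than aborting the run — the ambiguity of
partially annotating failing variants is resolved by full exclusion.

## Annotation store

The cache bins features into fixed 1 Mb regions; a feature spanning a bin
boundary is written to every bin it overlaps and deduplicated by id at
query time.  Bin files are JSON lines under `<chrom>/<bin>.jsonl` — a
portable, inspectable, schema-versioned format rather than any
language-specific object serialisation.  Bins are loaded lazily and
memoized for the life of a run, so consecutive input buffers over the same
region never reread disk; memoization is behaviourally invisible (asserted
by test).  Chromosome names are matched with a `chr`-prefix-insensitive
rule to tolerate mixed GFF/VCF dialects.

Transcript models come from GFF3 or GTF via `gffutils`; biotype, canonical
tag (attribute name configurable, default `tag`), CCDS/TSL/APPRIS flags and
versions are read from attributes, with version 1 assigned when absent.
CDS phases, when declared, are validated against the cumulative coding
length, and exons are validated against chromosome bounds; violations abort
the build naming the record.  Spliced cDNA, CDS, and protein sequences are
computed once per transcript per run and cached.

Mitochondrial chromosomes (configurable name set `{MT, chrM, M}`) translate
with the vertebrate mitochondrial code (NCBI table 2, via Biopython) — so
TGA is tryptophan and AGA/AGG are stops.  Selenocysteine positions arrive
in a sidecar TSV (`transcript_id TAB protein_position`), since GTF dialects
have no standard Sec annotation; an annotated TGA renders as `U`.  A
trailing incomplete codon is dropped from translation and drives
`incomplete_terminal_codon_variant`.

## Consequence assignment

One predicate exists per assignable term (22 transcript predicates).  Each
predicate has a *gate*: a cheap location check that is provably implied by
the predicate itself, so disabling gates changes only the number of
predicate evaluations, never the outcome — the test suite asserts exact
result equality with gates on and off, plus a strict reduction in
evaluations.  Costly intermediates (the coding-change analysis) are
computed once per (allele, transcript) pair and shared by all predicates.

Window conventions: splice donor/acceptor are the first/last 2 intronic
bases; splice region is exonic bases 1–3 adjacent to a junction or intronic
bases 3–8; `intron_variant` requires an intronic base outside the
donor/acceptor dinucleotides (so a donor+2 SNV is `splice_donor_variant`
alone, and an intron-3 SNV is `splice_region_variant` + `intron_variant`).
An insertion whose flanking bases straddle an exon/intron junction is
classified as splice-relevant (`splice_region_variant`), not coding — a
deterministic tie-break for an inherently ambiguous placement.

Coding SNV/MNV classification rebuilds the affected codons and compares
translations: initiator-codon changes are `start_lost`; a changed terminal
stop is `stop_retained_variant` (still a stop) or `stop_lost`; a new stop
is `stop_gained`; otherwise `missense_variant` or `synonymous_variant`.
Codon display upper-cases the changed bases inside lower-case context
(`gCc/gTc`).  Coding indels classify by length change modulo 3
(`frameshift_variant` vs `inframe_insertion`/`inframe_deletion`), with
`start_lost`/`stop_lost` co-assigned when the deletion covers those codons;
changes that cannot be precisely typed (N-containing alleles, spans
crossing a CDS edge) fall back to `coding_sequence_variant`.  In-frame
insertions that happen to introduce a stop codon are reported as
`inframe_insertion` (not additionally `stop_gained`); the protein-level
HGVS still shows the premature `Ter`.  Complex length-preserving MNVs
classify by their translation like SNVs; length-changing complex
substitutions classify by their net indel direction.

`mature_miRNA_variant` applies when a miRNA-biotype transcript carries an
annotated mature region (GFF attribute `mature=start-end`) overlapped by
the variant; other exonic non-coding overlap is
`non_coding_transcript_exon_variant`, intronic non-coding overlap
`intron_variant` + `non_coding_transcript_variant`.

Up/downstream status is measured to the **transcript** boundary (not the
gene), within a configurable flank, default 5000 bp inclusive (a variant at
exactly 5000 bp is assigned; 5001 is not).

Structural variants: a deletion containing a whole feature ablates it
(`transcript_ablation`, `TFBS_ablation`, `regulatory_region_ablation`); a
partial deletion is `feature_truncation` (plus `coding_sequence_variant`
when the CDS is hit); duplications and copy-number gains amplify contained
features and elongate partially covered ones; structural insertions inside
a feature elongate it.  CNV records are treated as copy-number gains for
term purposes.

The registry pins 33 classes with unique severity ranks (1 = most severe)
and impact classes: HIGH for ablations, amplifications, frameshift,
stop gained/lost, start lost, and splice donor/acceptor; MODERATE for
missense and in-frame indels; LOW for synonymous, splice region, stop
retained, and incomplete terminal codon; MODIFIER otherwise.  Complex
in-frame protein changes are expressed through the in-frame indel classes
rather than a separate catch-all class, keeping the registry at its
documented size.  Parent links preserve enough of the SO tree for the
most-specific-term rule and ontology-style filtering.

## HGVS

c./n. positions use the standard forms: negative for 5′UTR, `*` for 3′UTR,
`+`/`−` offsets from the nearest exon edge for introns (a dead-centre
intronic base formats from the donor side).  Indels are shifted maximally
3′ in the *described* sequence: the spliced cDNA for exonic indels (within
the containing intron, in transcript orientation, for intronic ones), and
the forward genomic strand for g. — genomic descriptions are 3′-shifted by
the same rule for consistency, a deliberate choice where conventions
diverge.  `del`/`dup` omit the deleted/duplicated bases (position-only
form), which is stable under genome edits.  Accessions are always
versioned.  Protein descriptions come from re-translating the mutant CDS
extended into the 3′UTR, so `fsTer`/`extTer` distances are observed, not
inferred; an initiator-codon change is `p.Met1?`.  Protein-level HGVS uses
the transcript accession as reference.  Structural variants and r.-level
descriptions are out of scope.

Parsing supports g./c./n. substitutions, deletions, duplications, and
insertions, projecting UTR and intronic offsets through the exon structure
(with strand-aware allele complementation); a version mismatch warns and
resolves on the accession; p. input is rejected as unsupported.

## Motifs and regulatory features

Motif effect is a relative min–max normalised log-probability score:
`score = (Σ log p − Σ log p_min) / (Σ log p_max − Σ log p_min)` over PWM
columns pseudocounted at 1e-2, so the consensus scores 1 and the
anti-consensus 0.  The formula is this package's design: it is bounded,
comparable across motifs, and monotone per column (asserted by test).  A
position is "informative" when its column's information content is at
least 1 bit of the 2-bit maximum — a simple, testable proxy for
consensus-critical positions.  Ref/alt motif sequences are built in motif
strand orientation; indels overlapping a motif report the term without a
score, since the alignment of mutant to matrix is undefined.  Regulatory
features may be restricted to user-specified cell types.

## Pipeline

Input streams in contiguous buffers (default 5000 variants).  A buffer may
be partitioned into up to `--workers` contiguous chunks; chunks are
processed independently and rejoined in input order before writing, making
the primary output byte-identical for any worker count.  The partitioning
is executed in-process: the contract the design serves is deterministic
order, and the chunk boundary is where process-level parallelism would
attach if a deployment needs it.  Identifier input resolves against the
known-variant track; HGVS input resolves through the parser; failures of
either are warnings, not errors.  Plugins run after consequence
calculation, per result, receiving the result, store, and configuration,
and merge returned key→value pairs into `extras` (shipped demo: an
up/downstream distance re-threshold).  Runtime filters apply in the order:
intergenic removal, common-variant removal (strict `>` on the co-located
global minor allele frequency, default 0.01), per-gene/pick prioritisation,
then the optional filter expression.

Prioritisation order: canonical flag, protein-coding biotype, most severe
term rank, longest CDS, lexicographically smallest feature id.  The filter
grammar is `FIELD OP [VALUE]` with AND binding tighter than OR and no
parentheses; `in` reads a file (one value per line) or a comma list;
`matches` is case-insensitive substring; numeric comparators evaluate
false on non-numeric fields; unknown fields evaluate false with a warning.

Co-location requires identical chrom/start/end; allele compatibility means
a shared reference allele and at least one shared alternative after
minimisation, with position-only matches flagged as mismatches.

## Synthetic data and what the tests show

The fixture generator writes a deterministic genome (seeded filler with
hand-designed sequence stamped in) carrying transcripts that reach every
registry class by construction: engineered codons for each protein-level
outcome, homopolymer tracts in genomic and cDNA space (both strands) for
HGVS shifting, a miRNA with a mature region, an incomplete terminal codon,
a selenocysteine codon, a mitochondrial transcript whose TGA/AGA codons
distinguish the codon tables, an isolated overlapping-isoform pair for
prioritisation and cardinality checks, and flank-boundary probes at
4999/5000/5001 bp.  A truth table lists expected terms per (variant,
allele, feature).

The independent oracle (`naive_annotate`) recomputes consequences from
first principles — positional window sets, full mutant-chromosome
re-splicing, whole-protein comparison — sharing no classification code,
gating, or caches with the engine; engine-vs-oracle agreement is asserted
exhaustively for every SNV at every position of two ~1 kb transcripts
(one forward, one minus-strand; ~6,100 cases).

These fixtures optimise class coverage and determinism, not realism: they
lack sequencing artefacts, dense overlapping annotation, alternative
haplotypes, and realistic allele-frequency spectra, so passing tests
demonstrate correctness of the annotation logic, not robustness to
malformed real-world annotation sets.  Problem sizes (40 kb genome, ~1 kb
sweep transcripts, 12,000-variant buffering/worker runs) were chosen as the
smallest sets that exercise every code path including multi-buffer
streaming.

## Known limitations

- Compound effects across phased variants are not considered; each variant
  annotates independently.
- bigWig custom tracks and GVF output are not implemented (documented
  extension points); pileup input and protein-level HGVS input are out of
  scope.
- Left-alignment of indels is intentionally not performed (see above).
- `stop_gained` is not co-assigned to in-frame insertions that introduce a
  stop (the HGVS p. description carries the information).
- Nonsense-mediated-decay assessment is not performed.
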