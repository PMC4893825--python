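# conseq

Offline variant consequence annotation: given variants (VCF, identifiers, or
HGVS notations), a transcript annotation set (GFF3/GTF + FASTA), and optional
regulatory, motif, and known-variant tracks, `conseq` reports one unit of
annotation **per alternative allele per overlapped genomic feature** —
Sequence Ontology (SO) consequence terms, transcript/CDS/protein coordinates,
codon and amino-acid changes, HGVS g./c./p. descriptions, transcription-factor
motif score changes, co-located variant frequencies and clinical attributes,
and tools to prioritise and filter the resulting annotation.

It is built for people who need variant interpretation pipelines that run
entirely offline against a versioned local annotation cache: clinical and
research groups annotating resequencing or exome call sets, and tool authors
who need a programmable annotation library rather than a web service.

## The model

For each input variant allele *a* and each genomic feature *f* it overlaps
(transcripts are searched with a configurable flank, default 5 kb), the
engine evaluates a suite of predicate functions, one per assignable SO class:
splice donor/acceptor (first/last 2 intronic bases), splice region (exonic
1–3 bp or intronic 3–8 bp from a junction), UTR, intron, and the protein-level
predicates, which rebuild the affected codons from the spliced CDS and
re-translate them (standard code; vertebrate mitochondrial code on
mitochondrial chromosomes; annotated selenocysteine TGA → U).  Cheap
*pre-predicate gates* skip predicates that cannot apply — a wholly intronic
allele never triggers a translation — so the naive `n·f·p` predicate cost
(n alleles, f features, p predicates) is reduced without changing any result;
both counts are tracked in the run statistics.  Assigned terms are reduced by
the SO tree so only the most specific term under any parent survives, while
terms on distinct branches (say `splice_region_variant` and
`missense_variant`) co-exist.  Structural variants (> 50 bp, or declared via
`SVTYPE`/`END` or symbolic alleles) get the ablation / amplification /
truncation / elongation terms instead.

The 33-class consequence registry (name, SO accession, parent links, severity
rank, impact class) ships as a data file and can be overridden by the user.

HGVS descriptions are normalised to the most 3′ position in repetitive
sequence *relative to the described sequence* — transcript orientation for
c./n. (on a minus-strand transcript that is the lowest genomic coordinate),
forward genomic strand for g. — and insertions that duplicate the adjacent
sequence are written as `dup`.  Protein descriptions re-translate the mutant
CDS, so frameshifts report the observed new stop (`p.Ala2ValfsTer13`) and
stop losses the observed extension (`p.Ter20CysextTer2`).

## Worked example

Everything below runs against the bundled synthetic fixture generator — no
downloads required:

```bash
conseq make-fixture --out fix --seed 5
conseq build-cache --gff fix/transcripts.gff3 --fasta fix/genome.fa \
    --out cache --regulatory fix/regulatory.gff3 --motifs fix/motifs.jaspar \
    --known fix/known.vcf --selenocysteine fix/selenocysteine.tsv
conseq annotate -i fix/variants.vcf -c cache -o out.tab
```

Selected columns of `out.tab` (the fixture's `v_mis` is a C>T SNV at
chrT:25 inside transcript TX1):

```
#Uploaded_variation  Location    Allele  Consequence            Feature  HGVSc          HGVSp                     cDNA  CDS  Protein  Amino_acids  Codons
v_mis                chrT:25     T       missense_variant       TX1.1    TX1.1:c.5C>T   TX1.1:p.Ala2Val           15    5    2        A/V          gCc/gTc
v_stopl              chrT:90     C       stop_lost              TX1.1    TX1.1:c.60A>C  TX1.1:p.Ter20CysextTer2   70    60   20       */C          tgA/tgC
vmot                 chrT:18103  T       TF_binding_site_variant MOT1    -              -                         -     -    -        -            -
```

Reading the first row: the alternative allele T converts the fifth coding
base of TX1 (cDNA position 15, protein residue 2), changing codon `gCc` to
`gTc` and alanine to valine — a `missense_variant` of MODERATE impact, with
matching HGVS descriptions at all three levels.  The `vmot` row reports a
motif hit: the engine scored the reference and mutant 8-mer against the
motif's position weight matrix (`MOTIF_SCORE_CHANGE` −0.14, at an
information-rich column, so `HIGH_INF_POS` is `Y`).

Useful flags: `--pick` (one result per variant, canonical transcript first,
then protein-coding biotype, then severity), `--per-gene`,
`--no-intergenic`, `--filter-common[=freq]` (drop variants co-located with a
known variant above 1 % minor allele frequency), `--custom
name=path=format[,exact]` (BED/GFF/VCF tracks), `--plugin name[:arg]`,
`--format vcf|json` (VCF output echoes the input records with a
header-declared `CSQ` INFO field), and `--workers N` (output is
byte-identical for any worker count).  Post-run filtering uses a simple
field-operator-value language:

```bash
conseq filter -i out.tab --expr "SIFT is deleterious OR PolyPhen is probably_damaging"
conseq filter -i out.tab --expr "AFR >0.1 AND EUR <0.05"
```

## Annotation cache

`build-cache` compiles the annotation into megabase-binned JSON-lines files
plus a faidx-indexed copy of the genome, under a versioned
`manifest.json` with source checksums:

```
cache/manifest.json      # schema version, bin size, checksums, per-chrom bins
cache/genome.fa[.fai]
cache/<chrom>/<bin>.jsonl  # transcripts, regulatory, motifs, known variants
```

Known variants are supplied as VCF with reserved INFO keys: `GMAF=T:0.02`
(global minor allele and frequency), `AF_<POP>=0.2` (per-population
frequencies), `CLNSIG=...`, `SOMATIC`, `PMID=...`.  Bins are loaded lazily
and memoized across input buffers.

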