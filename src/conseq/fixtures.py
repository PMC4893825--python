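"""Synthetic genomes, annotation, and variants with known ground truth.

``make_fixture`` writes a deterministic file set (FASTA, GFF3, VCF,
known-variant VCF, regulatory GFF, JASPAR PWM file, selenocysteine sidecar,
BED custom track, truth table) built around hand-designed transcripts whose
codon layout makes every consequence class reachable by construction:

* TX1   forward two-exon coding transcript with engineered codons
         (missense/synonymous/stop/start/splice/UTR/indel probes)
* TX2   minus-strand two-exon coding transcript with an A-run in cDNA space
         for transcript-orientation HGVS shifting
* TXO1/TXO2  ~1 kb coding transcripts (forward and minus) used for
         exhaustive engine-vs-oracle sweeps
* TX3   non-coding two-exon transcript; TX4 miRNA with a mature region
* TX5   coding transcript with an incomplete terminal codon
* TXSEC coding transcript with an annotated selenocysteine codon
* MTX1  mitochondrial transcript (vertebrate mito codon table)
* TXA/TXB  overlapping isoform pair (canonical vs not) on an isolated locus
         used for prioritisation and row-cardinality checks

Identical seeds give byte-identical files.  The fixtures optimise class
coverage, not population-genetic realism.

``naive_annotate`` is a deliberately slow first-principles annotator used
as an independent oracle: it recomputes consequences by splicing the full
mutant chromosome, re-translating, and comparing proteins positionally —
no pre-predicate gates, no sequence caches, no shared code with the
engine's classification paths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

from .models import Interval, Transcript

__all__ = ["FixtureSpec", "make_fixture", "make_random_vcf", "naive_annotate",
           "FLANK_TARGET", "FLANK_PROBE_POSITIONS"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# codons that are not stops in either the standard or vertebrate mito tables
SAFE_CODONS = ["GCT", "GCC", "GCA", "TGC", "GAT", "GAA", "GGT", "CAT", "ATC",
               "AAA", "CTG", "CTT", "CCC", "CGT", "TCC", "GTG", "TAC", "TTC"]

FLANK_TARGET = 5000
#: downstream flank boundary probes relative to the TXA/TXB locus end (30200)
FLANK_PROBE_POSITIONS = {4999: 35199, 5000: 35200, 5001: 35201}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data set (defaults are the study set)."""

    seed: int = 1
    chrom_lengths: dict = field(default_factory=lambda: {
        "chrT": 40000, "chrM": 600, "chrU": 2000})
    n_transcripts: int = 12
    include_regulatory: bool = True
    include_motifs: bool = True
    include_known_variants: bool = True
    n_random_variants: int = 0


class _GenomeBuilder:
    def __init__(self, length: int, rng: random.Random):
        self.seq = [rng.choice("ACGT") for _ in range(length)]
        self._stamped: list[tuple[int, int]] = []

    def stamp(self, start: int, seq: str) -> None:
        """Write ``seq`` at 1-based ``start``; overlapping stamps are a bug."""
        end = start + len(seq) - 1
        for s, e in self._stamped:
            if start <= e and end >= s:
                raise AssertionError(
                    f"fixture design error: stamp {start}-{end} overlaps {s}-{e}")
        self._stamped.append((start, end))
        self.seq[start - 1:end] = list(seq)

    def get(self, start: int, end: int) -> str:
        return "".join(self.seq[start - 1:end])

    def __str__(self) -> str:
        return "".join(self.seq)


def _codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(SAFE_CODONS) for _ in range(n))


# ---------------------------------------------------------------------------
# Variant bookkeeping


@dataclass
class _Var:
    """One curated variant in internal coordinates plus its truth rows."""

    vid: str
    chrom: str
    start: int
    end: int
    ref: str             # internal representation ("-" for insertions)
    alts: list[str]
    truth: list[tuple[str, str, str]]  # (allele, feature_id, "term,term")
    sv: bool = False
    sv_type: str | None = None

    def vcf_fields(self, genomes: dict[str, _GenomeBuilder]) -> list[str]:
        g = genomes[self.chrom]
        if self.sv:
            ref = g.get(self.start, self.start)
            return [self.chrom, str(self.start), self.vid, ref,
                    f"<{self.sv_type}>", ".", ".",
                    f"SVTYPE={self.sv_type};END={self.end}"]
        if self.ref != "-" and all(a != "-" for a in self.alts):
            return [self.chrom, str(self.start), self.vid, self.ref,
                    ",".join(self.alts), ".", ".", "."]
        # indel: re-anchor on the preceding base
        anchor_pos = self.start - 1 if self.ref != "-" else self.end
        anchor = g.get(anchor_pos, anchor_pos)
        ref = anchor + ("" if self.ref == "-" else self.ref)
        alts = [anchor + ("" if a == "-" else a) for a in self.alts]
        return [self.chrom, str(anchor_pos), self.vid, ref,
                ",".join(alts), ".", ".", "."]


def _snv(vid, chrom, pos, alt, truth, genomes, ref=None):
    g = genomes[chrom]
    ref = ref or g.get(pos, pos)
    if ref == alt:
        raise AssertionError(f"{vid}: alt equals reference {ref}")
    return _Var(vid, chrom, pos, pos, ref, [alt], truth)


# ---------------------------------------------------------------------------
# Fixture construction


def make_fixture(spec: FixtureSpec, out) -> dict[str, Path]:
    """Generate the fixture file set under ``out``; returns name -> path."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    genomes = {name: _GenomeBuilder(length, rng)
               for name, length in spec.chrom_lengths.items()}
    gT = genomes.get("chrT")
    gM = genomes.get("chrM")

    gff_lines = ["##gff-version 3"]
    transcripts_present = spec.n_transcripts > 0

    if transcripts_present:
        _design_transcripts(gT, gM, rng, gff_lines)

    variants: list[_Var] = []
    if transcripts_present:
        variants = _curated_variants(genomes, spec)
    else:
        for i in range(10):
            pos = 100 + i * 137
            ref = gT.get(pos, pos) if gT else genomes[next(iter(genomes))].get(pos, pos)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            chrom = "chrT" if gT else next(iter(genomes))
            variants.append(_snv(f"iv{i}", chrom, pos, alt,
                                 [(alt, "-", "intergenic_variant")], genomes))

    if spec.n_random_variants:
        variants += _random_snvs(genomes, rng, spec.n_random_variants)

    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for name in spec.chrom_lengths:
            seq = str(genomes[name])
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    paths["fasta"] = fasta

    gff = out / "transcripts.gff3"
    gff.write_text("\n".join(gff_lines) + "\n")
    paths["gff"] = gff

    vcf = out / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write("\t".join(v.vcf_fields(genomes)) + "\n")
    paths["vcf"] = vcf

    truth = out / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("#variant_id\tchrom\tstart\tend\tref\talt\tfeature\tterms\n")
        for v in variants:
            for allele, feature, terms in v.truth:
                fh.write(f"{v.vid}\t{v.chrom}\t{v.start}\t{v.end}\t{v.ref}\t"
                         f"{allele}\t{feature}\t{terms}\n")
    paths["truth"] = truth

    if transcripts_present and spec.include_regulatory:
        reg = out / "regulatory.gff3"
        reg_lines = ["##gff-version 3"]
        reg_lines.append(
            "chrT\tfixture\tpromoter\t18001\t18400\t.\t.\t.\t"
            "ID=REG1;cell_types=HeLa,K562")
        reg_lines.append(
            "chrT\tfixture\tenhancer\t20001\t20200\t.\t.\t.\t"
            "ID=REG2;cell_types=GM12878")
        if spec.include_motifs:
            reg_lines.append(
                "chrT\tfixture\tTF_binding_site\t18101\t18108\t.\t+\t.\t"
                "ID=MOT1;motif_name=MA9001.1")
            reg_lines.append(
                "chrT\tfixture\tTF_binding_site\t18201\t18208\t.\t-\t.\t"
                "ID=MOT2;motif_name=MA9001.1")
        reg.write_text("\n".join(reg_lines) + "\n")
        paths["regulatory"] = reg

    if transcripts_present and spec.include_motifs:
        pwm = out / "motifs.jaspar"
        pwm.write_text(
            ">MA9001.1 FIXTF\n"
            "A [ 94  2  2  2 30  2  2  2 ]\n"
            "C [  2 94  2  2 28 94  2  2 ]\n"
            "G [  2  2 94  2 22  2 94  2 ]\n"
            "T [  2  2  2 94 20  2  2 94 ]\n")
        paths["motifs"] = pwm

    if transcripts_present and spec.include_known_variants:
        known = out / "known.vcf"
        reg_ref = gT.get(18050, 18050)
        reg_alt = "ACGT"[("ACGT".index(reg_ref) + 1) % 4]
        with open(known, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chrT\t25\trsK1\tC\tT\t.\t.\tGMAF=T:0.02\n")
            fh.write("chrT\t29\trsK2\tA\tG\t.\t.\tGMAF=G:0.005\n")
            fh.write("chrT\t45\trsK3\tC\tT\t.\t.\tGMAF=T:0.004\n")
            fh.write(f"chrT\t18050\trsK4\t{reg_ref}\t{reg_alt}\t.\t.\t"
                     "AF_AFR=0.2;AF_EUR=0.01;CLNSIG=pathogenic;SOMATIC;"
                     "PMID=123,456\n")
        paths["known"] = known

    if transcripts_present:
        sec = out / "selenocysteine.tsv"
        sec.write_text("TXSEC\t15\n")
        paths["selenocysteine"] = sec

        bed = out / "custom.bed"
        bed.write_text("chrT\t18000\t18400\tpromoter_7\n")
        paths["custom_bed"] = bed

    return paths


def _design_transcripts(gT: _GenomeBuilder, gM, rng: random.Random,
                        gff: list[str]) -> None:
    """Stamp designed sequence into the genome and emit GFF records."""

    def gene(gid, chrom, start, end, strand):
        gff.append(f"{chrom}\tfixture\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                   f"ID={gid};Name={gid}_SYM")

    def transcript(tid, gid, chrom, start, end, strand, ftype="mRNA",
                   biotype="protein_coding", extra=""):
        attrs = f"ID={tid};Parent={gid};biotype={biotype};version=1"
        if extra:
            attrs += ";" + extra
        gff.append(f"{chrom}\tfixture\t{ftype}\t{start}\t{end}\t.\t{strand}"
                   f"\t.\t{attrs}")

    def exon(tid, chrom, start, end, strand, n):
        gff.append(f"{chrom}\tfixture\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                   f"ID={tid}.e{n};Parent={tid}")

    def cds(tid, chrom, pieces, strand):
        # pieces in transcript order; phase from cumulative coding length
        done = 0
        for n, (s, e) in enumerate(pieces, 1):
            phase = (3 - done % 3) % 3
            gff.append(f"{chrom}\tfixture\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}"
                       f"\tID={tid}.c{n};Parent={tid}")
            done += e - s + 1

    # ----- TX1: forward 2-exon coding, engineered codons ------------------
    tx1_cds1 = ("ATG" "GCC" "AAA" "ACG" "GAT" "TGC" "CTG" "GAA" "CAT" "CTT")
    tx1_cds2 = ("TGG" "CGT" "AGC" "GTA" "CCC" "TTA" "GGC" "ATC" "AAG" "TGA")
    gT.stamp(11, "GATTCGCAAC" + tx1_cds1 + "GTACTCTTAG" + tx1_cds2
             + "CATTAACGTT" + "AAACG")
    gene("G1", "chrT", 11, 100, "+")
    transcript("TX1", "G1", "chrT", 11, 100, "+")
    exon("TX1", "chrT", 11, 50, "+", 1)
    exon("TX1", "chrT", 61, 100, "+", 2)
    cds("TX1", "chrT", [(21, 50), (61, 90)], "+")

    # ----- TXO1: forward ~1 kb 2-exon coding (oracle sweep) ----------------
    o1_cds = "ATG" + _codons(rng, 231) + "TAA"  # 699 nt
    gT.stamp(3051, o1_cds[:350])
    gT.stamp(3401, "GT")
    gT.stamp(3599, "AG")
    gT.stamp(3601, o1_cds[350:])
    gene("GO1", "chrT", 3001, 4000, "+")
    transcript("TXO1", "GO1", "chrT", 3001, 4000, "+")
    exon("TXO1", "chrT", 3001, 3400, "+", 1)
    exon("TXO1", "chrT", 3601, 4000, "+", 2)
    cds("TXO1", "chrT", [(3051, 3400), (3601, 3949)], "+")

    # ----- TXO2: minus-strand ~1 kb 2-exon coding --------------------------
    o2_cds = "ATG" + _codons(rng, 231) + "TAA"
    o2_utr5 = "".join(rng.choice("ACGT") for _ in range(50))
    o2_utr3 = "".join(rng.choice("ACGT") for _ in range(51))
    o2_cdna = o2_utr5 + o2_cds + o2_utr3  # 800 nt
    gT.stamp(6601, _rc(o2_cdna[:400]))
    gT.stamp(6001, _rc(o2_cdna[400:]))
    gT.stamp(6599, "AC")  # donor GT on transcript strand
    gT.stamp(6401, "CT")  # acceptor AG on transcript strand
    gene("GO2", "chrT", 6001, 7000, "-")
    transcript("TXO2", "GO2", "chrT", 6001, 7000, "-")
    exon("TXO2", "chrT", 6601, 7000, "-", 1)
    exon("TXO2", "chrT", 6001, 6400, "-", 2)
    cds("TXO2", "chrT", [(6601, 6950), (6052, 6400)], "-")

    # ----- TX2: minus-strand 2-exon coding with cDNA A-run -----------------
    tx2_cds = ("ATG" "GCC" "AAA" "ACG" + _codons(rng, 28) + "TGA")  # 99 nt
    tx2_utr5 = "".join(rng.choice("ACGT") for _ in range(50))
    tx2_utr3 = "".join(rng.choice("ACGT") for _ in range(51))
    tx2_cdna = tx2_utr5 + tx2_cds + tx2_utr3  # 200 nt
    assert tx2_cdna[56:60] == "AAAA" and tx2_cdna[60] != "A"
    gT.stamp(9201, _rc(tx2_cdna[:100]))
    gT.stamp(9001, _rc(tx2_cdna[100:]))
    gT.stamp(9199, "AC")
    gT.stamp(9101, "CT")
    gene("G2", "chrT", 9001, 9300, "-")
    transcript("TX2", "G2", "chrT", 9001, 9300, "-")
    exon("TX2", "chrT", 9201, 9300, "-", 1)
    exon("TX2", "chrT", 9001, 9100, "-", 2)
    cds("TX2", "chrT", [(9201, 9250), (9052, 9100)], "-")

    # ----- TX4: miRNA with mature region -----------------------------------
    gene("G4", "chrT", 12001, 12090, "+")
    transcript("TX4", "G4", "chrT", 12001, 12090, "+", ftype="miRNA",
               biotype="miRNA", extra="mature=12031-12052")
    exon("TX4", "chrT", 12001, 12090, "+", 1)

    # ----- TX3: non-coding 2-exon -------------------------------------------
    gT.stamp(15201, "GT")
    gT.stamp(15299, "AG")
    gene("G3", "chrT", 15001, 15400, "+")
    transcript("TX3", "G3", "chrT", 15001, 15400, "+", ftype="lnc_RNA",
               biotype="lncRNA")
    exon("TX3", "chrT", 15001, 15200, "+", 1)
    exon("TX3", "chrT", 15301, 15400, "+", 2)

    # ----- motif consensus placements --------------------------------------
    gT.stamp(18101, "ACGTACGT")
    gT.stamp(18201, _rc("ACGTACGT"))

    # ----- TX5: incomplete terminal codon -----------------------------------
    gT.stamp(22021, "ATG" + _codons(rng, 25) + "GC")  # 80 nt CDS
    gene("G5", "chrT", 22001, 22100, "+")
    transcript("TX5", "G5", "chrT", 22001, 22100, "+")
    exon("TX5", "chrT", 22001, 22100, "+", 1)
    cds("TX5", "chrT", [(22021, 22100)], "+")

    # ----- TXSEC: selenocysteine at codon 15 --------------------------------
    gT.stamp(24011, "ATG" + _codons(rng, 13) + "TGA" + _codons(rng, 14) + "TAA")
    gene("G6", "chrT", 24001, 24120, "+")
    transcript("TXSEC", "G6", "chrT", 24001, 24120, "+")
    exon("TXSEC", "chrT", 24001, 24120, "+", 1)
    cds("TXSEC", "chrT", [(24011, 24100)], "+")

    # ----- TXA / TXB: overlapping isoforms on an isolated locus -------------
    txb_cds = ("ATG" "GCT" "CAT" "AAG" "TAC" "GAA" "TGC"
               + _codons(rng, 9) + "TAA")  # 51 nt, provides GT at 30041-42
    assert txb_cds[11] == "G" and txb_cds[12] == "T"
    gT.stamp(30030, txb_cds)
    gT.stamp(30099, "AG")
    gT.stamp(30110, "ATG" + _codons(rng, 25) + "TGA")  # TXA CDS, 81 nt
    gene("GA", "chrT", 30001, 30200, "+")
    transcript("TXA", "GA", "chrT", 30001, 30200, "+", extra="tag=canonical")
    exon("TXA", "chrT", 30001, 30040, "+", 1)
    exon("TXA", "chrT", 30101, 30200, "+", 2)
    cds("TXA", "chrT", [(30110, 30190)], "+")
    gene("GB", "chrT", 30001, 30200, "+")
    transcript("TXB", "GB", "chrT", 30001, 30200, "+")
    exon("TXB", "chrT", 30001, 30200, "+", 1)
    cds("TXB", "chrT", [(30030, 30080)], "+")

    # ----- MTX1: mitochondrial ----------------------------------------------
    if gM is not None:
        gM.stamp(111, "ATG" + _codons(rng, 29) + "TGA" + _codons(rng, 45)
                 + "AGA")  # TGA = Trp, AGA = stop under the mito table
        gene("GM", "chrM", 101, 400, "+")
        transcript("MTX1", "GM", "chrM", 101, 400, "+")
        exon("MTX1", "chrM", 101, 400, "+", 1)
        cds("MTX1", "chrM", [(111, 341)], "+")


def _curated_variants(genomes, spec: FixtureSpec) -> list[_Var]:
    gT = genomes["chrT"]
    v: list[_Var] = []

    def snv(vid, pos, alt, feature, terms, chrom="chrT"):
        v.append(_snv(vid, chrom, pos, alt, [(alt, feature, terms)], genomes))

    # TX1 probes
    snv("v_mis", 25, "T", "TX1", "missense_variant")
    snv("v_syn", 29, "G", "TX1", "synonymous_variant")
    snv("v_stopg", 77, "A", "TX1", "stop_gained")
    snv("v_stopl", 90, "C", "TX1", "stop_lost")
    snv("v_stopr", 89, "A", "TX1", "stop_retained_variant")
    snv("v_startl", 22, "C", "TX1", "start_lost")
    snv("v_donor", 52, "C", "TX1", "splice_donor_variant")
    snv("v_acceptor", 59, "G", "TX1", "splice_acceptor_variant")
    snv("v_sr_int", 55, "A", "TX1", "splice_region_variant,intron_variant")
    snv("v_5utr", 15, "T", "TX1", "5_prime_UTR_variant")
    snv("v_3utr", 93, "G", "TX1", "3_prime_UTR_variant")
    snv("v_sr_mis", 49, "C", "TX1", "splice_region_variant,missense_variant")
    snv("v_k3", 45, "G", "TX1", "missense_variant")
    snv("v_up", 5, "ACGT"[("ACGT".index(gT.get(5, 5)) + 1) % 4], "TX1",
        "upstream_gene_variant")
    snv("v_down", 300, "ACGT"[("ACGT".index(gT.get(300, 300)) + 1) % 4], "TX1",
        "downstream_gene_variant")
    v.append(_Var("v_fs", "chrT", 25, 25, "C", ["-"],
                  [("-", "TX1", "frameshift_variant")]))
    v.append(_Var("v_infdel", "chrT", 27, 29, "AAA", ["-"],
                  [("-", "TX1", "inframe_deletion")]))
    v.append(_Var("v_infins", "chrT", 33, 32, "-", ["GCT"],
                  [("GCT", "TX1", "inframe_insertion")]))

    # TX2 (minus strand)
    snv("v2_mis", 9246, "A", "TX2", "missense_variant")
    v.append(_Var("v2_del", "chrT", 9241, 9241, "T", ["-"],
                  [("-", "TX2", "frameshift_variant")]))
    snv("v2_int", 9150, "ACGT"[("ACGT".index(gT.get(9150, 9150)) + 1) % 4],
        "TX2", "intron_variant")

    # non-coding / miRNA / incomplete / Sec / mito
    snv("v3_ex", 15100,
        "ACGT"[("ACGT".index(gT.get(15100, 15100)) + 1) % 4], "TX3",
        "non_coding_transcript_exon_variant")
    snv("v3_int", 15250,
        "ACGT"[("ACGT".index(gT.get(15250, 15250)) + 1) % 4], "TX3",
        "intron_variant,non_coding_transcript_variant")
    snv("v4_mat", 12040,
        "ACGT"[("ACGT".index(gT.get(12040, 12040)) + 1) % 4], "TX4",
        "mature_miRNA_variant")
    snv("v4_nc", 12010,
        "ACGT"[("ACGT".index(gT.get(12010, 12010)) + 1) % 4], "TX4",
        "non_coding_transcript_exon_variant")
    snv("v5_inc", 22099,
        "ACGT"[("ACGT".index(gT.get(22099, 22099)) + 1) % 4], "TX5",
        "incomplete_terminal_codon_variant")
    snv("vsec", 24054, "C", "TXSEC", "missense_variant")
    if "chrM" in genomes:
        snv("vm_stopg", 202, "A", "MTX1", "stop_gained", chrom="chrM")
        snv("vm_stopr", 341, "G", "MTX1", "stop_retained_variant", chrom="chrM")

    # regulatory / motif
    if spec.include_regulatory:
        reg_ref = gT.get(18050, 18050)
        snv("vreg", 18050, "ACGT"[("ACGT".index(reg_ref) + 1) % 4], "REG1",
            "regulatory_region_variant")
        if spec.include_motifs:
            snv("vmot", 18103, "T", "MOT1", "TF_binding_site_variant")
            snv("vmot_weak", 18105, "C", "MOT1", "TF_binding_site_variant")

    # intergenic
    gU = genomes.get("chrU")
    if gU is not None:
        snv("vint", 500, "ACGT"[("ACGT".index(gU.get(500, 500)) + 1) % 4],
            "-", "intergenic_variant", chrom="chrU")

    # cardinality / prioritisation probe: 2 alts x 2 transcripts
    assert gT.get(30050, 30050) == "C"
    v.append(_Var("vcard", "chrT", 30050, 30050, "C", ["G", "T"], [
        ("G", "TXA", "intron_variant"),
        ("T", "TXA", "intron_variant"),
        ("G", "TXB", "missense_variant"),
        ("T", "TXB", "synonymous_variant"),
    ]))

    # flank boundary probes (downstream of the TXA/TXB locus end at 30200)
    for dist, pos in FLANK_PROBE_POSITIONS.items():
        ref = gT.get(pos, pos)
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        truth = ([ (alt, "TXA", "downstream_gene_variant"),
                   (alt, "TXB", "downstream_gene_variant") ]
                 if dist <= FLANK_TARGET else [(alt, "-", "intergenic_variant")])
        v.append(_Var(f"vflank{dist}", "chrT", pos, pos, ref, [alt], truth))

    # structural variants
    v.append(_Var("vsv_del_tx3", "chrT", 14900, 15500, "N", ["<DEL>"],
                  [("<DEL>", "TX3", "transcript_ablation")],
                  sv=True, sv_type="DEL"))
    v.append(_Var("vsv_dup_txo1", "chrT", 3550, 3700, "N", ["<DUP>"],
                  [("<DUP>", "TXO1", "feature_elongation")],
                  sv=True, sv_type="DUP"))
    v.append(_Var("vsv_del_tx1", "chrT", 85, 120, "N", ["<DEL>"],
                  [("<DEL>", "TX1",
                    "feature_truncation,coding_sequence_variant")],
                  sv=True, sv_type="DEL"))
    v.append(_Var("vsv_dup_tx4", "chrT", 11900, 12200, "N", ["<DUP>"],
                  [("<DUP>", "TX4", "transcript_amplification")],
                  sv=True, sv_type="DUP"))
    v.append(_Var("vsv_down", "chrT", 35000, 35100, "N", ["<DEL>"],
                  [("<DEL>", "TXA", "downstream_gene_variant"),
                   ("<DEL>", "TXB", "downstream_gene_variant")],
                  sv=True, sv_type="DEL"))
    if spec.include_regulatory:
        truth = [("<DEL>", "REG1", "regulatory_region_ablation")]
        if spec.include_motifs:
            truth += [("<DEL>", "MOT1", "TFBS_ablation"),
                      ("<DEL>", "MOT2", "TFBS_ablation")]
        v.append(_Var("vsv_del_reg1", "chrT", 17900, 18500, "N", ["<DEL>"],
                      truth, sv=True, sv_type="DEL"))
        v.append(_Var("vsv_dup_reg2", "chrT", 19900, 20300, "N", ["<DUP>"],
                      [("<DUP>", "REG2", "regulatory_region_amplification")],
                      sv=True, sv_type="DUP"))
        if spec.include_motifs:
            v.append(_Var("vsv_dup_mot1", "chrT", 18090, 18110, "N", ["<DUP>"],
                          [("<DUP>", "MOT1", "TFBS_amplification"),
                           ("<DUP>", "REG1", "feature_elongation")],
                          sv=True, sv_type="DUP"))
    return v


def _random_snvs(genomes, rng: random.Random, n: int) -> list[_Var]:
    gT = genomes["chrT"]
    length = len(gT.seq)
    out = []
    for i in range(n):
        pos = rng.randrange(1, length + 1)
        ref = gT.get(pos, pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        out.append(_Var(f"rnd{i}", "chrT", pos, pos, ref, [alt], []))
    return out


def make_random_vcf(fixture_dir, out_path, n: int, seed: int) -> Path:
    """A VCF of ``n`` random chrT SNVs drawn against the fixture genome."""
    import pyfaidx
    fa = pyfaidx.Fasta(str(Path(fixture_dir) / "genome.fa"))
    seq = str(fa["chrT"]).upper()
    rng = random.Random(seed)
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i in range(n):
            pos = rng.randrange(1, len(seq) + 1)
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fh.write(f"chrT\t{pos}\trnd{i}\t{ref}\t{alt}\t.\t.\t.\n")
    return out_path


# ---------------------------------------------------------------------------
# Brute-force oracle


def _oracle_translate(seq: str, table_id: int, sec=()) -> str:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon == "TGA" and (i // 3 + 1) in sec:
            out.append("U")
        elif codon in tbl.stop_codons:
            out.append("*")
        else:
            out.append(tbl.forward_table.get(codon, "X"))
    return "".join(out)


def _oracle_splice(chrom_seq: str, transcript: Transcript) -> str:
    parts = []
    for exon in transcript.exons:
        piece = chrom_seq[exon.start - 1:exon.end]
        parts.append(piece if transcript.strand == 1 else _rc(piece))
    return "".join(parts)


def naive_annotate(variant, transcript: Transcript, chrom_seq: str, *,
                   mito: bool = False, flank: int = 5000) -> set[str]:
    """First-principles consequence terms for one variant on one transcript.

    Rebuilds the full mutant chromosome, re-splices, re-translates, and
    compares whole proteins; junction windows are checked positionally.
    Supports SNVs and simple fully-coding indels.  No gating, no caching.
    """
    t = transcript
    table = 2 if mito else 1
    sec = t.selenocysteine_positions
    is_ins = variant.start == variant.end + 1
    s, e = (variant.end, variant.start) if is_ins else (variant.start, variant.end)

    # outside the transcript body: flank status only
    inside = (t.start <= s and e <= t.end) if is_ins else (
        s <= t.end and e >= t.start)
    if not inside:
        d = t.start - e if e < t.start else s - t.end
        if d > flank:
            return set()
        before = e < t.start
        upstream = before == (t.strand == 1)
        return {"upstream_gene_variant" if upstream
                else "downstream_gene_variant"}

    # positional window sets ------------------------------------------------
    walk: list[int] = []
    for exon in t.exons:
        rng_ = (range(exon.start, exon.end + 1) if t.strand == 1
                else range(exon.end, exon.start - 1, -1))
        walk.extend(rng_)
    exon_set = set(walk)
    genomic_exons = sorted((ex.start, ex.end) for ex in t.exons)
    introns = [(a[1] + 1, b[0] - 1)
               for a, b in zip(genomic_exons, genomic_exons[1:])]
    donor, acceptor, sregion = set(), set(), set()
    for iv_s, iv_e in introns:
        for p in range(iv_s, iv_e + 1):
            d5 = (p - iv_s + 1) if t.strand == 1 else (iv_e - p + 1)
            d3 = (iv_e - p + 1) if t.strand == 1 else (p - iv_s + 1)
            if d5 <= 2:
                donor.add(p)
            if d3 <= 2:
                acceptor.add(p)
            if 3 <= min(d5, d3) <= 8:
                sregion.add(p)
        # exonic 1..3 on both sides of the junction
        for q in range(iv_s - 3, iv_s):
            if q in exon_set:
                sregion.add(q)
        for q in range(iv_e + 1, iv_e + 4):
            if q in exon_set:
                sregion.add(q)

    positions = [s] if is_ins else list(range(s, e + 1))
    # treat an insertion as living between its two flanking bases
    ins_flanks = (s, e) if is_ins else None

    terms: set[str] = set()

    def touches(pos_set: set[int]) -> bool:
        if is_ins:
            return ins_flanks[0] in pos_set and ins_flanks[1] in pos_set
        return any(p in pos_set for p in positions)

    if touches(donor):
        terms.add("splice_donor_variant")
    if touches(acceptor):
        terms.add("splice_acceptor_variant")
    if touches(sregion):
        terms.add("splice_region_variant")
    intron_set = set()
    for iv_s, iv_e in introns:
        intron_set.update(range(iv_s, iv_e + 1))
    plain_intron = intron_set - donor - acceptor
    if is_ins:
        both_intronic = (ins_flanks[0] in intron_set
                         and ins_flanks[1] in intron_set)
        if both_intronic and not (
                touches(donor) or touches(acceptor)):
            terms.add("intron_variant")
    elif any(p in plain_intron for p in positions):
        terms.add("intron_variant")

    if not t.is_coding:
        exonic = touches(exon_set)
        if exonic:
            if (t.mature_mirna is not None
                    and any(t.mature_mirna.start <= p <= t.mature_mirna.end
                            for p in positions)):
                terms.add("mature_miRNA_variant")
            else:
                terms.add("non_coding_transcript_exon_variant")
        else:
            terms.add("non_coding_transcript_variant")
        return terms

    # coding transcript, exonic part ----------------------------------------
    if not touches(exon_set):
        return terms
    ccs_g = t.cds_genomic_start if t.strand == 1 else t.cds_genomic_end
    cce_g = t.cds_genomic_end if t.strand == 1 else t.cds_genomic_start
    ccs = walk.index(ccs_g) + 1
    cce = walk.index(cce_g) + 1

    if is_ins:
        idxs = [walk.index(p) + 1 for p in ins_flanks if p in exon_set]
        lo = min(idxs)
        hi = max(idxs)
    else:
        in_exon = [walk.index(p) + 1 for p in positions if p in exon_set]
        lo, hi = min(in_exon), max(in_exon)
    if lo < ccs:
        terms.add("5_prime_UTR_variant")
    if hi > cce:
        terms.add("3_prime_UTR_variant")
    if hi < ccs or lo > cce:
        return terms

    # the variant touches the CDS: rebuild and re-translate
    cds_len = cce - ccs + 1
    n_complete = cds_len - cds_len % 3

    if is_ins or variant.ref_allele == "-" or "-" in variant.alt_alleles \
            or len(variant.ref_allele) != len(variant.alt_alleles[0]):
        # simple indel arithmetic on coding bases
        del_coding = 0 if is_ins else sum(
            1 for p in positions
            if p in exon_set and ccs <= walk.index(p) + 1 <= cce)
        alt = variant.alt_alleles[0]
        ins_len = 0 if alt == "-" else len(alt)
        ref_len = 0 if variant.ref_allele == "-" else len(variant.ref_allele)
        if is_ins:
            net = ins_len
        else:
            net = ins_len - del_coding if ref_len == del_coding else -del_coding
        if net % 3 != 0:
            terms.add("frameshift_variant")
        elif net < 0:
            terms.add("inframe_deletion")
        elif net > 0:
            terms.add("inframe_insertion")
        return terms

    # SNV / MNV: whole-protein comparison
    alt = variant.alt_alleles[0]
    mutant = chrom_seq[:variant.start - 1] + alt + chrom_seq[variant.end:]
    cdna_ref = _oracle_splice(chrom_seq, t)
    cdna_alt = _oracle_splice(mutant, t)
    cds_ref = cdna_ref[ccs - 1:cce]
    cds_alt = cdna_alt[ccs - 1:cce]
    cds_positions = sorted(walk.index(p) + 1 - ccs + 1 for p in positions
                           if p in exon_set and ccs <= walk.index(p) + 1 <= cce)
    if any(cp > n_complete for cp in cds_positions):
        terms.add("incomplete_terminal_codon_variant")
        return terms
    ref_p = _oracle_translate(cds_ref, table, sec)
    alt_p = _oracle_translate(cds_alt, table, sec)
    if ref_p == alt_p:
        codon_idx = (cds_positions[0] - 1) // 3
        terms.add("stop_retained_variant" if ref_p[codon_idx] == "*"
                  else "synonymous_variant")
        return terms
    i = next(k for k in range(len(ref_p)) if ref_p[k] != alt_p[k])
    if i == 0:
        terms.add("start_lost")
    elif ref_p[i] == "*":
        terms.add("stop_lost")
    elif alt_p[i] == "*":
        terms.add("stop_gained")
    else:
        terms.add("missense_variant")
    return terms
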