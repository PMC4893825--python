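# Consequence term registry: Sequence Ontology classes assignable by the engine.
# Columns: so_name <TAB> so_accession <TAB> parents (comma list of so_names, "-" for none) <TAB> rank (1 = most severe) <TAB> impact
# Membership is data, not code; a user-supplied registry file with the same columns can override this one.
transcript_ablation	SO:0001893	-	1	HIGH
splice_acceptor_variant	SO:0001574	-	2	HIGH
splice_donor_variant	SO:0001575	-	3	HIGH
stop_gained	SO:0001587	coding_sequence_variant	4	HIGH
frameshift_variant	SO:0001589	coding_sequence_variant	5	HIGH
stop_lost	SO:0001578	coding_sequence_variant	6	HIGH
start_lost	SO:0002012	coding_sequence_variant	7	HIGH
transcript_amplification	SO:0001889	-	8	HIGH
inframe_insertion	SO:0001821	coding_sequence_variant	9	MODERATE
inframe_deletion	SO:0001822	coding_sequence_variant	10	MODERATE
missense_variant	SO:0001583	coding_sequence_variant	11	MODERATE
splice_region_variant	SO:0001630	-	12	LOW
incomplete_terminal_codon_variant	SO:0001626	coding_sequence_variant	13	LOW
stop_retained_variant	SO:0001567	coding_sequence_variant	14	LOW
synonymous_variant	SO:0001819	coding_sequence_variant	15	LOW
coding_sequence_variant	SO:0001580	-	16	MODIFIER
mature_miRNA_variant	SO:0001620	non_coding_transcript_exon_variant	17	MODIFIER
5_prime_UTR_variant	SO:0001623	-	18	MODIFIER
3_prime_UTR_variant	SO:0001624	-	19	MODIFIER
non_coding_transcript_exon_variant	SO:0001792	non_coding_transcript_variant	20	MODIFIER
intron_variant	SO:0001627	-	21	MODIFIER
non_coding_transcript_variant	SO:0001619	-	22	MODIFIER
upstream_gene_variant	SO:0001631	-	23	MODIFIER
downstream_gene_variant	SO:0001632	-	24	MODIFIER
TFBS_ablation	SO:0001895	-	25	HIGH
TFBS_amplification	SO:0001892	-	26	HIGH
TF_binding_site_variant	SO:0001782	regulatory_region_variant	27	MODIFIER
regulatory_region_ablation	SO:0001894	-	28	HIGH
regulatory_region_amplification	SO:0001891	-	29	HIGH
feature_elongation	SO:0001907	-	30	MODIFIER
regulatory_region_variant	SO:0001566	-	31	MODIFIER
feature_truncation	SO:0001906	-	32	MODIFIER
intergenic_variant	SO:0001628	-	33	MODIFIER
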