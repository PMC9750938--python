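rank	term
1	transcript_ablation
2	splice_acceptor_variant
3	splice_donor_variant
4	stop_gained
5	frameshift_variant
6	stop_lost
7	start_lost
8	transcript_amplification
9	inframe_insertion
10	inframe_deletion
11	missense_variant
12	protein_altering_variant
13	splice_region_variant
14	incomplete_terminal_codon_variant
15	start_retained_variant
16	stop_retained_variant
17	synonymous_variant
18	coding_sequence_variant
19	mature_miRNA_variant
20	5_prime_UTR_variant
21	3_prime_UTR_variant
22	non_coding_transcript_exon_variant
23	intron_variant
24	NMD_transcript_variant
25	non_coding_transcript_variant
26	upstream_gene_variant
27	downstream_gene_variant
28	TFBS_ablation
29	TFBS_amplification
30	TF_binding_site_variant
31	regulatory_region_ablation
32	regulatory_region_amplification
33	feature_elongation
34	regulatory_region_variant
35	feature_truncation
36	intergenic_variant
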