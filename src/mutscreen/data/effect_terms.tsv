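term	category
start_lost	disruptive
stop_lost	disruptive
stop_gained	disruptive
splice_donor_variant	disruptive
splice_acceptor_variant	disruptive
exon_loss_variant	disruptive
transcript_ablation	disruptive
frameshift_variant	coding
missense_variant	coding
synonymous_variant	coding
inframe_insertion	coding
inframe_deletion	coding
conservative_inframe_insertion	coding
conservative_inframe_deletion	coding
disruptive_inframe_insertion	coding
disruptive_inframe_deletion	coding
stop_retained_variant	coding
start_retained_variant	coding
initiator_codon_variant	coding
protein_altering_variant	coding
coding_sequence_variant	coding
incomplete_terminal_codon_variant	coding
splice_region_variant	non_coding
intron_variant	non_coding
intergenic_region	non_coding
intergenic_variant	non_coding
5_prime_UTR_variant	non_coding
3_prime_UTR_variant	non_coding
5_prime_UTR_premature_start_codon_gain_variant	non_coding
upstream_gene_variant	non_coding
downstream_gene_variant	non_coding
non_coding_transcript_variant	non_coding
non_coding_transcript_exon_variant	non_coding
regulatory_region_variant	non_coding
TF_binding_site_variant	non_coding
intragenic_variant	non_coding
sequence_feature	non_coding
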