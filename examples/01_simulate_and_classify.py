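"""Generate a synthetic tumor cohort and rebuild its mutation matrix from VCFs.

Emits per-patient annotated variant records, then runs the intake pipeline
(quality filters at 40x depth / 5 ALT reads, canonical-isoform restriction,
disruptive-impact classification) and ranks genes by mutation frequency.
The printed ranking should match the planted driver frequencies, and the
high-frequency passenger TTN is excluded.
"""

from tempfile import TemporaryDirectory

from mutscreen import (
    MutationCategory, SyntheticCohortConfig, apply_quality_filters,
    build_mutation_matrix, generate_variant_records, parse_vcf_dir,
    rank_mutation_frequency, select_canonical,
)

cfg = SyntheticCohortConfig(n_patients=300)

with TemporaryDirectory() as vcf_dir:
    _, truth = generate_variant_records(cfg, seed=17, out_dir=vcf_dir)
    variants = parse_vcf_dir(vcf_dir)
    print(f"parsed {len(variants)} variant records")
    variants = apply_quality_filters(variants, min_depth=40, min_alt_reads=5)
    variants = select_canonical(variants)
    print(f"{len(variants)} variants after QC + canonical restriction")

    matrix = build_mutation_matrix(variants, MutationCategory.DISRUPTIVE,
                                   cfg.patient_ids, cfg.mutation_genes)
    ranking = rank_mutation_frequency(matrix, exclude=["TTN"], top_k=10)
    print("\nmost frequently disrupted genes (TTN excluded):")
    print(ranking.to_string(index=False))

# 'fraction' is the share of patients carrying >=1 disruptive mutation in the
# gene; it tracks the planted frequencies (0.05-0.15) up to QC dropouts.
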