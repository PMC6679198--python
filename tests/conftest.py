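"""Shared fixtures: small synthetic cohorts and hand-written VCF text.

All fixtures are generated programmatically; the only stored file is a tiny
synthetic druggability snapshot (tests/data/synthetic_dgidb_snapshot.tsv).
"""

from pathlib import Path

import pytest

from mutscreen import (
    SyntheticCohortConfig, generate_cohort, normalize_counts,
)

DATA_DIR = Path(__file__).parent / "data"

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FILTER=<ID=germline_risk,Description="germline">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP001
"""


def ann(alt, gene, terms, canonical=True, tx="T1", cds="90/900"):
    tag = "CANONICAL" if canonical else ""
    return (f"{alt}|{'&'.join(terms)}|HIGH|{gene}|{gene}|transcript|{gene}_{tx}|"
            f"protein_coding|1/9|c.1A>T|p.K1*|120/1200|{cds}|30/300|0|{tag}")


def vcf_record(chrom, pos, ref, alt, filt, depth, alt_reads, ann_str):
    return (f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t"
            f"DP={depth};ANN={ann_str}\tGT:AD:DP\t"
            f"0/1:{depth - alt_reads},{alt_reads}:{depth}")


@pytest.fixture()
def make_vcf(tmp_path):
    """Write VCF text (records list of strings) to a file; returns the path."""

    def _make(records, name="P001.vcf"):
        path = tmp_path / name
        path.write_text(VCF_HEADER + "\n".join(records) + "\n")
        return path

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient, 300-gene cohort with the default plants; session-cached."""
    cfg = SyntheticCohortConfig(n_patients=120, n_genes=300, seed=42)
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    return normalize_counts(small_cohort.counts, poscounts=True)


@pytest.fixture()
def dgidb_table_path():
    return DATA_DIR / "synthetic_dgidb_snapshot.tsv"
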