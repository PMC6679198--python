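"""Variant parsing, quality filtering, classification, matrix construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutscreen import (
    AnnotatedVariant, MutationCategory, SyntheticCohortConfig,
    TranscriptAnnotation, apply_quality_filters, build_mutation_matrix,
    classify_variant, generate_cohort, parse_annotated_variants,
    rank_mutation_frequency, select_canonical,
)
from mutscreen.variants import load_effect_table

from conftest import ann, vcf_record


def make_variant(terms, ref="A", alt="T", filt="PASS", depth=60, alt_reads=20,
                 gene="APC", canonical=True, patient="P001"):
    return AnnotatedVariant(
        patient_id=patient, chrom="1", pos=100, ref=ref, alt=alt,
        filter_status=filt, total_depth=depth, alt_reads=alt_reads,
        annotations=[TranscriptAnnotation(gene, f"{gene}_T1",
                                          frozenset(terms), canonical)],
    )


# ---------------------------------------------------------------------------
# parsing


class TestParsing:
    def test_single_record_field_mapping(self, make_vcf):
        path = make_vcf([vcf_record("1", 1000, "C", "T", "PASS", 80, 30,
                                    ann("T", "APC", ["stop_gained"]))])
        variants = parse_annotated_variants(path)
        assert len(variants) == 1
        v = variants[0]
        assert (v.patient_id, v.chrom, v.pos, v.ref, v.alt) == ("P001", "1", 1000, "C", "T")
        assert v.filter_status == "PASS"
        assert (v.total_depth, v.alt_reads) == (80, 30)
        assert len(v.annotations) == 1
        assert v.annotations[0].effect_terms == frozenset({"stop_gained"})
        assert v.annotations[0].is_canonical

    def test_multiallelic_record_splits(self, make_vcf):
        rec = ("1\t2000\t.\tA\tT,G\t.\tPASS\tDP=100;ANN="
               + ann("T", "APC", ["missense_variant"]) + ","
               + ann("G", "APC", ["synonymous_variant"])
               + "\tGT:AD:DP\t1/2:40,30,30:100")
        variants = parse_annotated_variants(make_vcf([rec]))
        assert len(variants) == 2
        assert {v.alt for v in variants} == {"T", "G"}
        by_alt = {v.alt: v for v in variants}
        assert by_alt["T"].annotations[0].effect_terms == {"missense_variant"}
        assert by_alt["T"].alt_reads == 30
        assert by_alt["G"].alt_reads == 30

    def test_missing_ann_retained_with_empty_annotations(self, make_vcf):
        rec = "1\t3000\t.\tA\tT\t.\tPASS\tDP=50\tGT:AD:DP\t0/1:30,20:50"
        variants = parse_annotated_variants(make_vcf([rec]))
        assert len(variants) == 1
        assert variants[0].annotations == []
        # downstream canonical selection drops it
        assert select_canonical(variants) == []

    def test_generated_fixture_round_trips_core_fields(self, tmp_path):
        """12 synthetic records written then re-read keep their core fields."""
        from mutscreen.simulate import _ann_field, _vcf_record, _VCF_HEADER

        rng = np.random.default_rng(0)
        rows, expected = [], []
        for i in range(12):
            chrom, pos = str(i % 2 + 1), 1000 + 10 * i
            ref, alt = "AC"[i % 2], "TG"[i % 2]
            depth = int(rng.integers(40, 100))
            alt_reads = int(rng.integers(5, 30))
            rows.append((int(chrom), pos,
                         _vcf_record(chrom, pos, ref, alt, "PASS", depth, alt_reads,
                                     _ann_field(alt, "APC", ("missense_variant",),
                                                canonical=True))))
            expected.append((chrom, pos, ref, alt, depth, alt_reads))
        rows.sort()
        path = tmp_path / "P001.vcf"
        path.write_text(_VCF_HEADER + "##contig=<ID=1>\n##contig=<ID=2>\n"
                        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP001\n"
                        + "\n".join(r for _, _, r in rows) + "\n")
        variants = parse_annotated_variants(path)
        got = sorted((v.chrom, v.pos, v.ref, v.alt, v.total_depth, v.alt_reads)
                     for v in variants)
        assert got == sorted((c, p, r, a, d, ar) for c, p, r, a, d, ar in
                             [(e[0], e[1], e[2], e[3], e[4], e[5]) for e in expected])

    def test_symbolic_allele_rejected(self):
        with pytest.raises(ValueError, match="symbolic"):
            AnnotatedVariant("P1", "1", 10, "A", "<DEL>", "PASS", 50, 10, [])


# ---------------------------------------------------------------------------
# quality filters


class TestQualityFilters:
    @pytest.mark.parametrize("filt,depth,alt,kept", [
        ("PASS", 40, 5, True),    # both thresholds exactly attained
        ("PASS", 39, 10, False),  # depth one below
        ("PASS", 100, 4, False),  # ALT reads one below
        ("germline_risk", 100, 50, False),
    ])
    def test_boundaries(self, filt, depth, alt, kept):
        out = apply_quality_filters([make_variant(["missense_variant"], filt=filt,
                                                  depth=depth, alt_reads=alt)])
        assert (len(out) == 1) is kept

    def test_monotone_in_min_depth(self):
        rng = np.random.default_rng(1)
        variants = [make_variant(["missense_variant"],
                                 depth=int(rng.integers(10, 120)),
                                 alt_reads=int(rng.integers(0, 10)),
                                 filt=rng.choice(["PASS", "germline_risk"]))
                    for _ in range(100)]
        sizes = [len(apply_quality_filters(variants, min_depth=d))
                 for d in range(0, 130, 10)]
        assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# canonical selection


class TestCanonical:
    def test_non_canonical_annotation_removed(self):
        v = make_variant(["missense_variant"])
        v.annotations.append(TranscriptAnnotation("APC", "APC_T2",
                                                  frozenset({"stop_gained"}), False))
        out = select_canonical([v])
        assert len(out) == 1
        assert [a.effect_terms for a in out[0].annotations] == [{"missense_variant"}]

    def test_variant_without_canonical_dropped(self):
        v = make_variant(["stop_gained"], canonical=False)
        assert select_canonical([v]) == []

    def test_two_canonical_genes_both_retained(self):
        v = make_variant(["missense_variant"], gene="GENE_A")
        v.annotations.append(TranscriptAnnotation("GENE_B", "GENE_B_T1",
                                                  frozenset({"stop_gained"}), True))
        out = select_canonical([v])
        assert {a.gene_symbol for a in out[0].annotations} == {"GENE_A", "GENE_B"}

    def test_longest_cds_fallback_when_flag_absent(self, make_vcf):
        rec = ("1\t500\t.\tA\tT\t.\tPASS\tDP=60;ANN="
               + ann("T", "APC", ["missense_variant"], canonical=False, tx="T1",
                     cds="90/300") + ","
               + ann("T", "APC", ["synonymous_variant"], canonical=False, tx="T2",
                     cds="90/1200")
               + "\tGT:AD:DP\t0/1:40,20:60")
        variants = parse_annotated_variants(make_vcf([rec]))
        canon = [a for a in variants[0].annotations if a.is_canonical]
        assert len(canon) == 1
        assert canon[0].transcript_id == "APC_T2"  # longer CDS wins


# ---------------------------------------------------------------------------
# classification


class TestClassification:
    @pytest.mark.parametrize("terms,ref,alt,expected", [
        ({"stop_gained"}, "C", "T", "disruptive"),
        ({"start_lost"}, "A", "G", "disruptive"),
        ({"stop_lost"}, "T", "C", "disruptive"),
        ({"splice_donor_variant"}, "G", "A", "disruptive"),
        ({"splice_acceptor_variant"}, "A", "C", "disruptive"),
        ({"splice_region_variant"}, "A", "C", "non_coding"),
        ({"splice_region_variant", "synonymous_variant"}, "A", "C", "coding"),
        ({"frameshift_variant"}, "A", "AT", "disruptive"),        # 1-nt insertion
        ({"conservative_inframe_deletion"}, "GTCA", "G", "coding"),  # 3-nt deletion
        ({"synonymous_variant"}, "C", "A", "coding"),
        ({"missense_variant"}, "G", "T", "coding"),
        ({"intron_variant"}, "A", "T", "non_coding"),
        ({"totally_made_up_term"}, "A", "T", "non_coding"),  # fallback is total
    ])
    def test_category_rules(self, terms, ref, alt, expected):
        a = TranscriptAnnotation("G1", "G1_T1", frozenset(terms), True)
        assert classify_variant(a, ref, alt).value == expected

    @pytest.mark.parametrize("length", range(1, 13))
    def test_frameshift_rule_exhaustive(self, length):
        """Coding indels of length 1..12 are disruptive iff length % 3 != 0."""
        ref = "A"
        alt = "A" + "T" * length
        term = ("frameshift_variant" if length % 3
                else "conservative_inframe_insertion")
        a = TranscriptAnnotation("G1", "G1_T1", frozenset({term}), True)
        cat = classify_variant(a, ref, alt)
        if length % 3:
            assert cat is MutationCategory.DISRUPTIVE
        else:
            assert cat is not MutationCategory.DISRUPTIVE

    def test_category_nesting_over_whole_vocabulary(self):
        """disruptive => coding => any; coding and non_coding disjoint."""
        table = load_effect_table()
        for term in table:
            a = TranscriptAnnotation("G1", "G1_T1", frozenset({term}), True)
            cat = classify_variant(a, "A", "T")  # SNV: no frameshift promotion
            assert MutationCategory.ANY.includes(cat)
            if cat is MutationCategory.DISRUPTIVE:
                assert MutationCategory.CODING.includes(cat)
            if cat is MutationCategory.NON_CODING:
                assert not MutationCategory.CODING.includes(cat)


# ---------------------------------------------------------------------------
# mutation matrix


class TestMutationMatrix:
    def test_binarization_and_category_gate(self):
        variants = [make_variant(["stop_gained"], gene="APC") for _ in range(3)]
        variants.append(make_variant(["missense_variant"], gene="TP53"))
        m = build_mutation_matrix(variants, MutationCategory.DISRUPTIVE,
                                  ["P001", "P002"], ["APC", "TP53"])
        assert m.indicator.at["P001", "APC"] == 1   # 3 variants, still 1
        assert m.indicator.at["P001", "TP53"] == 0  # missense not disruptive
        assert m.indicator.loc["P002"].sum() == 0   # absent patient = wild-type

    def test_permutation_invariant_and_idempotent(self):
        rng = np.random.default_rng(2)
        variants = [make_variant(["stop_gained"], gene=g, patient=p)
                    for g in ("APC", "TP53") for p in ("P001", "P002", "P003")
                    if rng.random() < 0.6]
        pats, genes = ["P001", "P002", "P003"], ["APC", "TP53"]
        base = build_mutation_matrix(variants, MutationCategory.DISRUPTIVE, pats, genes)
        shuffled = list(variants)[::-1]
        dup = variants + variants
        for other in (shuffled, dup):
            m = build_mutation_matrix(other, MutationCategory.DISRUPTIVE, pats, genes)
            pd.testing.assert_frame_equal(m.indicator, base.indicator)

    def test_unknown_gene_skipped(self):
        v = make_variant(["stop_gained"], gene="NOT_IN_UNIVERSE")
        m = build_mutation_matrix([v], MutationCategory.DISRUPTIVE, ["P001"], ["APC"])
        assert m.indicator.to_numpy().sum() == 0

    def test_planted_frequency_within_binomial_interval(self):
        """10% planted frequency at n=500: column sum inside the 99% interval."""
        cfg = SyntheticCohortConfig(n_patients=500, n_genes=20,
                                    driver_specs=(("ACVR2A", 0.10),),
                                    plant_specs=(), hazard_specs=())
        cohort = generate_cohort(cfg, seed=123)
        count = cohort.mutation_matrix.indicator["ACVR2A"].sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.10)
        assert lo <= count <= hi


# ---------------------------------------------------------------------------
# frequency ranking


class TestRanking:
    def _matrix(self, counts: dict, n=500):
        pats = [f"P{i:04d}" for i in range(n)]
        df = pd.DataFrame(0, index=pats, columns=list(counts), dtype="int8")
        for g, k in counts.items():
            df.iloc[:k, df.columns.get_loc(g)] = 1
        from mutscreen import MutationMatrix
        return MutationMatrix(indicator=df, category=MutationCategory.DISRUPTIVE)

    def test_exclusion_and_sort(self):
        m = self._matrix({"APC": 300, "TP53": 250, "TTN": 400})
        r = rank_mutation_frequency(m, exclude=["TTN"], top_k=2)
        assert list(r["gene"]) == ["APC", "TP53"]
        assert list(r["mutated_count"]) == [300, 250]
        assert r["fraction"].iloc[0] == pytest.approx(0.6)

    def test_tie_broken_lexicographically(self):
        m = self._matrix({"ZZZ": 40, "AAA": 40, "MMM": 10})
        r = rank_mutation_frequency(m, exclude=[], top_k=3)
        assert list(r["gene"]) == ["AAA", "ZZZ", "MMM"]

    def test_top_k_exceeding_returns_all(self):
        m = self._matrix({"APC": 10, "TP53": 5})
        r = rank_mutation_frequency(m, exclude=[], top_k=10)
        assert len(r) == 2

    def test_ranking_matches_planted_frequencies(self, small_cohort):
        cfg = small_cohort.config
        r = rank_mutation_frequency(small_cohort.mutation_matrix,
                                    exclude=["TTN"], top_k=10)
        assert "TTN" not in set(r["gene"])
        # top planted driver (15%) should out-rank the bottom one (5%)
        ranks = {g: i for i, g in enumerate(r["gene"])}
        assert ranks["APC"] < ranks["MDN1"]
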