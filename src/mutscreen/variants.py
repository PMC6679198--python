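"""Somatic variant intake, quality filtering and impact classification.

This module turns annotated somatic variant calls (VCF with snpEff-style
``ANN`` INFO annotations) into a patient x gene binary *disruptive mutation*
matrix, the starting point of the screening funnel:

1. :func:`parse_annotated_variants` — read one tumor VCF into
   :class:`AnnotatedVariant` records (one per ALT allele).
2. :func:`apply_quality_filters` — keep caller-PASS calls with adequate
   per-site depth and ALT-supporting reads (defaults 40x / 5 reads).
3. :func:`select_canonical` — restrict annotations to the canonical isoform.
4. :func:`classify_variant` — map Sequence Ontology effect terms to one of
   ``disruptive`` / ``coding`` / ``non_coding``.  Disruptive means the protein
   product is predicted destroyed: loss of the START or STOP codon, a
   premature stop, a splice donor/acceptor hit (a splice *region* hit alone
   does not qualify), or a frameshift indel, operationalized as indel length
   not a multiple of 3.
5. :func:`build_mutation_matrix` / :func:`rank_mutation_frequency` — binary
   indicator matrix and frequency ranking of the most mutated genes.

The effect-term vocabulary ships as an editable table
(``mutscreen/data/effect_terms.tsv``) so annotation-dialect drift is a data
fix, not a code fix.  Unknown terms fall back to ``non_coding`` with a
logged warning; classification is total.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELE = re.compile(r"^[ACGT]+$")

__all__ = [
    "AnnotatedVariant",
    "TranscriptAnnotation",
    "MutationCategory",
    "MutationMatrix",
    "VcfParseError",
    "load_effect_table",
    "parse_annotated_variants",
    "parse_vcf_dir",
    "apply_quality_filters",
    "select_canonical",
    "classify_variant",
    "build_mutation_matrix",
    "rank_mutation_frequency",
]


class VcfParseError(ValueError):
    """Raised when a VCF stream cannot be parsed."""


class MutationCategory(str, Enum):
    """Variant impact category.

    Categories nest: every disruptive variant is also coding, and every
    variant is ``any``.  ``non_coding`` and ``coding`` are disjoint.
    """

    DISRUPTIVE = "disruptive"
    CODING = "coding"
    NON_CODING = "non_coding"
    ANY = "any"

    def includes(self, specific: "MutationCategory") -> bool:
        """Whether a variant classified as `specific` belongs to this category."""
        if self is MutationCategory.ANY:
            return True
        if self is MutationCategory.CODING:
            return specific in (MutationCategory.CODING, MutationCategory.DISRUPTIVE)
        return specific is self


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One per-transcript effect annotation of a variant."""

    gene_symbol: str
    transcript_id: str
    effect_terms: frozenset
    is_canonical: bool = False

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not self.effect_terms:
            raise ValueError("effect_terms must be non-empty")


@dataclass
class AnnotatedVariant:
    """One somatic variant (single ALT allele) with transcript annotations."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str
    total_depth: int
    alt_reads: int
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not _VALID_ALLELE.match(self.ref) or not _VALID_ALLELE.match(self.alt):
            raise ValueError(
                f"ref/alt must be non-empty A/C/G/T sequences "
                f"(symbolic alleles rejected): {self.ref!r}>{self.alt!r}"
            )
        if self.alt_reads > self.total_depth:
            raise ValueError("alt_reads cannot exceed total_depth")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass
class MutationMatrix:
    """Patients x genes binary indicator of mutation status for one category."""

    indicator: pd.DataFrame  # index = patient ids, columns = gene symbols, {0,1}
    category: MutationCategory

    def __post_init__(self):
        if self.indicator.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        if self.indicator.columns.has_duplicates:
            raise ValueError("duplicate gene symbols")

    @property
    def patient_ids(self) -> list:
        return list(self.indicator.index)

    @property
    def gene_symbols(self) -> list:
        return list(self.indicator.columns)


# ---------------------------------------------------------------------------
# Effect vocabulary


def load_effect_table(path=None) -> Mapping[str, str]:
    """Load the effect-term -> category table (package default or user TSV)."""
    if path is None:
        with resources.files("mutscreen.data").joinpath("effect_terms.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    bad = set(df["category"]) - {"disruptive", "coding", "non_coding"}
    if bad:
        raise ValueError(f"unknown categories in effect table: {bad}")
    return dict(zip(df["term"], df["category"]))


_EFFECT_TABLE = load_effect_table()
_warned_terms: set = set()


def classify_variant(
    annotation: TranscriptAnnotation,
    ref: str,
    alt: str,
    effect_table: Mapping[str, str] | None = None,
) -> MutationCategory:
    """Classify one transcript annotation into its most specific category.

    Disruptive iff any hard-disruptive term is present (start/stop loss,
    premature stop, splice donor/acceptor) or the variant is a coding indel
    whose length is not a multiple of 3 (frameshift).  ``splice_region_variant``
    alone never qualifies as disruptive.  Unknown terms are treated as
    non-coding with a one-time logged warning.
    """
    table = _EFFECT_TABLE if effect_table is None else effect_table
    classes = set()
    for term in annotation.effect_terms:
        cat = table.get(term)
        if cat is None:
            if term not in _warned_terms:
                logger.warning("unknown effect term %r; treating as non_coding", term)
                _warned_terms.add(term)
            cat = "non_coding"
        classes.add(cat)
    if "disruptive" in classes:
        return MutationCategory.DISRUPTIVE
    if "coding" in classes:
        indel_len = abs(len(alt) - len(ref))
        if indel_len > 0 and indel_len % 3 != 0:
            return MutationCategory.DISRUPTIVE
        return MutationCategory.CODING
    return MutationCategory.NON_CODING


# ---------------------------------------------------------------------------
# VCF parsing


def _parse_ann_entry(entry: str):
    """Split one pipe-delimited ANN sub-entry.

    Layout: Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|
    BioType|Rank|HGVS.c|HGVS.p|cDNA|CDS|AA|Distance|Errors.  The canonical
    isoform is flagged by the token CANONICAL in the trailing Errors/Info
    subfield; when absent for a whole variant, the longest CDS per gene is
    taken as canonical (logged fallback).
    """
    fields = entry.split("|")
    allele = fields[0]
    terms = frozenset(t for t in fields[1].split("&") if t) if len(fields) > 1 else frozenset()
    gene = fields[3] if len(fields) > 3 else ""
    transcript = fields[6] if len(fields) > 6 else ""
    cds_len = 0
    if len(fields) > 12 and "/" in fields[12]:
        try:
            cds_len = int(fields[12].split("/")[1])
        except ValueError:
            cds_len = 0
    canonical = len(fields) > 15 and "CANONICAL" in fields[15]
    return allele, gene, transcript, terms, canonical, cds_len


def parse_annotated_variants(source, patient_id: str | None = None) -> list:
    """Parse one VCF file into :class:`AnnotatedVariant` records.

    Parameters
    ----------
    source
        Path to a VCF 4.x file with snpEff-style ``ANN`` INFO annotations.
    patient_id
        Patient identifier; defaults to the sample name in the VCF header,
        else the file stem.

    Returns one record per ALT allele per VCF record (multi-allelic records
    are split).  Records with symbolic or non-ACGT alleles are dropped with a
    logged count; records whose ``ANN`` field is missing are retained with
    empty annotations (they are excluded downstream by
    :func:`select_canonical`).
    """
    import cyvcf2

    source = Path(source)
    try:
        vcf = cyvcf2.VCF(str(source))
    except Exception as exc:  # htslib errors are opaque; name the file
        raise VcfParseError(f"cannot parse VCF {source}: {exc}") from exc

    if patient_id is None:
        patient_id = vcf.samples[0] if vcf.samples else source.stem

    out: list = []
    n_symbolic = 0
    n_missing_ann = 0
    n_fallback_canon = 0
    for rec in vcf:
        filt = rec.FILTER or "PASS"
        ann_raw = rec.INFO.get("ANN")
        ad = rec.format("AD") if rec.num_called or vcf.samples else None
        for k, alt in enumerate(rec.ALT):
            if not _VALID_ALLELE.match(alt or "") or not _VALID_ALLELE.match(rec.REF or ""):
                n_symbolic += 1
                continue
            if ad is not None and ad.shape[1] > k + 1:
                alt_reads = int(ad[0][k + 1])
                total_depth = int(ad[0].clip(min=0).sum())
            else:
                alt_reads = int(rec.INFO.get("ALT_DP", 0) or 0)
                total_depth = int(rec.INFO.get("DP", alt_reads) or alt_reads)
            dp = rec.format("DP")
            if dp is not None:
                total_depth = max(total_depth, int(dp[0][0]))
            anns = []
            if ann_raw:
                for entry in str(ann_raw).split(","):
                    allele, gene, tx, terms, canon, cds_len = _parse_ann_entry(entry)
                    if allele != alt or not gene or not terms:
                        continue
                    anns.append((TranscriptAnnotation(gene, tx, terms, canon), cds_len))
            else:
                n_missing_ann += 1
            if anns and not any(a.is_canonical for a, _ in anns):
                # fallback: longest CDS per gene treated as canonical
                n_fallback_canon += 1
                best: dict = {}
                for a, cds_len in anns:
                    if a.gene_symbol not in best or cds_len > best[a.gene_symbol][1]:
                        best[a.gene_symbol] = (a, cds_len)
                anns = [
                    (
                        TranscriptAnnotation(
                            a.gene_symbol, a.transcript_id, a.effect_terms,
                            is_canonical=(a is best[a.gene_symbol][0]),
                        ),
                        c,
                    )
                    for a, c in anns
                ]
            out.append(
                AnnotatedVariant(
                    patient_id=patient_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    filter_status=filt,
                    total_depth=max(total_depth, alt_reads),
                    alt_reads=alt_reads,
                    annotations=[a for a, _ in anns],
                )
            )
    if n_symbolic:
        logger.info("%s: dropped %d symbolic/non-ACGT allele records", source.name, n_symbolic)
    if n_missing_ann:
        logger.info("%s: %d records missing ANN retained with empty annotations",
                    source.name, n_missing_ann)
    if n_fallback_canon:
        logger.debug("%s: canonical flag absent for %d variants; longest-CDS fallback used",
                     source.name, n_fallback_canon)
    return out


def parse_vcf_dir(vcf_dir, sample_map=None) -> list:
    """Parse every ``*.vcf`` under `vcf_dir`.

    `sample_map` optionally maps VCF sample/file ids to patient ids
    (two-column TSV path or dict: sample_id -> patient_id).
    """
    mapping = {}
    if sample_map is not None:
        if isinstance(sample_map, (str, Path)):
            df = pd.read_csv(sample_map, sep="\t")
            mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        else:
            mapping = dict(sample_map)
    variants: list = []
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        pid = mapping.get(path.stem)
        variants.extend(parse_annotated_variants(path, patient_id=pid))
    return variants


# ---------------------------------------------------------------------------
# Filtering


def apply_quality_filters(
    variants: Iterable[AnnotatedVariant],
    min_depth: int = 40,
    min_alt_reads: int = 5,
) -> list:
    """Keep caller-PASS variants with total depth >= `min_depth` and
    ALT-supporting reads >= `min_alt_reads` (defaults 40 and 5)."""
    if min_depth < 0 or min_alt_reads < 0:
        raise ValueError("thresholds must be non-negative")
    kept = []
    removed = Counter()
    for v in variants:
        if v.filter_status != "PASS":
            removed["non_pass"] += 1
        elif v.total_depth < min_depth:
            removed["low_depth"] += 1
        elif v.alt_reads < min_alt_reads:
            removed["low_alt_reads"] += 1
        else:
            kept.append(v)
    if removed:
        logger.info("quality filter removals: %s", dict(removed))
    return kept


def select_canonical(variants: Iterable[AnnotatedVariant]) -> list:
    """Reduce each variant's annotations to canonical-transcript ones.

    Variants left with no canonical annotation are dropped (logged count).
    A variant with canonical annotations on two genes keeps both — it counts
    toward both genes downstream.
    """
    kept = []
    n_dropped = 0
    for v in variants:
        canon = [a for a in v.annotations if a.is_canonical]
        if not canon:
            n_dropped += 1
            continue
        kept.append(
            AnnotatedVariant(
                v.patient_id, v.chrom, v.pos, v.ref, v.alt,
                v.filter_status, v.total_depth, v.alt_reads, canon,
            )
        )
    if n_dropped:
        logger.info("select_canonical dropped %d variants with no canonical annotation",
                    n_dropped)
    return kept


# ---------------------------------------------------------------------------
# Matrix construction


def build_mutation_matrix(
    variants: Iterable[AnnotatedVariant],
    category: MutationCategory,
    patient_ids: Sequence[str],
    gene_symbols: Sequence[str],
    effect_table: Mapping[str, str] | None = None,
) -> MutationMatrix:
    """Binary patients x genes indicator: 1 iff the patient carries >= 1
    variant of the requested category in that gene.

    Patients supplied in `patient_ids` but absent from the variants are
    wild-type (all-zero rows).  Variants annotated to genes outside
    `gene_symbols` are skipped with a logged count.  Idempotent under
    duplicated input and invariant to input order.
    """
    category = MutationCategory(category)
    mat = pd.DataFrame(0, index=list(patient_ids), columns=list(gene_symbols), dtype="int8")
    gene_set = set(gene_symbols)
    patient_set = set(patient_ids)
    n_unknown_gene = 0
    n_unknown_patient = 0
    for v in variants:
        if v.patient_id not in patient_set:
            n_unknown_patient += 1
            continue
        for ann in v.annotations:
            if ann.gene_symbol not in gene_set:
                n_unknown_gene += 1
                continue
            cat = classify_variant(ann, v.ref, v.alt, effect_table=effect_table)
            if category.includes(cat):
                mat.at[v.patient_id, ann.gene_symbol] = 1
    if n_unknown_gene:
        logger.info("build_mutation_matrix: skipped %d annotations to genes outside the "
                    "supplied universe", n_unknown_gene)
    if n_unknown_patient:
        logger.info("build_mutation_matrix: skipped %d variants from patients outside the "
                    "supplied universe", n_unknown_patient)
    return MutationMatrix(indicator=mat, category=category)


def rank_mutation_frequency(
    matrix: MutationMatrix,
    exclude: Sequence[str] = ("TTN",),
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank genes by number of mutated patients, descending (ties broken
    lexicographically by symbol); `exclude` genes (default TTN, a frequent
    passenger) are removed before ranking."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts = matrix.indicator.sum(axis=0)
    counts = counts.drop(index=[g for g in exclude if g in counts.index])
    n = len(matrix.indicator)
    df = (
        pd.DataFrame({"gene": counts.index, "mutated_count": counts.values})
        .sort_values(["mutated_count", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    df["fraction"] = df["mutated_count"] / n if n else 0.0
    if top_k > len(df):
        logger.warning("top_k=%d exceeds %d available genes; returning all", top_k, len(df))
        return df
    return df.head(top_k).reset_index(drop=True)
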