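"""Synthetic cohort generation with known ground truth.

Real inputs to the screening funnel (tumor VCFs, RNA-seq counts, survival
tables, qPCR plates) come from controlled-access repositories; this module
emits statistically analogous cohorts whose ground truth is known, so every
pipeline stage can be tested end to end without downloads.

What is emulated
----------------
* **Mutations** — each driver gene mutates patients independently at a
  configured frequency (defaults 5–15%, mirroring common colorectal driver
  frequencies; an ``ACVR2A``-like driver sits at 7.7%).  A high-frequency
  passenger (``TTN``) exercises the exclusion rule in frequency ranking.
* **Counts** — negative-binomial reads per gene x patient with log-normal
  per-gene baseline means and a single shared dispersion
  (variance = m + dispersion * m^2); carriers of a linked driver have the
  target gene's mean multiplied by the planted fold change.
* **Survival** — exponential event times whose hazard is
  lambda0 * exp(sum coef_g * z_g), with z_g the per-patient z-score of the
  *noise-free* log expression mean of each planted hazardous gene (so planted
  hazard ratios are interpretable per SD); censoring is uniform on
  (0, followup_max) with lambda0 solved so the expected censored fraction
  matches the configured value.
* **Variant records** — a VCF per mutated patient: each carrier receives one
  disruptive variant rotating through the disruptive subtypes (premature
  stop, START/STOP loss, splice donor/acceptor, frameshift indels of length
  1/2/4), and background non-disruptive variants (missense, synonymous,
  splice-region, intronic, in-frame 3-nt indels) with depths and ALT read
  counts straddling the 40x/5 quality thresholds and a mix of PASS and
  non-PASS records.  A configurable fraction of planted variants is emitted
  failing QC; those carriers flip to wild-type in the *adjusted* truth, which
  is what the round-trip contract guarantees.

Everything is reproducible: one integer seed drives independent child
streams (carriers / expression / survival / variants / qPCR), so the carrier
draw is identical between :func:`generate_cohort` and
:func:`generate_variant_records` for the same (config, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .normalize import normalize_counts
from .variants import MutationCategory, MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_variant_records",
    "generate_qpcr_table",
]

# disruptive subtypes rotated across planted carriers: (effect term, ref, alt)
_DISRUPTIVE_ROTATION = (
    ("stop_gained", "C", "T"),
    ("start_lost", "A", "G"),
    ("stop_lost", "T", "C"),
    ("splice_donor_variant", "G", "A"),
    ("splice_acceptor_variant", "A", "C"),
    ("frameshift_variant", "A", "AT"),          # 1-nt insertion
    ("frameshift_variant", "ATG", "A"),         # 2-nt deletion
    ("frameshift_variant", "C", "CACGT"),       # 4-nt insertion
)

# background, never-disruptive variants: (terms, ref, alt)
_BACKGROUND_TYPES = (
    (("missense_variant",), "G", "T"),
    (("synonymous_variant",), "C", "A"),
    (("splice_region_variant", "intron_variant"), "T", "G"),
    (("intron_variant",), "A", "T"),
    (("conservative_inframe_deletion",), "GTCA", "G"),   # 3-nt in-frame deletion
    (("conservative_inframe_insertion",), "A", "AGGC"),  # 3-nt in-frame insertion
)


@dataclass
class SyntheticCohortConfig:
    """Cohort parameters; defaults mirror a 582-patient discovery cohort with
    ten drivers at 5–15% disruptive frequency and a 2,000-gene expression
    panel (desk-scale stand-in for a transcriptome)."""

    n_patients: int = 582
    n_genes: int = 2000
    driver_specs: tuple = (
        ("APC", 0.15), ("TP53", 0.12), ("SYNE1", 0.10), ("AMER1", 0.082),
        ("SOX9", 0.081), ("ACVR2A", 0.077), ("ANK3", 0.076), ("ARID1A", 0.07),
        ("FBXW7", 0.06), ("MDN1", 0.05),
    )
    passenger_specs: tuple = (("TTN", 0.20),)
    plant_specs: tuple = (
        ("ACVR2A", "TRIB2", 2.0), ("ACVR2A", "DUSP4", 2.2), ("SOX9", "BMP4", 1.8),
        ("ANK3", "VSIG4", 2.0), ("ANK3", "DUSP4", 1.7), ("AMER1", "DUSP4", 1.6),
        ("TP53", "PKM2", 1.8), ("APC", "TRIM7", 1.7), ("ARID1A", "IL1RN", 2.0),
    )
    hazard_specs: tuple = (
        ("TRIB2", 0.5), ("VSIG4", 0.4), ("BMP4", 0.35), ("DUSP4", 0.3),
    )
    baseline_mean_log: tuple = (4.0, 1.0)  # (mu, sigma) of per-gene ln mean counts
    nb_dispersion: float = 0.2
    censor_fraction: float = 0.7
    followup_max: float = 120.0  # months
    qc_fail_fraction: float = 0.05  # planted variants emitted failing QC
    background_rate: float = 2.0  # mean non-disruptive variants per patient
    endpoint: str = "RFS"
    seed: int = 0

    def __post_init__(self):
        for g, f in tuple(self.driver_specs) + tuple(self.passenger_specs):
            if not 0 < f < 1:
                raise ValueError(f"frequency for {g} must be in (0,1), got {f}")
        for d, t, fc in self.plant_specs:
            if fc <= 0:
                raise ValueError(f"fold change for ({d},{t}) must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        targets = {t for _, t, _ in self.plant_specs} | {g for g, _ in self.hazard_specs}
        if len(targets) > self.n_genes:
            raise ValueError("planted target genes exceed the gene universe")

    @property
    def mutation_genes(self) -> list:
        return [g for g, _ in self.driver_specs] + [g for g, _ in self.passenger_specs]

    @property
    def gene_symbols(self) -> list:
        named = sorted({t for _, t, _ in self.plant_specs}
                       | {g for g, _ in self.hazard_specs})
        n_bg = self.n_genes - len(named)
        return named + [f"GENE{i:05d}" for i in range(1, n_bg + 1)]

    @property
    def patient_ids(self) -> list:
        return [f"P{i:04d}" for i in range(1, self.n_patients + 1)]


@dataclass
class GroundTruth:
    """What was planted: carriers, expression plants, hazardous genes."""

    carriers: dict            # driver/passenger gene -> sorted patient id list
    plants: list              # (driver, target, fold_change)
    hazards: list             # (gene, log hazard per SD)
    achieved_censor_fraction: float = float("nan")
    qc_failed_carriers: dict = field(default_factory=dict)  # gene -> patient ids

    def adjusted_carriers(self) -> dict:
        """Carriers after removing those whose only planted variant fails QC."""
        out = {}
        for g, pats in self.carriers.items():
            failed = set(self.qc_failed_carriers.get(g, []))
            out[g] = sorted(set(pats) - failed)
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    mutation_matrix: MutationMatrix
    counts: pd.DataFrame          # genes x patients raw counts
    survival: pd.DataFrame        # patient_id, time_months, event, endpoint
    truth: GroundTruth
    config: SyntheticCohortConfig


def _streams(config: SyntheticCohortConfig, seed):
    base = np.random.SeedSequence(config.seed if seed is None else seed)
    return [np.random.default_rng(s) for s in base.spawn(5)]


def _draw_carriers(config: SyntheticCohortConfig, rng) -> pd.DataFrame:
    genes = config.mutation_genes
    freqs = np.array([f for _, f in tuple(config.driver_specs)
                      + tuple(config.passenger_specs)])
    draw = rng.random((config.n_patients, len(genes))) < freqs
    return pd.DataFrame(draw.astype("int8"), index=config.patient_ids, columns=genes)


def generate_cohort(config: SyntheticCohortConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Draw a complete cohort: mutations, counts, survival, ground truth."""
    config = config or SyntheticCohortConfig()
    c_rng, e_rng, s_rng, _, _ = _streams(config, seed)

    indicator = _draw_carriers(config, c_rng)

    genes = config.gene_symbols
    gene_idx = {g: i for i, g in enumerate(genes)}
    mu, sigma = config.baseline_mean_log
    base_mean = np.exp(e_rng.normal(mu, sigma, len(genes)))
    mean = np.repeat(base_mean[:, None], config.n_patients, axis=1)
    for driver, target, fc in config.plant_specs:
        if target not in gene_idx:
            raise ValueError(f"planted target {target} outside gene universe")
        carriers = indicator[driver].to_numpy(dtype=bool)
        mean[gene_idx[target], carriers] *= fc

    r = 1.0 / config.nb_dispersion
    counts = e_rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(counts, index=genes, columns=config.patient_ids)

    # survival: hazard on z-scored noise-free log expression means
    lp = np.zeros(config.n_patients)
    for gene, coef in config.hazard_specs:
        logm = np.log(mean[gene_idx[gene]])
        sd = logm.std()
        z = (logm - logm.mean()) / sd if sd > 0 else np.zeros_like(logm)
        lp += coef * z
    rel = np.exp(lp)
    T = config.followup_max

    def expected_censored(lam0):
        lam = lam0 * rel
        return float(np.mean((1 - np.exp(-lam * T)) / (lam * T)) - config.censor_fraction)

    if config.censor_fraction <= 0:
        lam0 = 10.0 / T
        warnings.warn("censor_fraction ~0 is only attainable in the limit; "
                      "using a high baseline hazard")
    else:
        lam0 = brentq(expected_censored, 1e-10, 1e4)
    lam = lam0 * rel
    event_time = s_rng.exponential(1.0 / lam)
    censor_time = s_rng.uniform(0, T, config.n_patients)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    achieved = 1.0 - event.mean()
    if abs(achieved - config.censor_fraction) > 0.1:
        warnings.warn(f"achieved censor fraction {achieved:.2f} differs from "
                      f"target {config.censor_fraction:.2f}")

    survival = pd.DataFrame({
        "patient_id": config.patient_ids,
        "time_months": np.maximum(observed, 1e-6),
        "event": event,
        "endpoint": config.endpoint,
    })

    truth = GroundTruth(
        carriers={g: sorted(indicator.index[indicator[g] == 1])
                  for g in indicator.columns},
        plants=[list(p) for p in config.plant_specs],
        hazards=[list(h) for h in config.hazard_specs],
        achieved_censor_fraction=float(achieved),
    )
    matrix = MutationMatrix(indicator=indicator, category=MutationCategory.DISRUPTIVE)
    return SyntheticCohort(mutation_matrix=matrix, counts=counts,
                           survival=survival, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Variant records (VCF)

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|Transcript_BioType|Rank|HGVS.c|HGVS.p|cDNA.pos/cDNA.length|CDS.pos/CDS.length|AA.pos/AA.length|Distance|ERRORS/WARNINGS/INFO'">
##FILTER=<ID=germline_risk,Description="Possible germline variant">
##FILTER=<ID=low_qual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _ann_field(alt, gene, terms, canonical, cds_len=900, extra_tx=None):
    entries = []
    tag = "CANONICAL" if canonical else ""
    entries.append(
        f"{alt}|{'&'.join(terms)}|HIGH|{gene}|{gene}|transcript|{gene}_T1|"
        f"protein_coding|1/9|c.100A>T|p.K34*|120/1200|90/{cds_len}|30/300|0|{tag}"
    )
    if extra_tx:
        xterms, xcds = extra_tx
        entries.append(
            f"{alt}|{'&'.join(xterms)}|HIGH|{gene}|{gene}|transcript|{gene}_T2|"
            f"protein_coding|1/7|c.50A>T|p.L17*|80/800|60/{xcds}|20/200|0|"
        )
    return ",".join(entries)


def _vcf_record(chrom, pos, ref, alt, filt, depth, alt_reads, ann):
    ref_reads = depth - alt_reads
    return (f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t"
            f"DP={depth};ANN={ann}\tGT:AD:DP\t0/1:{ref_reads},{alt_reads}:{depth}")


def generate_variant_records(config: SyntheticCohortConfig | None = None,
                             seed: int | None = None,
                             out_dir=None):
    """Emit annotated somatic variant records as per-patient VCF text.

    Returns ``(vcfs, truth)`` where `vcfs` maps patient id -> VCF text (only
    patients carrying at least one variant record appear; absent patients are
    wild-type) and `truth` is the :class:`GroundTruth` whose
    ``adjusted_carriers()`` accounts for planted variants deliberately
    emitted failing QC.  If `out_dir` is given, one ``<patient>.vcf`` file is
    written per patient.

    The carrier draw uses the same child random stream as
    :func:`generate_cohort`, so for identical (config, seed) the VCFs encode
    exactly the cohort's mutation ground truth.
    """
    config = config or SyntheticCohortConfig()
    c_rng, _, _, v_rng, _ = _streams(config, seed)
    indicator = _draw_carriers(config, c_rng)

    genes = config.mutation_genes
    gene_loc = {g: (str(i % 22 + 1), 1_000_000 * (i + 1)) for i, g in enumerate(genes)}

    per_patient: dict = {pid: [] for pid in config.patient_ids}
    qc_failed: dict = {g: [] for g in genes}
    rotation_i = 0
    for g in genes:
        chrom, base = gene_loc[g]
        for pid in indicator.index[indicator[g] == 1]:
            term, ref, alt = _DISRUPTIVE_ROTATION[rotation_i % len(_DISRUPTIVE_ROTATION)]
            pos = base + int(v_rng.integers(0, 10_000))
            fail = v_rng.random() < config.qc_fail_fraction
            if fail:
                mode = int(v_rng.integers(0, 3))
                if mode == 0:
                    filt, depth, alt_reads = "germline_risk", 80, 20
                elif mode == 1:
                    filt, depth, alt_reads = "PASS", 39, 10  # depth below 40
                else:
                    filt, depth, alt_reads = "PASS", 60, 4   # ALT reads below 5
                qc_failed[g].append(pid)
            else:
                filt = "PASS"
                depth = int(v_rng.integers(40, 120))
                alt_reads = int(v_rng.integers(5, max(6, depth // 2)))
            ann = _ann_field(alt, g, (term,), canonical=True)
            per_patient[pid].append(
                (int(chrom), pos, _vcf_record(chrom, pos, ref, alt, filt,
                                              depth, alt_reads, ann)))
            rotation_i += 1

    # background non-disruptive variants (never change carrier truth)
    for pid in config.patient_ids:
        for _ in range(v_rng.poisson(config.background_rate)):
            g = genes[int(v_rng.integers(0, len(genes)))]
            terms, ref, alt = _BACKGROUND_TYPES[int(v_rng.integers(0, len(_BACKGROUND_TYPES)))]
            chrom, base = gene_loc[g]
            pos = base + 20_000 + int(v_rng.integers(0, 10_000))
            filt = "PASS" if v_rng.random() < 0.8 else "low_qual"
            depth = int(v_rng.integers(30, 90))
            alt_reads = int(v_rng.integers(2, 12))
            alt_reads = min(alt_reads, depth)
            # sometimes add a non-canonical transcript annotation with a
            # scary disruptive term; canonical-isoform selection must drop it
            extra = (("stop_gained",), 600) if v_rng.random() < 0.1 else None
            ann = _ann_field(alt, g, terms, canonical=True, extra_tx=extra)
            per_patient[pid].append(
                (int(chrom), pos, _vcf_record(chrom, pos, ref, alt, filt,
                                              depth, alt_reads, ann)))

    contigs = "".join(f"##contig=<ID={c}>\n" for c in map(str, range(1, 23)))
    vcfs = {}
    for pid, recs in per_patient.items():
        if not recs:
            continue
        recs.sort()
        body = "\n".join(r for _, _, r in recs)
        vcfs[pid] = (_VCF_HEADER + contigs
                     + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{pid}\n"
                     + body + "\n")

    truth = GroundTruth(
        carriers={g: sorted(indicator.index[indicator[g] == 1]) for g in genes},
        plants=[list(p) for p in config.plant_specs],
        hazards=[list(h) for h in config.hazard_specs],
        qc_failed_carriers={g: sorted(v) for g, v in qc_failed.items() if v},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, text in vcfs.items():
            (out_dir / f"{pid}.vcf").write_text(text)
    return vcfs, truth


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr_table(cohort: SyntheticCohort, genes, noise_sd: float = 0.5,
                        seed: int | None = None) -> pd.DataFrame:
    """Emit a qPCR Ct table for `genes` from the cohort's expression.

    Ct(target) = 30 - log2(normalized expression + 1) + N(0, noise_sd);
    Ct(reference) = 18 + N(0, noise_sd).  The link between expression and
    2^-dCt is monotone in expectation.  Ct values are clipped into (0, 45].
    """
    rng = np.random.default_rng(cohort.config.seed if seed is None else seed)
    norm = normalize_counts(cohort.counts, poscounts=True).values
    rows = []
    for g in genes:
        if g not in norm.index:
            raise ValueError(f"gene {g} not in cohort expression")
        expr = norm.loc[g].to_numpy()
        ct_t = 30.0 - np.log2(expr + 1.0) + rng.normal(0, noise_sd, len(expr))
        ct_r = 18.0 + rng.normal(0, noise_sd, len(expr))
        rows.append(pd.DataFrame({
            "patient_id": norm.columns,
            "gene": g,
            "ct_target": np.clip(ct_t, 0.1, 45.0),
            "ct_reference": np.clip(ct_r, 0.1, 45.0),
        }))
    return pd.concat(rows, ignore_index=True)
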