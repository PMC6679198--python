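# Methods

This note documents the statistical procedures implemented in `mutscreen`,
the defaults and why they were chosen, the design decisions taken where the
methodology is genuinely open, and the limits of what the synthetic cohorts
can demonstrate.

## Variant classification

Input is one somatic VCF per patient with snpEff-style `ANN` annotations;
variant calling and annotation themselves are out of scope.  Records are
split per ALT allele; symbolic/non-ACGT alleles are dropped with a logged
count.

**Quality filter.** A call is kept when the caller FILTER is `PASS`, the
per-site total depth is ≥ `min_depth` (default 40) and the ALT-supporting
reads are ≥ `min_alt_reads` (default 5).  "Coverage" thresholds of this kind
are ambiguous in the field (per-site vs per-sample mean; ALT vs total reads);
both knobs are explicit parameters so either reading can be configured.

**Canonical isoform.** Only canonical-transcript annotations count.  The
`ANN` format carries no canonical flag, so the parser accepts a `CANONICAL`
token in the trailing Errors/Info subfield (what the synthetic writer emits);
when absent for a variant, the transcript with the longest CDS per gene is
taken as canonical, else the first listed — both fallbacks are logged.  A
variant with canonical annotations on two genes counts toward both.

**Categories.** Every effect term maps through an editable TSV
(`mutscreen/data/effect_terms.tsv`) to `disruptive`, `coding` or
`non_coding`; unknown terms fall back to `non_coding` with a one-time
warning, so classification is total.  *Disruptive* = START/STOP loss,
premature stop (`stop_gained`), splice donor/acceptor hit, or frameshift.
The frameshift rule is operationalized purely by indel length:
a coding indel is disruptive iff |len(alt) − len(ref)| mod 3 ≠ 0, regardless
of the annotated term (the length rule overrides annotation in both
directions, which makes the rule exhaustively checkable).  A
`splice_region_variant` alone is never disruptive.  Categories nest:
disruptive ⊂ coding ⊂ any; non-coding is disjoint from coding.

The mutation matrix is binary (patient carries ≥ 1 qualifying variant in the
gene); patients present in the expression cohort but absent from the VCFs
are explicitly wild-type.  Frequency ranking excludes a configurable
passenger list (default `TTN`), sorts by carrier count with lexicographic
tie-break.

## Normalization

Median-of-ratios size factors: the reference is the per-gene geometric mean
across samples over genes with no zero anywhere; each sample's factor is the
median of its count/reference ratios.  A `poscounts`-style fallback (per-gene
geometric mean over positive samples only) handles zero-heavy matrices.  No
dispersion modelling or variance stabilization is applied — the downstream
test is rank-based, so per-sample scaling suffices.  Note that
median-of-ratios output is invariant to per-sample rescaling of the raw
counts only up to the geometric mean of the applied scales (the reference
moves with the counts); between-sample structure is what is removed.

## Mutation-stratified screen

Per driver gene the cohort splits into disruptive-mutation carriers and
wild-type.  Each expressed gene is tested with a two-sided Mann–Whitney U
test on normalized expression:

* midrank U statistic, reported for the mutant group;
* exact null by complete enumeration of label assignments when the smaller
  group has < 8 observations and C(n, n₁) ≤ 25 000;
* otherwise a normal approximation with tie correction and continuity
  correction.  The cohort-scale path is vectorized (one ranking pass per
  expression matrix, shared across drivers) and agrees with the scalar test.

Fold change is the ratio of group means of linear-scale normalized values
with pseudocount 0.5 on both means (mean rather than median to match common
practice; the pseudocount guards against zero-mean genes; both
configurable).  Fold change is computed on the linear scale — whether to log
first is an open interpretation, and the rank test is unaffected either way.

A gene is *significantly upregulated* when raw p < α (default 0.01) **and**
FC ≥ 1.44 (boundary inclusive: a cutoff "at 1.44" is read as attained).
Benjamini–Hochberg q-values are computed per driver — each driver defines
its own family of ~n_genes tests — and are reported but do not gate by
default; `gate_on_q=True` gives the stricter reading.  Per driver the
selection is capped at the `top_k` (default 50) smallest p-values, ties
broken by larger FC then symbol; shorter lists are kept whole.  Drivers with
fewer than 3 carriers are skipped with a log entry.

## Survival analysis

**Cox fit.** Single-covariate Cox proportional hazards, maximizing the Efron
tie-corrected partial likelihood by Newton–Raphson with step halving
(tolerance 1e−8 on the coefficient, ≤ 50 iterations), Wald p-value.  The
implementation is vectorized over event times because the cutoff scan fits
hundreds of models per gene; it agrees with lifelines to ~1e−7 and with
direct maximization of the written-out partial likelihood on small no-tie
instances to 1e−6 (both asserted in tests).  Monotone likelihood (complete
separation of events) is detected by coefficient runaway; β is capped at
±15 and flagged.  Efron rather than Breslow because month-resolution
survival times produce moderate ties.

**Best-cutoff scan.** Candidate cutoffs are the observed expression values v
with Q1 ≤ v < Q3; the high group is expression *strictly greater* than v, so
both groups always hold at least a quarter of the cohort.  The cutoff with
the smallest test p wins (Cox Wald p by default; log-rank via flag —
smallest p rather than largest effect size, the standard convention for this
methodology); ties resolve to the cutoff closest to the median.  **No
correction is applied across scanned cutoffs**: the minimum-p selection is
anti-conservative, a property the test suite asserts rather than corrects,
and every result carries `n_cutoffs_scanned` so readers can judge the
inflation.  Outcome classes at α = 0.05 on the raw best p: `worse`
(HR > 1), `better` (HR < 1), `not_significant`.

Kaplan–Meier curves and the two-group log-rank test are delegated to
lifelines; the convention for degenerate inputs (no events anywhere,
identical groups) is statistic 0, p = 1.

## Actionability and qPCR validation

The druggability stage is a data-driven join against a user-supplied
drug–gene snapshot TSV (live interaction databases are versioned and
unstable; a frozen snapshot keeps runs reproducible).  Matching is by
upper-cased symbol; both druggable-category and interaction-claim rows
qualify; no alias resolution ships.

qPCR relative expression is `2^(−ΔCt)` with ΔCt = Ct(target) −
Ct(reference); technical replicates are averaged on the Ct scale before
ΔCt.  The median split assigns values equal to the median to the **low**
group (high = strictly greater).  The Youden cutoff maximizes
J = sensitivity + specificity − 1 over midpoints between consecutive sorted
unique values (a cutoff must actually split the cohort), ties to the
smallest threshold.  Group survival is compared by log-rank; a Mann–Whitney
comparison of expression between recurred and non-recurred patients is
provided as an alternative read-out, since either may be the appropriate
published summary for a given gene.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

* **Defaults**: 582 patients, ten drivers at 5–15% disruptive frequency
  (including a 7.7% ACVR2A-like driver), a 20% *TTN*-like passenger, 2 000
  expressed genes (a transcriptome stand-in), a 171-patient validation
  cohort for qPCR examples, ~70% censoring over a 120-month follow-up.
* **Counts**: negative binomial with per-gene log-normal baseline means
  (ln-mean 4, ln-sd 1 → typical means ~55 counts) and one shared dispersion
  0.2 (variance m + 0.2 m²); carriers of a linked driver get the target
  gene's mean multiplied by the planted fold change (defaults 1.6–2.2,
  the range where a 1.44 gate is discriminative).  A single shared
  dispersion is enough because the downstream test is rank-based.
* **Survival**: exponential times with hazard λ₀·exp(Σ coef·z), z the
  per-patient z-score of the *noise-free* log mean of each hazardous gene —
  so planted coefficients are log-HR per SD and interpretable.  λ₀ is solved
  numerically so uniform-(0, followup) censoring yields the configured
  censored fraction in expectation.  Consequence: a hazard coefficient on a
  gene whose only expression variation is a minority-carrier fold change
  concentrates risk in that minority, and quartile-bounded cutoff scans
  dilute it — visible in `examples/03`.
* **Variant records**: every disruptive subtype is exercised (premature
  stop, START/STOP loss, splice donor/acceptor, frameshift lengths 1/2/4),
  plus background missense/synonymous/splice-region/intronic/in-frame
  variants with depths and ALT counts straddling the 40×/5 thresholds and a
  PASS/non-PASS mix.  A configurable fraction (default 5%) of planted
  variants is emitted failing QC; the *adjusted* ground truth drops those
  carriers, and the round-trip contract (VCF → matrix equals adjusted truth,
  exactly, per seed) is the generator's central test.
* **Reproducibility**: one seed drives independent child streams (carriers /
  expression / survival / variants / qPCR), so the carrier draw is identical
  between the cohort and the VCF emitter and all outputs are byte-stable per
  seed.

**What passing tests do not show**: synthetic cohorts have independent
drivers (no co-mutation structure), no tumor purity or batch effects, no
linkage between mutation load and subtype (e.g. hypermutator phenotypes),
and a single expression value per gene (no probe/isoform ambiguity).
Calibration and recovery results demonstrate correctness of the machinery
under the stated model, not performance on real tumor data.

## Numerical choices and problem sizes

Convergence: Cox Newton–Raphson 1e−8 on β, ≤ 50 iterations, step halving on
likelihood decrease; size factors error out (with a `poscounts` hint) when
no gene is positive everywhere; degenerate markers (constant expression)
raise rather than return arbitrary splits; all-tied rank tests return p = 1.
Ties: lexicographic for ranking, (p asc, FC desc, symbol) for screen
selection, closest-to-median for cutoffs, smallest threshold for Youden.

Test-suite and acceptance-script simulations use desk-scale sizes chosen to
make the statistical assertions sharp but cheap: 100 000 gene-tests for
null calibration (3-SE band around 0.01), 200 replicates at n = 500 for Cox
coverage, 100 replicates at n = 300 for cutoff recovery, 20 seeds at
n = 582 for exact round-trip recovery.  All randomness flows from explicit
seeds; reruns are deterministic.
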