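"""Clinical qPCR validation of candidate genes.

A candidate that survives the discovery funnel is re-measured in an
independent clinical cohort by quantitative RT-PCR.  Relative expression is
computed against a reference gene (beta-actin in the motivating design) as

    relative expression = 2^(-dCt),   dCt = Ct(target) - Ct(reference),

so lower target Ct (earlier amplification) means higher expression.  The
cohort is then dichotomized at the median relative expression (values equal
to the median go to the LOW group; high = strictly greater) or at the
Youden-index cutoff against a binary outcome, and recurrence-free survival is
compared between groups with a log-rank test.

Technical replicate Ct values for the same patient/gene are averaged before
dCt.  A Mann–Whitney comparison of expression between recurred and
non-recurred patients is provided as an alternative read-out
(:func:`compare_recurrence_groups`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import mann_whitney_test
from .survival import kaplan_meier, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationResult",
    "relative_expression",
    "median_cutoff",
    "youden_cutoff",
    "validate_gene",
    "compare_recurrence_groups",
]


@dataclass
class ValidationResult:
    gene: str
    cutoff_mode: str
    cutoff: float
    n_high: int
    n_low: int
    logrank_chi2: float
    p_value: float
    km_high: tuple  # (timeline, survival)
    km_low: tuple
    low_power_flag: bool = False


def relative_expression(ct_target, ct_reference):
    """2^-(Ct_target - Ct_reference); vectorized over array inputs."""
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    out = np.power(2.0, -(ct_t - ct_r))
    if out.ndim == 0:
        return float(out)
    return out


def median_cutoff(values) -> float:
    """Sample median (midpoint of the middle pair for even n).

    The value equal to the median belongs to the LOW group downstream
    (high = strictly greater).  Raises on a degenerate (constant) marker.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("degenerate marker: all values equal, no split possible")
    return float(np.median(v))


def youden_cutoff(values, binary_outcome):
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; a case is called positive when its value is strictly greater
    than the threshold.  Ties on J resolve to the smallest threshold.
    Returns ``(cutoff, J)``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(binary_outcome, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and outcome must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("degenerate marker: all values equal")
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    best = None
    for thr in thresholds:
        call = v > thr
        sens = (call & (y == 1)).sum() / n_pos
        spec = (~call & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (float(thr), float(j))
    return best


def _per_patient_expression(qpcr: pd.DataFrame, target_gene: str | None) -> pd.Series:
    df = qpcr
    if target_gene is not None:
        df = df[df["gene"] == target_gene]
        if df.empty:
            raise ValueError(f"no qPCR records for gene {target_gene!r}")
    elif df["gene"].nunique() > 1:
        raise ValueError("qPCR table holds multiple genes; pass target_gene")
    # technical replicates: average Ct before dCt
    agg = df.groupby("patient_id")[["ct_target", "ct_reference"]].mean()
    finite = np.isfinite(agg["ct_target"]) & np.isfinite(agg["ct_reference"])
    if (~finite).any():
        logger.warning("dropping %d patients with non-finite Ct", int((~finite).sum()))
        agg = agg[finite]
    return pd.Series(
        relative_expression(agg["ct_target"].to_numpy(), agg["ct_reference"].to_numpy()),
        index=agg.index, name="relative_expression",
    )


def validate_gene(qpcr_records: pd.DataFrame, survival_records: pd.DataFrame,
                  cutoff_mode: str = "median", target_gene: str | None = None,
                  min_group: int = 3) -> ValidationResult:
    """Dichotomize qPCR relative expression and compare survival.

    `qpcr_records` needs columns ``patient_id``, ``gene``, ``ct_target``,
    ``ct_reference``; `survival_records` needs ``patient_id``,
    ``time_months``, ``event``.  ``cutoff_mode`` is ``"median"`` or
    ``"youden"`` (Youden uses the event indicator as the binary outcome).
    Groups smaller than `min_group` flag the result as low-power.
    """
    if cutoff_mode not in ("median", "youden"):
        raise ValueError("cutoff_mode must be 'median' or 'youden'")
    expr = _per_patient_expression(qpcr_records, target_gene)
    surv = survival_records.set_index("patient_id")
    common = [p for p in expr.index if p in surv.index]
    if not common:
        raise ValueError("no shared patients between qPCR and survival tables")
    expr = expr.loc[common]
    times = surv.loc[common, "time_months"].to_numpy(dtype=float)
    events = surv.loc[common, "event"].to_numpy(dtype=int)

    if cutoff_mode == "median":
        cut = median_cutoff(expr.to_numpy())
    else:
        cut, _ = youden_cutoff(expr.to_numpy(), events)
    high = expr.to_numpy() > cut

    n_high, n_low = int(high.sum()), int((~high).sum())
    low_power = min(n_high, n_low) < min_group
    if low_power:
        logger.warning("validation group sizes %d/%d below %d; low power",
                       n_high, n_low, min_group)
    chi2, p = logrank_test(times[high], events[high], times[~high], events[~high])
    gene_name = target_gene or qpcr_records["gene"].iloc[0]
    return ValidationResult(
        gene=gene_name, cutoff_mode=cutoff_mode, cutoff=float(cut),
        n_high=n_high, n_low=n_low, logrank_chi2=chi2, p_value=p,
        km_high=kaplan_meier(times[high], events[high]),
        km_low=kaplan_meier(times[~high], events[~high]),
        low_power_flag=low_power,
    )


def compare_recurrence_groups(qpcr_records: pd.DataFrame,
                              survival_records: pd.DataFrame,
                              target_gene: str | None = None):
    """Mann–Whitney comparison of relative expression between patients with
    and without an observed event (recurrence); returns (U, p)."""
    expr = _per_patient_expression(qpcr_records, target_gene)
    surv = survival_records.set_index("patient_id")
    common = [p for p in expr.index if p in surv.index]
    events = surv.loc[common, "event"].to_numpy(dtype=int)
    values = expr.loc[common].to_numpy()
    if len(np.unique(events)) < 2:
        raise ValueError("both recurrence classes must be present")
    return mann_whitney_test(values[events == 1], values[events == 0])
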