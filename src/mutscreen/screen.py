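"""Mutation-stratified differential-expression screen.

For each selected driver gene the cohort is split into carriers of a
disruptive mutation and wild-type patients.  Every expressed gene is then
compared between the two groups with a two-sided Mann–Whitney U test on
normalized expression, with a linear-scale fold-change gate.  A gene is
called significantly upregulated under a driver when

    p < alpha  (default 0.01)   and   FC >= fc_cutoff  (default 1.44),

where FC = (mean mutant + pseudocount) / (mean wild-type + pseudocount).
Benjamini–Hochberg q-values are computed per driver (each driver defines its
own test family) and reported alongside; by default they do not gate the call
(``gate_on_q=True`` gives the stricter reading).  Per driver, the selection is
capped at the `top_k` (default 50) smallest p-values — ties broken by larger
fold change, then gene symbol — and the whole list is kept when fewer genes
pass.

The scalar :func:`mann_whitney_test` uses midranks with exact enumeration for
small groups and a tie- and continuity-corrected normal approximation
otherwise; :func:`run_screen` uses an equivalent vectorized asymptotic path
(one ranking pass per gene matrix) for cohort-scale speed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix
from .variants import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "ScreenResult",
    "split_cohort",
    "mann_whitney_test",
    "fold_change",
    "bh_adjust",
    "run_screen",
]

_EXACT_MAX_COMB = 25_000  # exact enumeration budget (covers totals <= 16)


@dataclass
class ScreenParams:
    """Tuning knobs of the screen (defaults = the published thresholds)."""

    alpha: float = 0.01
    fc_cutoff: float = 1.44
    top_k: int = 50
    pseudocount: float = 0.5
    direction: str = "up"  # {"up", "down", "both"}
    min_group: int = 3
    gate_on_q: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be one of up/down/both")


@dataclass
class ScreenResult:
    """All per-(driver, gene) records plus the capped per-driver selections."""

    records: pd.DataFrame
    selected: dict = field(default_factory=dict)  # driver -> ordered gene list
    skipped_drivers: dict = field(default_factory=dict)  # driver -> reason


def split_cohort(matrix: MutationMatrix, driver_gene: str):
    """Partition patients into (mutant carriers, wild-type), order-stable."""
    if driver_gene not in matrix.indicator.columns:
        raise KeyError(
            f"driver {driver_gene!r} not in mutation matrix; available: "
            f"{sorted(matrix.indicator.columns)}"
        )
    col = matrix.indicator[driver_gene]
    mut = list(col.index[col == 1])
    wt = list(col.index[col == 0])
    return mut, wt


def _tie_term_rows(values: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tie groups, per row of `values`."""
    s = np.sort(values, axis=1)
    nrow, n = s.shape
    change = np.ones_like(s, dtype=bool)
    change[:, 1:] = s[:, 1:] != s[:, :-1]
    idx = np.flatnonzero(change.ravel())
    t = np.diff(np.append(idx, nrow * n)).astype(float)
    return np.bincount(idx // n, weights=t**3 - t, minlength=nrow)


def _asymptotic_p(u1: np.ndarray, n1: int, n2: int, tie_term: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation p with tie and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones_like(np.asarray(u1, dtype=float))
    ok = var > 0
    z = np.zeros_like(p)
    dev = np.abs(np.asarray(u1, dtype=float) - mu)
    z[ok] = np.maximum(dev[ok] - 0.5, 0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(2 * stats.norm.sf(z[ok]), 1.0)
    return p


def mann_whitney_test(x: Sequence[float], y: Sequence[float],
                      exact: bool | None = None):
    """Two-sided Mann–Whitney U test; returns (U for the first group, p).

    U is computed from midrank sums.  The null distribution is enumerated
    exactly (all C(n1+n2, n1) labelings of the pooled midranks) when the
    smaller group has < 8 observations and the enumeration is affordable;
    otherwise a tie-corrected normal approximation with continuity correction
    is used.  If both samples are one identical constant, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if exact is None:
        exact = min(n1, n2) < 8 and comb(n1 + n2, n1) <= _EXACT_MAX_COMB
    elif exact and comb(n1 + n2, n1) > _EXACT_MAX_COMB:
        logger.warning("exact Mann–Whitney enumeration too large; using approximation")
        exact = False

    if np.ptp(pooled) == 0:
        return float(u1), 1.0

    if exact:
        mu = n1 * n2 / 2.0
        obs_dev = abs(u1 - mu)
        offset = n1 * (n1 + 1) / 2.0
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        return float(u1), count / total

    tie = _tie_term_rows(pooled[None, :])
    p = _asymptotic_p(np.array([u1]), n1, n2, tie)[0]
    return float(u1), float(p)


def fold_change(mutant_values: Sequence[float], wt_values: Sequence[float],
                pseudocount: float = 0.5) -> float:
    """(mean mutant + pc) / (mean wild-type + pc) on the linear scale."""
    m = float(np.mean(mutant_values)) + pseudocount
    w = float(np.mean(wt_values)) + pseudocount
    if m == 0 and w == 0:
        logger.warning("both group means zero with pseudocount 0; FC = 1 convention")
        return 1.0
    return m / w


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values), capped at 1.

    NaN inputs propagate as NaN (with a warning); the family size is the
    number of non-NaN p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    mask = np.isnan(p)
    if mask.any():
        warnings.warn("NaN p-values propagated through BH adjustment")
    out = np.full(p.shape, np.nan)
    valid = p[~mask]
    if valid.size:
        if ((valid < 0) | (valid > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[~mask] = multipletests(valid, method="fdr_bh")[1]
    return out


def _screen_one_driver(values: np.ndarray, mut_mask: np.ndarray,
                       params: ScreenParams, ranks=None, tie=None) -> tuple:
    """Vectorized U/p/FC for every gene (row of `values`) for one driver.

    `ranks` and `tie` are per-gene midranks and tie terms, precomputable once
    per expression matrix and shared across drivers.
    """
    n1 = int(mut_mask.sum())
    n2 = values.shape[1] - n1
    if min(n1, n2) < 8:
        # small-group path: scalar test per gene (exact where affordable)
        u = np.empty(values.shape[0])
        p = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            u[i], p[i] = mann_whitney_test(values[i, mut_mask], values[i, ~mut_mask])
    else:
        if ranks is None:
            ranks = stats.rankdata(values, axis=1)
        if tie is None:
            tie = _tie_term_rows(values)
        r1 = ranks[:, mut_mask].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        p = _asymptotic_p(u, n1, n2, tie)
    mut_mean = values[:, mut_mask].mean(axis=1)
    wt_mean = values[:, ~mut_mask].mean(axis=1)
    fc = (mut_mean + params.pseudocount) / (wt_mean + params.pseudocount)
    return u, p, fc, n1, n2


def run_screen(
    normalized: NormalizedMatrix | pd.DataFrame,
    matrix: MutationMatrix,
    driver_genes: Iterable[str],
    params: ScreenParams | None = None,
) -> ScreenResult:
    """Run the full screen for each driver gene.

    Returns a :class:`ScreenResult` whose ``records`` frame holds one row per
    (driver, expressed gene) with U, p, per-driver BH q, fold change,
    direction and the selected flag, and whose ``selected`` dict maps each
    driver to its capped, ordered significant-upregulated gene list.

    Drivers with fewer than ``params.min_group`` carriers (or wild-types) are
    skipped with a log entry.
    """
    params = params or ScreenParams()
    expr = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    driver_genes = list(driver_genes)
    if not driver_genes:
        raise ValueError("driver_genes must be non-empty")

    common = [p for p in matrix.indicator.index if p in set(expr.columns)]
    if len(common) < len(matrix.indicator.index) or len(common) < expr.shape[1]:
        logger.info("screen: %d patients shared between mutation matrix (%d) and "
                    "expression (%d)", len(common), len(matrix.indicator.index),
                    expr.shape[1])
    if not common:
        raise ValueError("no shared patients between mutation matrix and expression")
    expr = expr[common]
    values = expr.to_numpy(dtype=float)
    genes = np.asarray(expr.index)

    ranks = stats.rankdata(values, axis=1)
    tie = _tie_term_rows(values)

    frames = []
    selected: dict = {}
    skipped: dict = {}
    for driver in driver_genes:
        mut_ids, _ = split_cohort(matrix, driver)
        mut_mask = np.asarray([pid in set(mut_ids) for pid in common])
        n1 = int(mut_mask.sum())
        n2 = len(common) - n1
        if min(n1, n2) < params.min_group:
            logger.warning("driver %s skipped: group sizes %d/%d below min_group=%d",
                           driver, n1, n2, params.min_group)
            skipped[driver] = f"group sizes {n1}/{n2} below min_group={params.min_group}"
            selected[driver] = []
            continue
        u, p, fc, n1, n2 = _screen_one_driver(values, mut_mask, params,
                                              ranks=ranks, tie=tie)
        q = bh_adjust(p)
        direction = np.where(fc > 1, "up", "down")
        df = pd.DataFrame({
            "driver_gene": driver,
            "expressed_gene": genes,
            "n_mut": n1,
            "n_wt": n2,
            "u_statistic": u,
            "p_value": p,
            "q_value": q,
            "fold_change": fc,
            "direction": direction,
        })
        gate_p = df["q_value"] if params.gate_on_q else df["p_value"]
        sig = gate_p < params.alpha
        if params.direction == "up":
            sig &= df["fold_change"] >= params.fc_cutoff
        elif params.direction == "down":
            sig &= df["fold_change"] <= 1.0 / params.fc_cutoff
        else:
            sig &= (df["fold_change"] >= params.fc_cutoff) | (
                df["fold_change"] <= 1.0 / params.fc_cutoff)
        df["significant"] = sig
        ranked = df[sig].sort_values(
            ["p_value", "fold_change", "expressed_gene"],
            ascending=[True, False, True], kind="mergesort",
        )
        pick = list(ranked["expressed_gene"].head(params.top_k))
        selected[driver] = pick
        df["selected"] = df["expressed_gene"].isin(set(pick)) & sig
        frames.append(df)

    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=[
                   "driver_gene", "expressed_gene", "n_mut", "n_wt", "u_statistic",
                   "p_value", "q_value", "fold_change", "direction", "significant",
                   "selected"]))
    return ScreenResult(records=records, selected=selected, skipped_drivers=skipped)
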