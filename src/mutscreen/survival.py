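"""Best-cutoff survival analysis for candidate genes.

The screening funnel asks, for each candidate overexpressed gene, whether
high expression carries prognostic information.  Rather than fixing the
median split, the *auto-select best cutoff* methodology scans every observed
expression value between the first and third quartiles, dichotomizes the
cohort at each (high = expression strictly greater than the cutoff), fits a
univariate Cox proportional-hazards model (or a log-rank test), and keeps the
cutoff with the smallest p-value.  Genes are then classified as
``worse`` (HR > 1, p < alpha), ``better`` (HR < 1, p < alpha) or
``not_significant``.

No multiplicity correction is applied across the scanned cutoffs — the
minimum-p selection is anti-conservative by construction, which is an
accepted property of this methodology; ``n_cutoffs_scanned`` is surfaced in
every result so readers can judge the inflation.

The Cox fit is a single-covariate Newton–Raphson maximization of the partial
likelihood with Efron tie handling, vectorized over event times so that
scanning hundreds of cutoffs per gene stays cheap.  Kaplan–Meier curves and
the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "CutoffScanResult",
    "CoxConvergenceError",
    "kaplan_meier",
    "logrank_test",
    "cox_fit_binary",
    "best_cutoff_scan",
    "classify_outcome_association",
]

_BETA_CAP = 15.0  # |beta| beyond this signals monotone likelihood


class CoxConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message, trace):
        super().__init__(f"{message}; trace (beta per iteration): {trace}")
        self.trace = trace


@dataclass
class CoxFit:
    beta: float
    se: float
    hazard_ratio: float
    p_value: float
    n_iter: int
    converged: bool
    monotone_flag: bool = False


@dataclass
class CutoffScanResult:
    """Best expression threshold for one gene with its survival association."""

    gene: str
    best_cutoff: float
    hazard_ratio: float
    beta: float
    p_value: float
    n_high: int
    n_low: int
    n_cutoffs_scanned: int
    outcome_class: str = "not_significant"


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank (lifelines-backed)


def kaplan_meier(times, events):
    """Product-limit survival estimate.

    Returns ``(timeline, survival)`` arrays; the step function is
    right-continuous, starts at S(0) = 1 and is non-increasing.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("all times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns (chi-square statistic, p).

    Convention: if neither group has any event, the statistic is 0 and p = 1.
    """
    from lifelines.statistics import logrank_test as _lr

    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(np.asarray(times_a)) == 0 or len(np.asarray(times_b)) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return 0.0, 1.0
    res = _lr(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (single covariate, Efron ties)


class _CoxData:
    """Pre-sorted arrays shared across Newton iterations and scan cutoffs."""

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        if times.shape != events.shape:
            raise ValueError("times and events must align")
        order = np.argsort(times, kind="mergesort")
        self.order = order
        self.t = times[order]
        self.d = events[order]
        self.n = len(self.t)
        if not self.d.any():
            raise ValueError("at least one event is required")
        ut = np.unique(self.t[self.d])
        self.risk_start = np.searchsorted(self.t, ut, side="left")
        gidx = np.searchsorted(ut, self.t[self.d])
        self.dj = np.bincount(gidx, minlength=len(ut))
        self.gidx = gidx
        m = int(self.d.sum())
        # per-event (j, l) expansion for the Efron correction
        self.rep = np.repeat(np.arange(len(ut)), self.dj)
        l_all = np.arange(m) - np.repeat(np.cumsum(self.dj) - self.dj, self.dj)
        self.frac = l_all / np.repeat(self.dj, self.dj)

    def derivs(self, beta, x):
        """(loglik, score, information) at `beta` for sorted covariate `x`."""
        w = np.exp(beta * x)
        xw = x * w
        x2w = x * xw

        def suffix(a):
            return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])

        Sw, Sxw, Sx2w = suffix(w), suffix(xw), suffix(x2w)
        rw = Sw[self.risk_start][self.rep]
        rxw = Sxw[self.risk_start][self.rep]
        rx2w = Sx2w[self.risk_start][self.rep]

        dw = np.bincount(self.gidx, weights=w[self.d], minlength=len(self.dj))[self.rep]
        dxw = np.bincount(self.gidx, weights=xw[self.d], minlength=len(self.dj))[self.rep]
        dx2w = np.bincount(self.gidx, weights=x2w[self.d], minlength=len(self.dj))[self.rep]

        denom = rw - self.frac * dw
        a = rxw - self.frac * dxw
        b = rx2w - self.frac * dx2w

        xsum = x[self.d].sum()
        loglik = beta * xsum - np.log(denom).sum()
        score = xsum - (a / denom).sum()
        info = (b / denom - (a / denom) ** 2).sum()
        return loglik, score, info


def cox_fit_binary(times, events, group_indicator, tol: float = 1e-8,
                   max_iter: int = 50) -> CoxFit:
    """Univariate Cox proportional-hazards fit for a single covariate.

    Maximizes the Efron-tie partial likelihood by Newton–Raphson with step
    halving (convergence: |delta beta| < `tol` on the coefficient, at most
    `max_iter` iterations).  Returns the coefficient, its standard error,
    hazard ratio ``exp(beta)`` and the Wald p-value.

    Although named for the binary high/low-expression use, any real-valued
    single covariate is accepted.  Monotone likelihood (complete separation
    of events) is detected when |beta| runs away; the coefficient is capped
    at +/-15 and flagged.
    """
    x = np.asarray(group_indicator, dtype=float)
    data = _CoxData(times, events)
    xs = x[data.order]
    if np.ptp(xs) == 0:
        raise ValueError("covariate is constant; both levels must be present")

    beta = 0.0
    trace = []
    ll, score, info = data.derivs(beta, xs)
    monotone = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            monotone = True
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = data.derivs(new_beta, xs)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = data.derivs(new_beta, xs)
            halvings += 1
        trace.append(new_beta)
        delta = abs(new_beta - beta)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > _BETA_CAP:
            monotone = True
            break
        if delta < tol:
            converged = True
            break

    if monotone or abs(beta) > _BETA_CAP:
        logger.warning("monotone partial likelihood; capping |beta| at %.1f", _BETA_CAP)
        beta = float(np.sign(beta) or 1.0) * _BETA_CAP
        _, _, info = data.derivs(beta, xs)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return CoxFit(beta, se, float(np.exp(beta)),
                      2 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) else 1.0,
                      it, False, monotone_flag=True)
    if not converged:
        raise CoxConvergenceError(
            f"Cox Newton–Raphson did not converge in {max_iter} iterations", trace)
    se = 1.0 / np.sqrt(info)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return CoxFit(float(beta), float(se), float(np.exp(beta)), float(p),
                  it, True)


# ---------------------------------------------------------------------------
# Best-cutoff scan


def best_cutoff_scan(expression, survival: pd.DataFrame, statistic: str = "cox",
                     alpha: float = 0.05, gene: str = "") -> CutoffScanResult:
    """Scan all expression cutoffs between the quartiles; keep the best.

    Parameters
    ----------
    expression
        Per-patient expression, a :class:`pandas.Series` indexed by patient id
        (or an array aligned with `survival`).
    survival
        Frame with columns ``patient_id``, ``time_months``, ``event``.
    statistic
        ``"cox"`` (Wald p of the univariate fit; default) or ``"logrank"``.

    Candidate cutoffs are the observed expression values v with
    Q1 <= v < Q3; patients with expression strictly greater than v form the
    high group, so both groups always hold at least a quarter of the cohort.
    The cutoff with the smallest p-value wins; ties go to the cutoff closest
    to the median.  The number of cutoffs scanned is recorded — the minimum-p
    selection is anti-conservative and readers need that context.
    """
    if statistic not in ("cox", "logrank"):
        raise ValueError("statistic must be 'cox' or 'logrank'")
    surv = survival.set_index("patient_id") if "patient_id" in survival.columns else survival
    if isinstance(expression, pd.Series):
        common = [p for p in surv.index if p in expression.index]
        if len(common) < 8:
            raise ValueError("need >= 8 patients with both expression and survival")
        expr = expression.loc[common].to_numpy(dtype=float)
        times = surv.loc[common, "time_months"].to_numpy(dtype=float)
        events = surv.loc[common, "event"].to_numpy(dtype=int)
    else:
        expr = np.asarray(expression, dtype=float)
        times = surv["time_months"].to_numpy(dtype=float)
        events = surv["event"].to_numpy(dtype=int)
        if len(expr) != len(times):
            raise ValueError("expression and survival must align")
        if len(expr) < 8:
            raise ValueError("need >= 8 patients")

    if np.ptp(expr) == 0:
        raise ValueError("all expression values identical; no valid cutoff")
    q1, q3 = np.quantile(expr, [0.25, 0.75])
    med = float(np.median(expr))
    candidates = np.unique(expr[(expr >= q1) & (expr < q3)])
    if candidates.size == 0:
        raise ValueError("no observed expression value in [Q1, Q3); degenerate marker")

    cox_data = _CoxData(times, events) if statistic == "cox" else None
    best = None  # (p, dist_to_median, cutoff, beta, hr, n_high)
    for v in candidates:
        high = expr > v
        if statistic == "cox":
            xs = high[cox_data.order].astype(float)
            try:
                fit = _newton_quick(cox_data, xs)
            except ValueError:
                continue
            p, beta, hr = fit
        else:
            chi2, p = logrank_test(times[high], events[high],
                                   times[~high], events[~high])
            try:
                f = cox_fit_binary(times, events, high.astype(float))
                beta, hr = f.beta, f.hazard_ratio
            except (ValueError, CoxConvergenceError):
                beta, hr = np.nan, np.nan
        key = (p, abs(v - med), v)
        if best is None or key < best[0]:
            best = (key, float(v), beta, hr, int(high.sum()))
    if best is None:
        raise ValueError("no cutoff yielded a valid fit")
    key, cutoff, beta, hr, n_high = best
    res = CutoffScanResult(
        gene=gene, best_cutoff=cutoff, hazard_ratio=float(hr), beta=float(beta),
        p_value=float(key[0]), n_high=n_high, n_low=len(expr) - n_high,
        n_cutoffs_scanned=int(candidates.size),
    )
    res.outcome_class = classify_outcome_association(res, alpha=alpha)
    return res


def _newton_quick(data: _CoxData, xs: np.ndarray):
    """Lean Newton loop for the scan (sorted covariate given); returns
    (wald p, beta, HR)."""
    if np.ptp(xs) == 0:
        raise ValueError("constant covariate")
    beta = 0.0
    ll, score, info = data.derivs(beta, xs)
    for _ in range(50):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = data.derivs(new_beta, xs)
        h = 0
        while new_ll < ll - 1e-12 and h < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = data.derivs(new_beta, xs)
            h += 1
        delta = abs(new_beta - beta)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > _BETA_CAP or delta < 1e-8:
            break
    beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
    if info <= 0:
        return 1.0, beta, float(np.exp(beta))
    se = 1.0 / np.sqrt(info)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return float(p), beta, float(np.exp(beta))


def classify_outcome_association(result: CutoffScanResult, alpha: float = 0.05) -> str:
    """``worse`` iff p < alpha and HR > 1; ``better`` iff p < alpha and
    HR < 1; otherwise ``not_significant``."""
    if result.p_value < alpha and result.hazard_ratio > 1:
        return "worse"
    if result.p_value < alpha and result.hazard_ratio < 1:
        return "better"
    return "not_significant"
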