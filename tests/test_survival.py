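"""Kaplan–Meier, log-rank, Cox partial likelihood, best-cutoff scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from mutscreen import (
    CutoffScanResult, best_cutoff_scan, classify_outcome_association,
    cox_fit_binary, kaplan_meier, logrank_test,
)


def partial_loglik_no_ties(beta, times, events, x):
    """Partial likelihood written out directly from its definition (oracle;
    valid when event times are distinct)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_max_beta(times, events, x):
    res = minimize_scalar(
        lambda b: -partial_loglik_no_ties(b, times, events, x),
        bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-9})
    return res.x


def surv_frame(times, events):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(times))],
        "time_months": times, "event": events,
    })


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        t, s = kaplan_meier([1, 2, 3], [1, 1, 1])
        lookup = dict(zip(t, s))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        _, s = kaplan_meier([5, 8, 12], [0, 0, 0])
        np.testing.assert_allclose(s, 1.0)

    def test_mixed_fixture_hand_table(self):
        # subjects: event t=2, censored t=3, event t=5, event t=5, censored t=7
        # S(2) = 4/5; S(5) = 4/5 * (1 - 2/3) = 4/15
        t, s = kaplan_meier([2, 3, 5, 5, 7], [1, 0, 1, 1, 0])
        lookup = dict(zip(t, s))
        assert lookup[2.0] == pytest.approx(4 / 5)
        assert lookup[5.0] == pytest.approx(4 / 15)
        assert lookup[7.0] == pytest.approx(4 / 15)

    def test_bounds_and_monotone(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        _, s = kaplan_meier(t, e)
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 20), rng.exponential(10, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        s1 = logrank_test(ta, ea, tb, eb)
        s2 = logrank_test(tb, eb, ta, ea)
        assert s1[0] == pytest.approx(s2[0])

    def test_no_events_convention(self):
        assert logrank_test([1, 2], [0, 0], [3, 4], [0, 0]) == (0.0, 1.0)

    def test_separated_groups_vs_permutation_null(self):
        """Early-event vs late-censored groups: small p, agreeing with a
        label-permutation null of the same statistic."""
        ta = np.arange(1.0, 11.0)           # all events, early
        ea = np.ones(10, dtype=int)
        tb = np.arange(50.0, 60.0)          # all events, late
        eb = np.ones(10, dtype=int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        assert p < 0.01
        rng = np.random.default_rng(7)
        t = np.concatenate([ta, tb])
        e = np.concatenate([ea, eb])
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            lab = rng.permutation(20) < 10
            c, _ = logrank_test(t[lab], e[lab], t[~lab], e[~lab])
            hits += c >= chi2
        assert hits / n_perm < 0.01


class TestCoxFit:
    def test_matches_brute_force_likelihood_small(self):
        """On tiny no-ties instances the Newton beta matches direct
        maximization of the written-out partial likelihood to 1e-6."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            times = rng.permutation(np.arange(1.0, n + 1))  # distinct
            events = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n).astype(float)
            if events.sum() == 0 or np.ptp(x) == 0:
                continue
            if np.ptp(x[events == 1]) == 0 and (x[events == 0] == x[events == 1][0]).all():
                continue
            try:
                fit = cox_fit_binary(times, events, x)
            except Exception:
                continue
            if fit.monotone_flag:
                continue
            assert fit.beta == pytest.approx(grid_max_beta(times, events, x),
                                             abs=1e-6)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 150
        x = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(12 / np.exp(0.6 * x)))  # month ties
        e = (rng.random(n) < 0.75).astype(int)
        fit = cox_fit_binary(t, e, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)
        assert fit.hazard_ratio == pytest.approx(np.exp(fit.beta))

    def test_null_simulation_calibrated(self):
        """Covariate independent of hazard: Wald p roughly uniform."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            n = 100
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(10, n)
            e = (rng.random(n) < 0.8).astype(int)
            pvals.append(cox_fit_binary(t, e, x).p_value)
        # KS against uniform; generous threshold for 200 reps
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert abs(np.mean(np.array(pvals) < 0.05) - 0.05) < 0.05

    def test_monotone_likelihood_flagged(self):
        """All events in one group before any in the other: separation."""
        times = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        events = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = cox_fit_binary(times, events, x)
        assert fit.monotone_flag
        assert abs(fit.beta) == pytest.approx(15.0)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant|levels"):
            cox_fit_binary([1, 2, 3], [1, 1, 0], [1, 1, 1])


class TestBestCutoffScan:
    def test_ordered_toy_worse_outcome(self):
        n = 24
        expr = pd.Series(np.arange(n, dtype=float),
                         index=[f"P{i}" for i in range(n)])
        # higher expression => earlier event
        times = np.linspace(30, 1, n)
        events = np.ones(n, dtype=int)
        res = best_cutoff_scan(expr, surv_frame(times, events), gene="G")
        assert res.hazard_ratio > 1
        assert res.n_high + res.n_low == n
        # complete separation makes the Cox Wald p unreliable; the log-rank
        # statistic calls the association cleanly
        res_lr = best_cutoff_scan(expr, surv_frame(times, events), gene="G",
                                  statistic="logrank")
        assert res_lr.outcome_class == "worse"

    def test_best_p_not_above_median_split_p(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 61
            expr = rng.normal(0, 1, n)
            times = rng.exponential(20, n)
            events = (rng.random(n) < 0.7).astype(int)
            res = best_cutoff_scan(pd.Series(expr, index=[f"P{i}" for i in range(n)]),
                                   surv_frame(times, events))
            med_fit = cox_fit_binary(times, events,
                                     (expr > np.median(expr)).astype(float))
            assert res.p_value <= med_fit.p_value + 1e-12

    def test_cutoff_within_quartiles(self):
        rng = np.random.default_rng(22)
        n = 80
        expr = rng.normal(0, 1, n)
        times = rng.exponential(20, n)
        events = (rng.random(n) < 0.7).astype(int)
        res = best_cutoff_scan(pd.Series(expr, index=[f"P{i}" for i in range(n)]),
                               surv_frame(times, events))
        q1, q3 = np.quantile(expr, [0.25, 0.75])
        assert q1 <= res.best_cutoff <= q3
        assert res.n_cutoffs_scanned >= 1

    def test_constant_expression_errors(self):
        with pytest.raises(ValueError, match="identical"):
            best_cutoff_scan(pd.Series(1.0, index=[f"P{i}" for i in range(10)]),
                             surv_frame(np.arange(1.0, 11), np.ones(10, int)))

    def test_null_scan_anticonservative(self):
        """Under the null, min-p cutoff selection inflates the hit rate above
        the nominal 5% — a documented property of the methodology."""
        rng = np.random.default_rng(23)
        hits = 0
        reps = 120
        for _ in range(reps):
            n = 60
            expr = rng.normal(0, 1, n)
            times = rng.exponential(20, n)
            events = (rng.random(n) < 0.7).astype(int)
            res = best_cutoff_scan(
                pd.Series(expr, index=[f"P{i}" for i in range(n)]),
                surv_frame(times, events))
            hits += res.p_value < 0.05
        assert hits / reps > 0.05

    def test_logrank_statistic_mode(self):
        rng = np.random.default_rng(24)
        n = 40
        expr = rng.normal(0, 1, n)
        times = rng.exponential(20, n)
        events = (rng.random(n) < 0.7).astype(int)
        res = best_cutoff_scan(pd.Series(expr, index=[f"P{i}" for i in range(n)]),
                               surv_frame(times, events), statistic="logrank")
        assert 0 <= res.p_value <= 1
        assert res.n_cutoffs_scanned >= 1


class TestClassifyOutcome:
    @pytest.mark.parametrize("hr,p,expected", [
        (2.0, 0.01, "worse"),
        (0.5, 0.01, "better"),
        (3.0, 0.2, "not_significant"),
        (1.0, 0.001, "not_significant"),
    ])
    def test_rule(self, hr, p, expected):
        res = CutoffScanResult(gene="G", best_cutoff=0, hazard_ratio=hr,
                               beta=np.log(hr) if hr > 0 else 0, p_value=p,
                               n_high=10, n_low=10, n_cutoffs_scanned=5)
        assert classify_outcome_association(res) == expected
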