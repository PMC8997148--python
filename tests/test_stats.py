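"""Association and survival statistics: odds ratios, logistic fits, KM, log-rank."""

import numpy as np
import pandas as pd
import pytest

from varmedal import (
    ContingencyTable2x2,
    SeparationError,
    SimConfig,
    fit_logistic,
    fit_logistic_matrix,
    km_estimate,
    log_rank,
    odds_ratio,
    simulate_patients,
)


class TestOddsRatio:
    def test_symmetric_table_is_unity(self):
        assert odds_ratio(ContingencyTable2x2(10, 10, 10, 10)).odds_ratio == pytest.approx(1.0)

    def test_worked_example_with_woolf_interval(self):
        # OR = 20*20 / (10*10) = 4; CI = exp(ln4 +/- 1.96*sqrt(4/20 + 2/10))
        r = odds_ratio(ContingencyTable2x2(20, 10, 10, 20))
        assert r.odds_ratio == pytest.approx(4.0)
        assert r.ci_low == pytest.approx(1.3670, abs=1e-3)
        assert r.ci_high == pytest.approx(11.704, abs=1e-2)

    def test_zero_cell_gets_haldane_correction(self):
        r = odds_ratio(ContingencyTable2x2(5, 0, 5, 10))
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 0
        assert np.isfinite(r.ci_high)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestLogistic:
    def test_intercept_only_at_even_prevalence(self):
        y = np.array([0.0, 1.0] * 100)
        fit = fit_logistic_matrix(y)
        assert fit.term("const").coef == pytest.approx(0.0, abs=1e-10)

    def test_single_binary_covariate_matches_contingency_or(self):
        # 2x2 layout with no empty cells: MLE equals the cross-product ratio
        x = np.repeat([1, 1, 0, 0], [30, 25, 20, 40]).astype(float)
        y = np.concatenate([np.ones(30), np.zeros(25), np.ones(20), np.zeros(40)])
        fit = fit_logistic_matrix(y, pd.DataFrame({"x": x}))
        expected = odds_ratio(ContingencyTable2x2(30, 25, 20, 40)).odds_ratio
        assert fit.term("x").odds_ratio == pytest.approx(expected, abs=1e-6)

    def test_null_covariates_recover_near_zero_coefficients(self):
        rng = np.random.default_rng(11)
        n = 2000
        X = pd.DataFrame({"a": rng.random(n) < 0.3, "b": rng.normal(0, 1, n)})
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_logistic_matrix(y, X)
        assert abs(fit.term("a").coef) < 0.2
        assert abs(fit.term("b").coef) < 0.2

    def test_separation_raises_naming_covariate(self):
        y = np.array([0.0] * 50 + [1.0] * 50)
        X = pd.DataFrame({"leak": y.copy()})
        with pytest.raises(SeparationError, match="leak"):
            fit_logistic_matrix(y, X)

    def test_rank_deficiency_rejected(self):
        y = np.array([0.0, 1.0] * 25)
        X = pd.DataFrame({"a": np.arange(50.0), "b": 2 * np.arange(50.0)})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic_matrix(y, X)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_matrix(np.ones(20))

    def test_cohort_model_recovers_planted_family_history_or(self):
        cfg = SimConfig(seed=5, n_patients=2000, carrier_effect={"family_history": 3.0})
        patients, carrier = simulate_patients(cfg)
        fit = fit_logistic(patients, {p for p, c in carrier.items() if c})
        assert fit.term("family_history").odds_ratio == pytest.approx(3.0, abs=0.8)

    def test_too_few_patients_rejected(self):
        cfg = SimConfig(seed=5, n_patients=5)
        patients, carrier = simulate_patients(cfg)
        with pytest.raises(ValueError):
            fit_logistic(patients, set(carrier))


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = km_estimate([5, 10, 15], [False, False, False])
        assert km.survival_at(100) == 1.0

    def test_hand_computed_product_limit(self):
        # censored 5, events 10 and 15, censored 20, event 25:
        # S(10) = 3/4, S(15) = 3/4 * 2/3 = 1/2, S(25) = 1/2 * 0/1 = 0
        km = km_estimate([5, 10, 15, 20, 25], [False, True, True, False, True])
        assert km.survival_at(10) == pytest.approx(0.75, abs=1e-12)
        assert km.survival_at(15) == pytest.approx(0.5, abs=1e-12)
        assert km.survival_at(25) == pytest.approx(0.0, abs=1e-12)

    def test_all_events_at_once_drop_to_zero(self):
        km = km_estimate([1, 1, 1], [True, True, True])
        assert km.survival_at(1) == 0.0

    def test_curve_is_monotone_from_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(30, 80)
        e = rng.random(80) < 0.7
        km = km_estimate(t, e)
        assert km.survival_at(0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-15)


def _manual_logrank(times, events, groups):
    """Hand-rolled O/E hypergeometric log-rank for cross-checking."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g = np.asarray(groups)
    o1 = e1 = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == g[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (g == g[0])).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        t = [3, 5, 8, 12, 3, 5, 8, 12]
        e = [True] * 8
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = log_rank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_statistic_invariant_to_label_swap(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(20, 30), rng.exponential(40, 30)])
        e = rng.random(60) < 0.8
        g = np.array([0] * 30 + [1] * 30)
        assert log_rank(t, e, g)[0] == pytest.approx(log_rank(t, e, 1 - g)[0])

    def test_matches_hand_computed_oe_tables(self):
        # early events in group A, late in group B, no censoring
        t = [1.0, 2.0, 10.0, 12.0]
        e = [True] * 4
        g = ["A", "A", "B", "B"]
        chi2, _ = log_rank(t, e, g)
        assert chi2 == pytest.approx(_manual_logrank(t, e, g), abs=1e-9)

    def test_no_events_is_undefined(self):
        with pytest.raises(ValueError):
            log_rank([1, 2, 3, 4], [False] * 4, [0, 0, 1, 1])

    def test_survival_recovery_on_simulated_carriers(self):
        cfg = SimConfig(seed=9, n_patients=600, survival_hazard_ratio=3.0)
        patients, carrier = simulate_patients(cfg)
        t = [p.followup_months for p in patients]
        e = [p.recurrence_event for p in patients]
        g = [carrier[p.patient_id] for p in patients]
        chi2, p_val = log_rank(t, e, g)
        assert p_val < 0.01  # a 3x hazard ratio at n=600 is detectable
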