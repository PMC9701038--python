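"""KM, log-rank, maxstat cutpoints and univariate Cox."""

import numpy as np
import pandas as pd
import pytest

from pgkit.io import OmicsMatrix
from pgkit.survival import (
    cox_univariate,
    km_estimate,
    km_survival_at,
    logrank,
    logrank_scores,
    maxstat_cutpoint,
    survival_screen,
)
from pgkit.synthetic import simulate_survival

from conftest import make_matrix


class TestKmEstimate:
    def test_hand_product_limit_no_censoring(self):
        out = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        surv = out.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_survival_one(self):
        out = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (out["survival"] == 1.0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 2.0], [1, 1])

    def test_invariant_to_increasing_time_transform(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        events[0] = 1
        s1 = km_estimate(times, events)["survival"]
        s2 = km_estimate(np.log1p(times), events)["survival"]
        np.testing.assert_allclose(s1, s2, atol=1e-12)


def logrank_oracle(times, events, groups):
    """From-scratch two-group O-E/V statistic over pooled event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_duplicated_groups_null(self, rng):
        times = rng.exponential(10, 40)
        events = np.ones(40, dtype=int)
        chi2, df, p = logrank(np.concatenate([times, times]),
                              np.concatenate([events, events]),
                              np.repeat([0, 1], 40))
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_oracle_five_subjects(self):
        times = [2.0, 3.0, 5.0, 7.0, 11.0]
        events = [1, 1, 0, 1, 1]
        groups = [1, 0, 1, 0, 1]
        chi2, df, p = logrank(times, events, groups)
        assert df == 1
        assert chi2 == pytest.approx(logrank_oracle(times, events, groups),
                                     abs=1e-10)

    def test_power_on_rate_ratio_three(self, rng):
        lows = 0
        for _ in range(10):
            t1, e1 = simulate_survival(np.zeros(200), 0.01, 0.0, rng)
            t2, e2 = simulate_survival(np.full(200, np.log(3)), 0.01, 0.0,
                                       rng)
            _, _, p = logrank(np.concatenate([t1, t2]),
                              np.concatenate([e1, e2]),
                              np.repeat([0, 1], 200))
            lows += (p < 1e-6)
        assert lows >= 9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank([1, 2], [1, 1], [0, 0])


class TestMaxstat:
    def exhaustive_oracle(self, x, times, events, q_low=0.1, q_high=0.9,
                          min_group=10):
        a = logrank_scores(np.asarray(times, float),
                           np.asarray(events, int))
        a = a - a.mean()
        n = len(x)
        s2 = float((a ** 2).mean())
        lo, hi = np.quantile(x, [q_low, q_high])
        best = (None, -1.0)
        for c in np.unique(x):
            n1 = int((x <= c).sum())
            if not (lo <= c <= hi) or n1 < min_group or n - n1 < min_group:
                continue
            z = a[x <= c].sum() / np.sqrt(n1 * (n - n1) / (n - 1) * s2)
            if abs(z) > best[1]:
                best = (c, abs(z))
        return best

    def test_equals_exhaustive_scan(self, rng):
        for _ in range(5):
            n = 60
            x = rng.normal(size=n)
            lp = np.where(x > 0.3, 1.0, 0.0)
            times, events = simulate_survival(lp, 0.01, 0.003, rng)
            ms = maxstat_cutpoint(x, times, events, n_perm=50, rng_seed=0)
            c, stat = self.exhaustive_oracle(x, times, events)
            assert ms.statistic == pytest.approx(stat, abs=1e-10)
            assert ms.cutpoint > c - 1e-12

    def test_perfect_separator_cut_between_groups(self, rng):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        x += rng.normal(0, 0.01, 40)
        lp = np.where(x > 0.5, 2.5, 0.0)
        times, events = simulate_survival(lp, 0.01, 0.0, rng)
        ms = maxstat_cutpoint(x, times, events, n_perm=100, rng_seed=0)
        assert 0.1 < ms.cutpoint < 0.9
        assert ms.p < 0.05

    def test_constant_feature_rejected(self, rng):
        times, events = simulate_survival(np.zeros(30), 0.01, 0.0, rng)
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutpoint(np.ones(30), times, events)

    def test_null_permutation_p_not_anticonservative(self, rng):
        ps = []
        for _ in range(60):
            n = 50
            x = rng.normal(size=n)
            times, events = simulate_survival(np.zeros(n), 0.01, 0.002, rng)
            ps.append(maxstat_cutpoint(x, times, events, n_perm=99,
                                       rng_seed=1).p)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.05 + 0.07


class TestCoxUnivariate:
    def test_recovers_true_hazard_ratio(self, rng):
        hrs = []
        for _ in range(20):
            x = rng.integers(0, 2, 500)
            t, e = simulate_survival(np.log(2) * x, 0.01, 0.002, rng)
            hrs.append(cox_univariate(x, t, e).hr)
        assert 1.7 <= np.median(hrs) <= 2.35

    def test_constant_covariate_rejected(self, rng):
        t, e = simulate_survival(np.zeros(30), 0.01, 0.0, rng)
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(np.ones(30), t, e)

    def test_grid_oracle_partial_likelihood_optimum(self, rng):
        """lifelines' beta maximizes the (no-ties) partial likelihood."""
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        times = np.array([2.0, 3.1, 4.7, 5.3, 7.9, 11.2])
        events = np.array([1, 1, 0, 1, 1, 1])

        def pll(beta):
            order = np.argsort(times)
            total = 0.0
            for i in order:
                if events[i] == 0:
                    continue
                risk = times >= times[i]
                total += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return total

        fit = cox_univariate(x, times, events, min_events=3)
        beta = np.log(fit.hr)
        assert pll(beta) >= pll(beta + 0.01) - 1e-12
        assert pll(beta) >= pll(beta - 0.01) - 1e-12
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_agrees_with_logrank_on_large_n(self, rng):
        x = rng.integers(0, 2, 400)
        t, e = simulate_survival(0.7 * x, 0.01, 0.002, rng)
        fit = cox_univariate(x, t, e)
        _, _, p_lr = logrank(t, e, x)
        assert fit.hr > 1.0
        ratio = fit.p / p_lr if p_lr > 0 else 1.0
        assert 0.5 <= ratio <= 2.0 or max(fit.p, p_lr) < 1e-8


class TestSurvivalScreen:
    def test_planted_hazardous_marker_recovered(self, small_cohort):
        protein = small_cohort.layers["protein"]
        tumor_ids = [s for s in protein.values.columns if s.endswith("_T")]
        feats = small_cohort.truth.biomarkers[:4]
        sub = OmicsMatrix(protein.values.loc[feats, tumor_ids],
                          "protein", "log2")
        fits = survival_screen(sub, small_cohort.clinical, n_perm=200,
                               rng_seed=3)
        assert (fits["hr"] > 1.0).all()
        assert (fits["q"] < 0.05).all()

    def test_features_with_few_events_skipped(self, rng):
        from pgkit.io import ClinicalTable
        n = 30
        ids = [f"P{i:03d}_T" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ids, "patient_id": [f"P{i:03d}" for i in range(n)],
            "tissue": "tumor", "age": 60, "sex": "M", "tnm_stage": "IA",
            "location": "head", "diabetes": "no", "metastasis": "no",
            "blood_glucose": 5.0, "purity": 0.5,
            "os_time": rng.exponential(100, n).round(1),
            "os_event": 0, "dfs_time": 10.0, "dfs_event": 0}))
        mat = make_matrix(rng.normal(size=(3, n)), samples=ids)
        fits = survival_screen(mat, clin, n_perm=50, rng_seed=0)
        assert fits.empty
        assert fits.attrs["skipped"] == 3
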