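"""Linear/Cox endotype association models, diagnostics, and KM curves."""

import numpy as np
import pandas as pd
import pytest

from endotyper import (
    GeneratorConfig, check_proportionality, compute_vif, fit_cox,
    fit_linear_models, generate_cohort, km_estimate,
)
from endotyper.preprocess import cohort_summaries


def efron_partial_loglik(beta, time, event, group):
    """Hand-coded Efron partial log-likelihood for one binary covariate."""
    ll = 0.0
    eta = beta * group
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        sum_r = np.exp(eta[R]).sum()
        sum_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        m = len(D)
        for j in range(m):
            ll -= np.log(sum_r - (j / m) * sum_d)
    return ll


class TestLinearModels:
    def test_noiseless_effect_recovered_exactly(self):
        n = 60
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"center": np.zeros(n, dtype=int)})
        labels = np.repeat([1, 2], n // 2)
        x = (labels == 2).astype(float)
        y = 2.0 * x
        res = fit_linear_models(y, labels, table, models=("Model 1",))
        term = res["Model 1"].term("endotype_2")
        assert term["beta"] == pytest.approx(2.0, abs=1e-10)
        assert term["se"] == pytest.approx(0.0, abs=1e-8)

    def test_dummy_coding_has_k_minus_one_terms(self, default_cohort, discovery):
        sev = cohort_summaries(default_cohort)["cimt_mean_max"].to_numpy()
        res = fit_linear_models(sev, discovery.assignment, default_cohort.data,
                                models=("Model 1",), outcome_name="cimt_mean_max")
        terms = res["Model 1"].table.term.tolist()
        endo_terms = [t for t in terms if t.startswith("endotype_")]
        assert endo_terms == [f"endotype_{e}" for e in range(2, discovery.assignment.k + 1)]
        assert "endotype_1" not in terms

    def test_generator_truth_effect_for_class4(self, default_cohort):
        # planted class means 1.10 vs 1.50 -> class-4 effect 0.40
        sev = cohort_summaries(default_cohort)["cimt_mean_max"].to_numpy()
        res = fit_linear_models(sev, default_cohort.true_class, default_cohort.data,
                                models=("Model 1", "Model 2", "Model 3"))
        for name in ("Model 1", "Model 2", "Model 3"):
            term = res[name].term("endotype_4")
            assert abs(term["beta"] - 0.40) < 3 * term["se"]

    def test_rank_deficient_design_names_aliased_terms(self, small_cohort):
        table = small_cohort.data.copy()
        table["dup"] = table["bmi"]
        y = np.zeros(len(table))
        with pytest.raises(ValueError, match="dup"):
            fit_linear_models(y, small_cohort.true_class, table,
                              models=("Model 2",), extra_covariates=("dup",))


class TestCox:
    def test_identical_groups_hr_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)
        event = np.array([1, 0, 1, 1, 0, 1] * 2)
        group = np.repeat([1, 2], 6)
        surv = pd.DataFrame({"time": time, "event": event})
        res = fit_cox(surv, group)["Model 1"]
        assert res.term("endotype_2")["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_bruteforce_efron_partial_likelihood(self):
        fixtures = [
            (np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
             np.array([1, 1, 0, 1, 1, 0]),
             np.array([0, 1, 0, 1, 0, 1])),
            (np.array([2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 9.0]),   # ties
             np.array([1, 1, 1, 1, 0, 1, 0, 1]),
             np.array([0, 0, 1, 1, 1, 0, 1, 1])),
        ]
        for time, event, group in fixtures:
            surv = pd.DataFrame({"time": time, "event": event})
            res = fit_cox(surv, group + 1, estimate="ml", ci_method="wald")["Model 1"]
            beta_hat = res.term("endotype_2")["beta"]
            grid = np.linspace(beta_hat - 0.5, beta_hat + 0.5, 2001)
            lls = [efron_partial_loglik(b, time, event, group) for b in grid]
            coarse = grid[int(np.argmax(lls))]
            fine = np.linspace(coarse - 1e-3, coarse + 1e-3, 4001)
            lls = [efron_partial_loglik(b, time, event, group) for b in fine]
            assert abs(beta_hat - fine[int(np.argmax(lls))]) < 1e-6

    def test_no_events_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            fit_cox(surv, np.array([1, 2]))

    def test_planted_hazard_ratio_recovered(self, default_cohort):
        surv = default_cohort.data[["time_years", "event"]].rename(
            columns={"time_years": "time"})
        res = fit_cox(surv, default_cohort.true_class)["Model 1"]
        term = res.term("endotype_4")
        assert term["ci_lo"] < 2.85 < term["ci_hi"]


class TestSchoenfeld:
    def _simulate(self, rng, n=150, flip=False, beta=1.5):
        group = rng.integers(0, 2, size=n).astype(float)
        u = rng.uniform(size=n)
        base = 0.2
        if not flip:
            t = -np.log(u) / (base * np.exp(beta * group))
        else:
            # effect +beta before t0, -beta after: piecewise exponential
            t0 = 2.0
            rate1 = base * np.exp(beta * group)
            rate2 = base * np.exp(-beta * group)
            t = -np.log(u) / rate1
            late = t > t0
            t[late] = t0 - np.log(rng.uniform(size=late.sum())) / rate2[late]
        time = np.minimum(t, 12.0)
        event = (t <= 12.0).astype(int)
        return pd.DataFrame({"time": time, "event": event}), group + 1

    def test_null_calibration_p_uniform(self):
        from scipy.stats import kstest
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            surv, group = self._simulate(rng, flip=False, beta=0.5)
            res = fit_cox(surv, group)["Model 1"]
            pvals.append(check_proportionality(res).schoenfeld_p["endotype_2"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_sign_flipping_effect(self):
        hits = 0
        n_sims = 40
        for rep in range(n_sims):
            rng = np.random.default_rng(10_000 + rep)
            surv, group = self._simulate(rng, n=400, flip=True, beta=1.5)
            res = fit_cox(surv, group)["Model 1"]
            if check_proportionality(res).schoenfeld_p["endotype_2"] < 0.05:
                hits += 1
        assert hits >= 0.8 * n_sims

    def test_zero_variance_covariate_rejected(self):
        rng = np.random.default_rng(0)
        surv, group = self._simulate(rng)
        res = fit_cox(surv, group)["Model 1"]
        res.training_df["endotype_2"] = 1.0
        with pytest.raises(ValueError):
            check_proportionality(res)


class TestVIF:
    def test_orthogonal_covariates_unit_vif(self, rng):
        raw = rng.normal(size=(100, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        rep = compute_vif(pd.DataFrame(q, columns=list("abc")))
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_known_r2_gives_vif_four(self, rng):
        raw = rng.normal(size=(200, 2))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        e1, e2 = q[:, 0], q[:, 1]
        x1 = e1
        x2 = np.sqrt(0.75) * e1 + np.sqrt(0.25) * e2   # R^2 on x1 = 0.75
        rep = compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert rep.vif["x1"] == pytest.approx(4.0, abs=1e-8)
        assert rep.vif["x2"] == pytest.approx(4.0, abs=1e-8)

    def test_duplicated_covariate_flagged(self, rng):
        x = rng.normal(size=100)
        rep = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert rep.collinearity_flag
        assert rep.vif["a"] == float("inf")


class TestKM:
    def test_four_distinct_events_quarter_steps(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
        curve = km_estimate(surv)[1]
        got = curve.set_index("time")["survival"]
        assert np.allclose(got.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_curve(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        curve = km_estimate(surv)[1]
        assert (curve["survival"] == 1.0).all()

    def test_mixed_toy_product_limit(self):
        # events at 1 and 3, censored at 2: S(3) = 0.75 * (1 - 1/2) = 0.375
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 0]})
        curve = km_estimate(surv)[1].set_index("time")["survival"]
        assert curve.loc[3.0] == pytest.approx(0.375)

    def test_per_group_curves(self, default_cohort):
        surv = default_cohort.data[["time_years", "event"]].rename(
            columns={"time_years": "time"})
        curves = km_estimate(surv, default_cohort.true_class)
        assert sorted(curves) == [1, 2, 3, 4]
        # severe classes have lower 3-year survival
        s3 = {g: c[c.time <= 3.0].survival.iloc[-1] for g, c in curves.items()}
        assert s3[4] < s3[1]
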