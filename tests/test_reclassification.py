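"""Risk scores, concordance, censoring-adjusted NRI, and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from endotyper.reclassification import (
    NRIResult, bootstrap_ci, categorize_risk, compute_nri, harrell_c,
    load_score_config, score2_linear_predictor,
)


class TestScore2:
    def config(self):
        return {
            "baseline_survival": 0.95,
            "terms": {
                "age": {"coefficient": 0.3, "center": 60.0, "scale": 5.0},
                "sbp": {"coefficient": 0.2, "center": 120.0, "scale": 20.0},
                "smoking": {"coefficient": 0.5, "center": 0.0, "scale": 1.0},
            },
            "calibration": {"scale1": 0.1, "scale2": 1.1},
            "thresholds": {"low_upper": 0.05, "moderate_upper": 0.10},
        }

    def test_linear_predictor_is_the_hand_dot_product(self):
        cfg = self.config()
        df = pd.DataFrame({"age": [67.0], "sbp": [151.0], "smoking": [1.0]})
        rs = score2_linear_predictor(df, cfg)
        expected = 0.3 * (67 - 60) / 5 + 0.2 * (151 - 120) / 20 + 0.5 * 1
        assert rs.linear_predictor[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_covariates_give_calibrated_baseline(self):
        cfg = self.config()
        df = pd.DataFrame({"age": [60.0], "sbp": [120.0], "smoking": [0.0]})
        rs = score2_linear_predictor(df, cfg)
        assert rs.linear_predictor[0] == 0.0
        uncal = 1 - 0.95
        expected = 1 - np.exp(-np.exp(0.1 + 1.1 * np.log(-np.log(1 - uncal))))
        assert rs.risk[0] == pytest.approx(expected, abs=1e-12)

    def test_risk_increases_with_sbp(self):
        cfg = self.config()
        df = pd.DataFrame({"age": [60.0] * 3, "sbp": [110.0, 130.0, 170.0],
                           "smoking": [0.0] * 3})
        rs = score2_linear_predictor(df, cfg)
        assert np.all(np.diff(rs.risk) > 0)

    def test_missing_risk_factor_rejected(self):
        with pytest.raises(ValueError, match="smoking"):
            score2_linear_predictor(pd.DataFrame({"age": [60.0], "sbp": [120.0]}),
                                    self.config())

    def test_packaged_config_loads_both_schemes(self):
        for scheme in ("SCORE2", "SCORE2-OP"):
            cfg = load_score_config(scheme)
            assert "terms" in cfg and "thresholds" in cfg


class TestCategories:
    @pytest.mark.parametrize("risk,expected", [
        (0.049, "low"), (0.05, "moderate"), (0.099, "moderate"), (0.10, "high")])
    def test_score2_thresholds(self, risk, expected):
        assert categorize_risk([risk], "SCORE2")[0] == expected

    @pytest.mark.parametrize("risk,expected", [
        (0.074, "low"), (0.075, "moderate"), (0.15, "high")])
    def test_score2_op_thresholds(self, risk, expected):
        assert categorize_risk([risk], "SCORE2-OP")[0] == expected

    def test_negative_risk_rejected(self):
        with pytest.raises(ValueError):
            categorize_risk([-0.01])


class TestHarrellC:
    def test_perfect_ranking_no_censoring(self):
        surv = pd.DataFrame({"time": [5.0, 4.0, 3.0, 2.0, 1.0], "event": [1] * 5})
        assert harrell_c(surv, [1, 2, 3, 4, 5]) == 1.0

    def test_matches_pair_enumeration_with_censoring(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0, 5.0],
                             "event": [1, 0, 1, 1, 0]})
        risk = np.array([2.0, 1.0, 3.0, 3.0, 0.5])
        time, event = surv.time.to_numpy(), surv.event.to_numpy()
        num = den = 0.0
        for i in range(5):
            for j in range(5):
                if event[i] == 1 and time[i] < time[j]:
                    den += 1
                    if risk[i] > risk[j]:
                        num += 1
                    elif risk[i] == risk[j]:
                        num += 0.5
        assert harrell_c(surv, risk) == pytest.approx(num / den, abs=1e-12)

    def test_uninformative_risk_near_half(self, rng):
        n = 2000
        time = rng.exponential(5.0, size=n)
        event = (time < 8.0).astype(int)
        surv = pd.DataFrame({"time": np.minimum(time, 8.0), "event": event})
        c = harrell_c(surv, rng.normal(size=n))
        assert abs(c - 0.5) < 0.03

    def test_no_events_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            harrell_c(surv, [1, 2])


def km_event_prob_oracle(time, event, horizon):
    """Independent product-limit implementation."""
    order = np.argsort(time)
    time, event = np.asarray(time)[order], np.asarray(event)[order]
    surv = 1.0
    for t in np.unique(time[(event == 1) & (time <= horizon)]):
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        surv *= 1 - d / at_risk
    return 1 - surv


class TestNRI:
    def test_no_reclassification_is_zero(self):
        surv = pd.DataFrame({"time": np.arange(1, 21, dtype=float),
                             "event": [1, 0] * 10})
        cats = np.array(["low", "moderate"] * 10)
        nri = compute_nri(surv, cats, cats, horizon=10.0)
        assert nri.event_nri == nri.nonevent_nri == nri.total_nri == 0.0

    def test_uncensored_toy_equals_direct_counting(self):
        # 10 events: 4 up, 1 down; 90 non-events: 2 up, 7 down
        n_event, n_non = 10, 90
        old = np.array(["low"] * (n_event + n_non), dtype=object)
        new = old.copy()
        new[:4] = "moderate"; old[4] = "moderate"; new[4] = "low"
        new[n_event:n_event + 2] = "moderate"
        old[n_event + 2:n_event + 9] = "moderate"; new[n_event + 2:n_event + 9] = "low"
        time = np.concatenate([np.full(n_event, 1.0), np.full(n_non, 5.0)])
        event = np.concatenate([np.ones(n_event, int), np.zeros(n_non, int)])
        surv = pd.DataFrame({"time": time, "event": event})
        nri = compute_nri(surv, old, new, horizon=3.0)
        assert nri.event_nri == pytest.approx(0.300, abs=1e-10)
        assert nri.nonevent_nri == pytest.approx(5 / 90, abs=1e-10)
        assert nri.total_nri == pytest.approx(0.300 + 5 / 90, abs=1e-10)

    def test_censored_toy_matches_km_oracle(self, rng):
        n = 120
        time = rng.exponential(4.0, size=n)
        censor = rng.uniform(1.0, 8.0, size=n)
        obs = np.minimum(time, censor)
        event = (time <= censor).astype(int)
        surv = pd.DataFrame({"time": obs, "event": event})
        old = rng.choice(["low", "moderate", "high"], size=n)
        new = rng.choice(["low", "moderate", "high"], size=n)
        horizon = 3.0
        nri = compute_nri(surv, old, new, horizon)

        order = {"low": 0, "moderate": 1, "high": 2}
        move = np.sign([order[b] - order[a] for a, b in zip(old, new)])
        move = np.asarray(move)
        pe_all = km_event_prob_oracle(obs, event, horizon)
        up, dn = move == 1, move == -1
        pe_up = km_event_prob_oracle(obs[up], event[up], horizon) if up.any() else 0
        pe_dn = km_event_prob_oracle(obs[dn], event[dn], horizon) if dn.any() else 0
        ev = (up.mean() * pe_up - dn.mean() * pe_dn) / pe_all
        ne = (dn.mean() * (1 - pe_dn) - up.mean() * (1 - pe_up)) / (1 - pe_all)
        assert nri.event_nri == pytest.approx(ev, abs=1e-10)
        assert nri.nonevent_nri == pytest.approx(ne, abs=1e-10)
        assert nri.total_nri == pytest.approx(nri.event_nri + nri.nonevent_nri, abs=1e-12)

    def test_no_events_by_horizon_rejected(self):
        surv = pd.DataFrame({"time": [5.0, 6.0], "event": [0, 0]})
        cats = np.array(["low", "high"])
        with pytest.raises(ValueError):
            compute_nri(surv, cats, cats, horizon=3.0)


class TestBootstrap:
    def test_constant_statistic(self, rng):
        ci = bootstrap_ci(lambda d: 3.5, np.zeros(50), B=100, seed=0)
        assert ci == (3.5, 3.5)

    def test_mean_ci_width_matches_clt(self, rng):
        x = rng.normal(size=10_000)
        lo, hi = bootstrap_ci(lambda d: d.mean(), x, B=400, seed=1)
        assert lo < x.mean() < hi
        expected_width = 2 * 1.96 / np.sqrt(len(x))
        assert abs((hi - lo) - expected_width) < 0.2 * expected_width

    def test_determinism(self, rng):
        x = rng.normal(size=500)
        assert bootstrap_ci(lambda d: d.mean(), x, B=50, seed=7) == \
            bootstrap_ci(lambda d: d.mean(), x, B=50, seed=7)

    def test_excess_failures_error(self, rng):
        def bad(d):
            raise RuntimeError("nope")
        with pytest.raises(RuntimeError):
            bootstrap_ci(bad, np.zeros(10), B=20, seed=0)
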