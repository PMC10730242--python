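"""Independent hand-coded oracles shared by the test suite."""

import numpy as np


def efron_partial_loglik(beta, time, event, group):
    """Efron-tie Cox partial log-likelihood for one binary covariate."""
    ll = 0.0
    eta = beta * np.asarray(group, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
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


def km_event_prob_oracle(time, event, horizon):
    """Product-limit event probability by the horizon, coded from scratch."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        return 0.0
    surv = 1.0
    for t in np.unique(time[(event == 1) & (time <= horizon)]):
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        surv *= 1 - d / at_risk
    return 1 - surv
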