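"""ASCVD risk scores, discrimination, and censoring-adjusted reclassification.

Covers the SCORE2-style config-driven linear predictor and risk categories,
Harrell's concordance for censored outcomes, the categorical net
reclassification improvement with Kaplan-Meier adjustment for censoring
(reducing exactly to cell counting when nothing is censored before the
horizon), and subject-level percentile bootstrap confidence intervals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index

__all__ = [
    "load_score_config", "score2_linear_predictor", "categorize_risk",
    "harrell_c", "compute_nri", "bootstrap_ci", "NRIResult", "RiskScore",
    "cox_risk_at_horizon", "endotype_reclassification",
]

CATEGORIES = np.array(["low", "moderate", "high"])


def load_score_config(scheme: str = "SCORE2", path=None) -> dict:
    """Load a risk-score scheme from YAML (packaged placeholder by default)."""
    if path is None:
        ref = importlib.resources.files("endotyper") / "config" / "score2.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    try:
        return raw["schemes"][scheme]
    except KeyError as exc:
        raise KeyError(f"unknown risk scheme {scheme!r}") from exc


@dataclass
class RiskScore:
    linear_predictor: np.ndarray
    risk: np.ndarray              # calibrated absolute risk in [0, 1]
    category: np.ndarray
    scheme: str


def score2_linear_predictor(riskfactors: pd.DataFrame, config: dict,
                            scheme: str = "SCORE2") -> RiskScore:
    """Config-driven linear predictor and calibrated absolute risk.

    LP = sum of coefficient * (x - center) / scale over the configured terms;
    uncalibrated risk = 1 - S0^exp(LP); the calibrated risk applies the
    two-parameter recalibration
    1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - risk)))).
    """
    missing = [t for t in config["terms"] if t not in riskfactors.columns]
    if missing:
        raise ValueError(f"missing risk factors: {missing}")
    lp = np.zeros(len(riskfactors))
    for name, spec in config["terms"].items():
        x = riskfactors[name].to_numpy(dtype=float)
        lp += spec["coefficient"] * (x - spec.get("center", 0.0)) / spec.get("scale", 1.0)
    s0 = float(config["baseline_survival"])
    uncal = 1.0 - s0 ** np.exp(lp)
    uncal = np.clip(uncal, 1e-12, 1 - 1e-12)
    cal = config.get("calibration", {"scale1": 0.0, "scale2": 1.0})
    risk = 1.0 - np.exp(-np.exp(cal["scale1"] + cal["scale2"] * np.log(-np.log(1.0 - uncal))))
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("calibrated risk left [0, 1]")
    cats = categorize_risk(risk, thresholds=config["thresholds"])
    return RiskScore(linear_predictor=lp, risk=risk, category=cats, scheme=scheme)


def categorize_risk(risk, scheme: str = "SCORE2", thresholds: dict | None = None) -> np.ndarray:
    """low / moderate / high categories; boundaries belong to the upper category.

    SCORE2: <5% low, 5-<10% moderate, >=10% high.
    SCORE2-OP: <7.5% low, 7.5-<15% moderate, >=15% high.
    """
    risk = np.atleast_1d(np.asarray(risk, dtype=float))
    if np.any(risk < 0):
        raise ValueError("risk must be non-negative")
    if np.any(risk > 1):
        raise ValueError("risk must be expressed as a fraction in [0, 1]")
    if thresholds is None:
        thresholds = {"SCORE2": {"low_upper": 0.05, "moderate_upper": 0.10},
                      "SCORE2-OP": {"low_upper": 0.075, "moderate_upper": 0.15}}[scheme]
    lo, mid = thresholds["low_upper"], thresholds["moderate_upper"]
    return CATEGORIES[(risk >= lo).astype(int) + (risk >= mid).astype(int)]


def harrell_c(survival: pd.DataFrame, risk) -> float:
    """Harrell's concordance for a censored outcome and a risk score.

    Fraction of usable (event-anchored) pairs in which the higher risk goes to
    the earlier event; ties in risk count one half.
    """
    risk = np.asarray(risk, dtype=float)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    # concordance_index is oriented toward 'higher score, longer survival'
    return float(concordance_index(time, -risk, event))


def _km_event_prob(time, event, horizon) -> float:
    """1 - S(horizon) by the product-limit estimator (0 if the group is empty)."""
    if len(time) == 0:
        return 0.0
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    return float(1.0 - kmf.predict(horizon))


@dataclass
class NRIResult:
    event_nri: float
    nonevent_nri: float
    total_nri: float
    horizon: float
    ci: tuple | None = None
    n_bootstrap: int = 0


_CAT_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


def compute_nri(survival: pd.DataFrame, old_categories, new_categories,
                horizon: float) -> NRIResult:
    """Censoring-adjusted categorical NRI at a fixed horizon.

    Event and non-event probabilities inside the up-/down-/un-reclassified
    groups are estimated by Kaplan-Meier at the horizon, so that
    NRI+ = P(up | event) - P(down | event) and
    NRI- = P(down | non-event) - P(up | non-event).
    With no censoring before the horizon this reduces exactly to cell counting.
    """
    old = np.asarray(old_categories)
    new = np.asarray(new_categories)
    if old.shape != new.shape or len(old) != len(survival):
        raise ValueError("category vectors must align with the survival records")
    if horizon > float(survival["time"].max()):
        raise ValueError("horizon exceeds the maximum follow-up")
    unknown = set(old) | set(new) - set(_CAT_ORDER)
    unknown -= set(_CAT_ORDER)
    if unknown:
        raise ValueError(f"unknown risk categories: {sorted(unknown)}")
    rank_old = np.array([_CAT_ORDER[c] for c in old])
    rank_new = np.array([_CAT_ORDER[c] for c in new])
    move = np.sign(rank_new - rank_old)          # +1 up, -1 down, 0 same

    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    p_event_all = _km_event_prob(time, event, horizon)
    if p_event_all <= 0:
        raise ValueError("no events estimated by the horizon")

    def group_stats(mask):
        p_group = float(mask.mean())
        p_event = _km_event_prob(time[mask], event[mask], horizon) if mask.any() else 0.0
        return p_group, p_event

    p_up, pe_up = group_stats(move == 1)
    p_dn, pe_dn = group_stats(move == -1)

    event_nri = (p_up * pe_up - p_dn * pe_dn) / p_event_all
    nonevent_nri = (p_dn * (1 - pe_dn) - p_up * (1 - pe_up)) / (1 - p_event_all)
    return NRIResult(event_nri=float(event_nri), nonevent_nri=float(nonevent_nri),
                     total_nri=float(event_nri + nonevent_nri), horizon=float(horizon))


def bootstrap_ci(statistic, data, B: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple:
    """Subject-level percentile bootstrap interval for a resample-aware statistic.

    ``statistic(resampled_data) -> float``; ``data`` is indexed positionally
    (DataFrame rows or first array axis). Failing resamples are skipped and
    counted; more than 10% failures is an error.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    n = len(data)
    rng = np.random.default_rng(seed)
    values, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True) if isinstance(data, pd.DataFrame) \
            else data[idx]
        try:
            values.append(float(statistic(sample)))
        except Exception:
            failures += 1
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap resamples failed")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def cox_risk_at_horizon(survival: pd.DataFrame, covariates: pd.DataFrame,
                        horizon: float) -> np.ndarray:
    """Predicted absolute event risk at the horizon from a Cox fit."""
    df = covariates.copy()
    df["time"] = survival["time"].to_numpy(dtype=float)
    df["event"] = survival["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    surv = cph.predict_survival_function(covariates, times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy(dtype=float)


def endotype_reclassification(survival: pd.DataFrame, base_covariates: pd.DataFrame,
                              endotypes, horizon: float = 3.0,
                              thresholds: dict | None = None,
                              scheme: str = "SCORE2") -> tuple:
    """Reclassification by adding endotype dummies to a baseline risk model.

    Both risk models are Cox fits (with and without endotype indicators);
    predicted risks at the horizon are categorized by the scheme thresholds and
    compared by the censoring-adjusted NRI. Returns (NRIResult, old_cat,
    new_cat).
    """
    labels = np.asarray(getattr(endotypes, "labels", endotypes))
    dummies = pd.get_dummies(pd.Series(labels, name="endotype"), prefix="endotype",
                             drop_first=True, dtype=float)
    dummies.index = base_covariates.index
    risk_old = cox_risk_at_horizon(survival, base_covariates, horizon)
    risk_new = cox_risk_at_horizon(survival, pd.concat([base_covariates, dummies], axis=1),
                                   horizon)
    old_cat = categorize_risk(risk_old, scheme=scheme, thresholds=thresholds)
    new_cat = categorize_risk(risk_new, scheme=scheme, thresholds=thresholds)
    nri = compute_nri(survival, old_cat, new_cat, horizon)
    return nri, old_cat, new_cat
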