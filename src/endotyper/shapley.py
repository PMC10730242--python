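"""Model-agnostic Shapley attribution by Monte-Carlo permutation sampling.

For each subject x and endotype e, the attribution phi[x, v, e] estimates the
Shapley value of variable v toward the model's predicted probability of e,
relative to a background reference sample. Estimates are efficiency-normalized:
after an additive correction the attributions of each (subject, endotype) sum
exactly to prediction minus the background-mean prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AttributionMatrix", "shapley_attribution", "rank_variables"]


@dataclass
class AttributionMatrix:
    phi: np.ndarray               # subjects x variables x endotypes
    baseline: np.ndarray          # background-mean prediction per endotype
    predictions: np.ndarray       # subjects x endotypes
    variables: list
    endotypes: np.ndarray

    @property
    def shap_endotype(self) -> pd.DataFrame:
        """Mean |phi| per (variable, endotype)."""
        vals = np.abs(self.phi).mean(axis=0)
        return pd.DataFrame(vals, index=self.variables,
                            columns=[f"endotype_{e}" for e in self.endotypes])

    @property
    def global_shap(self) -> pd.Series:
        """Mean |phi| over subjects and endotypes."""
        return pd.Series(np.abs(self.phi).mean(axis=(0, 2)), index=self.variables)

    def to_long(self) -> pd.DataFrame:
        n, p, K = self.phi.shape
        idx = np.indices((n, p, K)).reshape(3, -1)
        return pd.DataFrame({
            "subject": idx[0],
            "variable": np.asarray(self.variables)[idx[1]],
            "endotype": self.endotypes[idx[2]],
            "phi": self.phi.ravel(),
        })


def shapley_attribution(predict_fn, subjects, background,
                        n_permutations: int = 64, seed: int = 0,
                        variables=None) -> AttributionMatrix:
    """Permutation-sampling Shapley estimates of predict_fn per endotype.

    For each sampled permutation of the variables and background row, variables
    are switched one by one from the background value to the subject's value;
    the successive prediction differences are unbiased marginal-contribution
    draws. The estimates are then additively adjusted so the efficiency
    identity sum_v phi = f(x) - mean f(background) holds exactly.
    """
    if isinstance(subjects, pd.DataFrame):
        variables = list(subjects.columns)
        X = subjects.to_numpy(dtype=float)
    else:
        X = np.asarray(subjects, dtype=float)
        if variables is None:
            variables = [f"x{i}" for i in range(X.shape[1])]
    B = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) \
        else np.asarray(background, dtype=float)
    if B.size == 0:
        raise ValueError("background sample must be non-empty")
    if B.ndim == 1:
        B = B[None, :]
    n, p = X.shape
    rng = np.random.default_rng(seed)

    pred_x = np.asarray(predict_fn(X), dtype=float)
    if pred_x.ndim == 1:
        pred_x = pred_x[:, None]
    if not np.all(np.isfinite(pred_x)):
        raise ValueError("predict_fn returned non-finite values")
    K = pred_x.shape[1]
    baseline = np.asarray(predict_fn(B), dtype=float)
    if baseline.ndim == 1:
        baseline = baseline[:, None]
    baseline = baseline.mean(axis=0)

    # one coalition walk per (permutation, subject); all permutations advance
    # in lock-step so the model is called only p + 1 times on stacked batches
    orders = np.stack([rng.permutation(p) for _ in range(n_permutations)])
    b_rows = B[rng.integers(0, len(B), size=(n_permutations, n))]
    current = b_rows.reshape(n_permutations * n, p).copy()
    Xtile = np.tile(X, (n_permutations, 1))

    def batched_predict(A):
        out = np.asarray(predict_fn(A), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        return out.reshape(n_permutations, n, -1)

    phi = np.zeros((n, p, K))
    prev = batched_predict(current)
    rows = np.arange(n_permutations * n)
    block = np.repeat(np.arange(n_permutations), n)
    for step in range(p):
        v_per_row = orders[block, step]
        current[rows, v_per_row] = Xtile[rows, v_per_row]
        nxt = batched_predict(current)
        diff = nxt - prev                      # (B, n, K)
        for b in range(n_permutations):
            phi[:, orders[b, step], :] += diff[b]
        prev = nxt
    phi /= n_permutations

    # efficiency normalization: distribute the Monte-Carlo residue uniformly
    target = pred_x - baseline[None, :]
    residue = target - phi.sum(axis=1)
    phi += residue[:, None, :] / p

    return AttributionMatrix(phi=phi, baseline=baseline, predictions=pred_x,
                             variables=variables,
                             endotypes=np.arange(1, K + 1))


@dataclass
class VariableRanking:
    global_ranking: list
    per_endotype: dict            # endotype -> ordered variable list
    top10_per_endotype: dict
    degenerate: bool = False


def rank_variables(attr: AttributionMatrix, n_subjects_sampled: int = 300) -> VariableRanking:
    """Rank variables by global mean |phi| and per-endotype mean |phi|.

    Ties break alphabetically; an all-zero attribution matrix is flagged
    degenerate (pure alphabetical order). ``n_subjects_sampled`` documents the
    intended sample size; if the matrix holds fewer subjects all are used.
    """
    if attr.phi.size == 0:
        raise ValueError("empty attribution matrix")
    g = attr.global_shap
    order = sorted(g.index, key=lambda v: (-g[v], v))
    per = {}
    se = attr.shap_endotype
    for e in attr.endotypes:
        col = se[f"endotype_{e}"]
        per[int(e)] = sorted(col.index, key=lambda v: (-col[v], v))
    degenerate = bool(np.allclose(attr.phi, 0.0))
    if degenerate:
        order = sorted(g.index)
        per = {int(e): sorted(g.index) for e in attr.endotypes}
    return VariableRanking(global_ranking=order, per_endotype=per,
                           top10_per_endotype={e: v[:10] for e, v in per.items()},
                           degenerate=degenerate)
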