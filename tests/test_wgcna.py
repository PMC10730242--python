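"""Correlation network construction: soft power, TOM closed forms, module cut."""

import numpy as np
import pandas as pd
import pytest

from endotyper.wgcna import (
    compute_tom, detect_modules, endotype_module_summary, pick_soft_power,
    scale_free_fit,
)


def exact_correlation_design(rng, n, corr_matrix):
    """Columns with exactly the requested sample correlation matrix."""
    p = corr_matrix.shape[0]
    raw = rng.normal(size=(n, p + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    basis = q[:, :p]                      # orthonormal, zero-mean columns
    chol = np.linalg.cholesky(corr_matrix)
    return basis @ chol.T


class TestTOMClosedForms:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, 2 * x + 1])
        ms = compute_tom(X, beta_power=3)
        assert ms.adjacency[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert ms.tom[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_three_variables_half_correlation_beta_two(self, rng):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        X = exact_correlation_design(rng, 50, C)
        ms = compute_tom(X, beta_power=2)
        assert np.allclose(ms.adjacency[0, 1], 0.25, atol=1e-10)
        # l_12 = 0.0625, k = 0.5 -> TOM = 0.3125 / 1.25 = 0.25
        assert ms.tom[0, 1] == pytest.approx(0.25, abs=1e-10)

    def test_uncorrelated_pair(self, rng):
        C = np.eye(2)
        X = exact_correlation_design(rng, 40, C)
        ms = compute_tom(X, beta_power=2)
        assert ms.tom[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_constant_biomarker_named(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="v1"):
            compute_tom(X, beta_power=2)

    def test_symmetry_and_range_fuzz(self, rng):
        for _ in range(200):
            n, p = int(rng.integers(20, 60)), int(rng.integers(4, 10))
            X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
            if np.any(X.std(axis=0) == 0):
                continue
            ms = compute_tom(X, beta_power=int(rng.integers(1, 8)))
            assert np.allclose(ms.tom, ms.tom.T, atol=1e-12)
            assert ms.tom.min() >= 0.0 and ms.tom.max() <= 1.0
            assert np.allclose(np.diag(ms.tom), 1.0)


class TestSoftPower:
    def test_fit_matches_independent_loglog_regression(self, default_cohort):
        expr = default_cohort.data[default_cohort.columns_with_role("biomarker")]
        beta, fits, _ = pick_soft_power(expr)
        ms = compute_tom(expr, beta)
        # independent oracle: normal-equations fit of log10 p(k) on log10 k
        k = ms.connectivity[ms.connectivity > 0]
        edges = np.linspace(k.min(), k.max() + 1e-12, 11)
        counts, _ = np.histogram(k, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        lx, ly = np.log10(centers[keep]), np.log10(counts[keep] / counts.sum())
        A = np.column_stack([lx, np.ones_like(lx)])
        coef = np.linalg.solve(A.T @ A, A.T @ ly)
        resid = ly - A @ coef
        r2 = 1 - resid @ resid / np.sum((ly - ly.mean()) ** 2)
        assert scale_free_fit(ms.connectivity) == pytest.approx(r2, abs=1e-10)
        assert fits.loc[fits.power == beta, "r2"].iloc[0] == pytest.approx(r2, abs=1e-10)

    def test_independent_noise_triggers_fallback(self, rng):
        X = rng.normal(size=(2000, 30))
        _, _, fallback = pick_soft_power(X)
        assert fallback

    def test_mean_connectivity_nonincreasing_in_power(self, rng):
        X = rng.normal(size=(200, 15)) @ rng.normal(size=(15, 15))
        _, fits, _ = pick_soft_power(X)
        assert np.all(np.diff(fits.mean_connectivity) <= 1e-12)


class TestModuleDetection:
    def planted_blocks(self, rng, sizes, within=0.9, n=400):
        cols, truth = [], []
        for b, size in enumerate(sizes):
            f = rng.normal(size=(n, 1))
            noise = rng.normal(size=(n, size))
            cols.append(np.sqrt(within) * f + np.sqrt(1 - within) * noise)
            truth += [b + 1] * size
        return np.hstack(cols), np.array(truth)

    def test_two_planted_blocks_exact_membership(self, rng):
        X, truth = self.planted_blocks(rng, [5, 5])
        ms = compute_tom(X, beta_power=6)
        mm = detect_modules(ms, min_module_size=3)
        assert ms.n_modules == 2
        for b in (1, 2):
            dets = mm[truth == b]
            assert dets.nunique() == 1 and dets.iloc[0] > 0

    def test_all_independent_all_unassigned(self, rng):
        X = rng.normal(size=(2000, 12))
        ms = compute_tom(X, beta_power=6)
        mm = detect_modules(ms, min_module_size=3)
        assert (mm == 0).all()

    def test_undersized_block_unassigned(self, rng):
        X, truth = self.planted_blocks(rng, [6, 2])
        ms = compute_tom(X, beta_power=6)
        mm = detect_modules(ms, min_module_size=3)
        assert (mm[truth == 2] == 0).all()
        assert (mm[truth == 1] > 0).all()


class TestEndotypeSummary:
    def test_planted_shift_shows_in_summary(self, default_cohort):
        from endotyper import GeneratorConfig, z_standardize
        tab = default_cohort
        cfg = GeneratorConfig()
        names = cfg.biomarker_names()
        Z, _ = z_standardize(tab, names)
        mm = pd.Series(cfg.module_assignment(), index=names)
        summary = endotype_module_summary(Z, tab.true_class, mm)
        block4 = mm[mm == 6].index            # OPG/GDF15/MMP12/CHI3L1 block
        means = summary.loc[block4, [f"endotype_{e}" for e in range(1, 5)]]
        # the class-4 elevation survives overall standardization, attenuated
        assert (means["endotype_4"] > 0.4).all()
        assert (means["endotype_4"].to_numpy()
                == means.max(axis=1).to_numpy()).all()

    def test_single_endotype_summary_is_overall_mean(self, rng):
        Z = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        Zc = (Z - Z.mean()) / Z.std(ddof=1)
        mm = pd.Series([1, 1, 2, 2], index=list("abcd"))
        s = endotype_module_summary(Zc, np.ones(100, dtype=int), mm)
        assert np.allclose(s["endotype_1"], 0.0, atol=1e-10)

    def test_empty_endotype_rejected(self, rng):
        Z = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        mm = pd.Series([1, 1], index=list("ab"))
        labels = np.ones(10, dtype=int)
        with pytest.raises(ValueError):
            endotype_module_summary(Z, np.where(labels == 2, 1, 1)[:5], mm)
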