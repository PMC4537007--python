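"""Detectable-feature filtering, two-way factorial selection, and PCA.

The selection stage flags features regulated by either treatment factor
(ATRA, Lapatinib) or their interaction via per-feature two-way ANOVA with
replication on the balanced 2x2 design.  P-values are used unadjusted for
selection by default (a Benjamini-Hochberg mode is available); a feature is
selected when any of its three factorial p-values falls below ``alpha``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, condition_labels

logger = logging.getLogger(__name__)

_EPS = 1e-12


def detect_expressed(matrix: ExpressionMatrix, threshold: float) -> set[str]:
    """Features whose per-condition mean exceeds ``threshold`` in >=1 condition."""
    if matrix.n_features == 0:
        raise ValueError("empty expression matrix")
    means = matrix.condition_means()
    keep = (means > threshold).any(axis=1)
    detected = set(means.index[keep])
    logger.info("detectable expression: %d / %d features above %.3g",
                len(detected), matrix.n_features, threshold)
    return detected


def factorial_select(matrix: ExpressionMatrix, alpha: float,
                     adjust: bool = False,
                     allow_unbalanced: bool = False) -> pd.DataFrame:
    """Per-feature two-factor ANOVA with replication on the 2x2 design.

    Returns a DataFrame indexed by feature id with columns ``p_atra``,
    ``p_lapatinib``, ``p_interaction``, ``log2fc_atra``, ``log2fc_lap``,
    ``log2fc_combo``, ``degenerate`` and ``selected``.  Zero-variance
    features get p = 1 with ``degenerate=True`` so downstream joins never
    lose ids.  Balanced designs use a closed-form sums-of-squares
    decomposition; unbalanced designs are refused unless
    ``allow_unbalanced`` enables a per-feature OLS fallback.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    sheet = matrix.sample_sheet
    for col in ("ATRA", "Lapatinib"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks design column {col!r}")
    a = sheet["ATRA"].astype(int).to_numpy()
    l = sheet["Lapatinib"].astype(int).to_numpy()
    cells = {(ai, li): np.flatnonzero((a == ai) & (l == li))
             for ai in (0, 1) for li in (0, 1)}
    counts = {c: len(ix) for c, ix in cells.items()}
    if min(counts.values()) < 2:
        raise ValueError(f"each design cell needs >=2 replicates, got {counts}")
    balanced = len(set(counts.values())) == 1

    Y = matrix.values.to_numpy(dtype=float)
    if balanced:
        r = counts[(0, 0)]
        n = Y.shape[1]
        M = {c: Y[:, ix].mean(axis=1) for c, ix in cells.items()}
        mean_a1 = (M[(1, 0)] + M[(1, 1)]) / 2
        mean_a0 = (M[(0, 0)] + M[(0, 1)]) / 2
        mean_l1 = (M[(0, 1)] + M[(1, 1)]) / 2
        mean_l0 = (M[(0, 0)] + M[(1, 0)]) / 2
        ss_a = n / 4 * (mean_a1 - mean_a0) ** 2
        ss_b = n / 4 * (mean_l1 - mean_l0) ** 2
        delta = M[(1, 1)] - M[(1, 0)] - M[(0, 1)] + M[(0, 0)]
        ss_ab = n / 16 * delta ** 2
        ss_within = np.zeros(Y.shape[0])
        for c, ix in cells.items():
            ss_within += ((Y[:, ix] - M[c][:, None]) ** 2).sum(axis=1)
        df_within = n - 4
        ms_within = ss_within / df_within

        def _p(ss):
            with np.errstate(divide="ignore", invalid="ignore"):
                f = ss / ms_within
            p = stats.f.sf(f, 1, df_within)
            p = np.where(ms_within < _EPS, np.where(ss < _EPS, 1.0, 0.0), p)
            return p

        p_a, p_b, p_ab = _p(ss_a), _p(ss_b), _p(ss_ab)
        degenerate = (ms_within < _EPS) & (ss_a < _EPS) & (ss_b < _EPS) & (ss_ab < _EPS)
    else:
        if not allow_unbalanced:
            raise ValueError(
                f"unbalanced 2x2 design (cell counts {counts}); "
                "pass allow_unbalanced=True for the linear-model fallback"
            )
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        p_a = np.empty(Y.shape[0]); p_b = np.empty(Y.shape[0])
        p_ab = np.empty(Y.shape[0])
        degenerate = np.zeros(Y.shape[0], dtype=bool)
        df = pd.DataFrame({"A": a, "L": l})
        for i in range(Y.shape[0]):
            df["y"] = Y[i]
            if np.ptp(Y[i]) < _EPS:
                p_a[i] = p_b[i] = p_ab[i] = 1.0
                degenerate[i] = True
                continue
            fit = ols("y ~ C(A) * C(L)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            p_a[i], p_b[i], p_ab[i] = tab["PR(>F)"].to_numpy()[:3]
        M = {c: Y[:, ix].mean(axis=1) for c, ix in cells.items()}

    veh = M[(0, 0)]
    result = pd.DataFrame({
        "p_atra": p_a,
        "p_lapatinib": p_b,
        "p_interaction": p_ab,
        "log2fc_atra": M[(1, 0)] - veh,
        "log2fc_lap": M[(0, 1)] - veh,
        "log2fc_combo": M[(1, 1)] - veh,
        "degenerate": degenerate,
    }, index=matrix.feature_ids)
    pmat = result[["p_atra", "p_lapatinib", "p_interaction"]]
    if adjust:
        from statsmodels.stats.multitest import multipletests
        padj = pmat.apply(
            lambda col: multipletests(col.to_numpy(), method="fdr_bh")[1], axis=0
        )
        result["selected"] = (padj < alpha).any(axis=1)
    else:
        result["selected"] = (pmat < alpha).any(axis=1).to_numpy()
    logger.info("factorial selection: %d / %d features at alpha=%.4g%s",
                int(result["selected"].sum()), len(result), alpha,
                " (BH-adjusted)" if adjust else "")
    return result


def pca_projection(matrix: ExpressionMatrix, on=None, scale: bool = False):
    """First two principal components of the feature-centered data.

    Samples are the observations.  Returns ``(coords, explained)`` where
    ``coords`` is a samples x 2 DataFrame (columns PC1, PC2) and
    ``explained`` the fractions of variance captured by each component.
    """
    values = matrix.values if on is None else matrix.values.loc[sorted(on)]
    if values.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 features")
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    # samples as rows for the decomposition
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)
    coords = pd.DataFrame(U[:, :2] * s[:2], index=values.columns,
                          columns=["PC1", "PC2"])
    total = (s ** 2).sum()
    explained = (s[:2] ** 2 / total) if total > 0 else np.zeros(2)
    return coords, explained
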