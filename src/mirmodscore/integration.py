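"""Two-criterion miR->target integration.

A candidate (miR, mRNA) pair survives integration when (1) at least one
prediction source lists it and (2) the miR and mRNA expression profiles are
strongly anti-correlated: Spearman rho < ``rho_cutoff`` (default -0.9) with
Benjamini-Hochberg q < ``q_cutoff`` (default 0.05), both strict.

Correlation can be taken over matched per-sample profiles (default when the
two matrices share sample ids) or over the four condition means
(``axis="condition_means"``).  Note the granularity caveat of the latter:
on 4 untied points the achievable Spearman values are {-1, -0.8, ...}, so
rho < -0.9 is only satisfiable by perfect anti-ranking.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

#: profile length at or below which the exact permutation p-value is used
EXACT_PERM_MAX_N = 8


def union_candidates(per_source_edges: list[pd.DataFrame],
                     source_names: list[str] | None = None,
                     known_mirs=None, known_mrnas=None) -> pd.DataFrame:
    """Union of per-source edge lists, tagging each pair with its sources.

    Each input is a two-column (``mir_id``, ``mrna_id``) DataFrame.  Edges
    referencing ids outside ``known_mirs``/``known_mrnas`` (when given) are
    dropped with a logged count.  Returns columns ``mir_id``, ``mrna_id``,
    ``sources`` (sorted tuple of source names).
    """
    if not per_source_edges:
        raise ValueError("need at least one prediction source")
    if source_names is None:
        source_names = [f"source{i + 1}" for i in range(len(per_source_edges))]
    if len(source_names) != len(per_source_edges):
        raise ValueError("source_names length mismatch")
    known_mirs = set(known_mirs) if known_mirs is not None else None
    known_mrnas = set(known_mrnas) if known_mrnas is not None else None

    tagged: dict[tuple, set] = {}
    n_dropped = 0
    for name, df in zip(source_names, per_source_edges):
        for col in ("mir_id", "mrna_id"):
            if col not in df.columns:
                raise ValueError(f"source {name!r} lacks column {col!r}")
        for mir, mrna in df[["mir_id", "mrna_id"]].itertuples(index=False):
            if (known_mirs is not None and mir not in known_mirs) or \
               (known_mrnas is not None and mrna not in known_mrnas):
                n_dropped += 1
                continue
            tagged.setdefault((mir, mrna), set()).add(name)
    if n_dropped:
        logger.warning("dropped %d predicted edges with unknown feature ids",
                       n_dropped)
    rows = [(m, g, tuple(sorted(srcs))) for (m, g), srcs in sorted(tagged.items())]
    out = pd.DataFrame(rows, columns=["mir_id", "mrna_id", "sources"])
    logger.info("candidate union: %d pairs from %d sources", len(out),
                len(per_source_edges))
    return out


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


@lru_cache(maxsize=8)
def _untied_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| permutation distribution for untied profiles of length n."""
    rx = np.arange(1.0, n + 1)
    ry = rx[_perm_matrix(n)]
    x = rx - rx.mean()
    y = ry - ry.mean(axis=1, keepdims=True)
    rhos = (y @ x) / ((x ** 2).sum())
    return np.sort(np.abs(rhos))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    n = len(rx)
    if len(set(rx)) == n and len(set(ry)) == n:
        # untied: the permutation distribution depends only on n
        null = _untied_null_abs_rho(n)
        idx = np.searchsorted(null, abs(rho_obs) - 1e-12, side="left")
        return float((len(null) - idx) / len(null))
    perms = _perm_matrix(n)
    ry_perm = ry[perms]                       # (n!, n)
    x = rx - rx.mean()
    y = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((x ** 2).sum()) * np.sqrt((y ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (y @ x) / denom
    rhos = rhos[np.isfinite(rhos)]
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_pairs(mir_matrix: ExpressionMatrix, mrna_matrix: ExpressionMatrix,
                   candidates: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Spearman rho and p for each candidate pair.

    ``axis="samples"`` pairs the matrices on shared sample ids;
    ``axis="condition_means"`` pairs the four per-condition means (for
    designs measured at different times, where samples do not correspond).
    Ties get average ranks.  p is two-sided: exact by permutation when the
    profile length is <= 8, otherwise the large-sample t approximation.
    Constant profiles yield NaN rho/p (excluded downstream with a logged
    count).
    """
    if axis == "samples":
        shared = mir_matrix.sample_ids.intersection(mrna_matrix.sample_ids)
        if len(shared) < 3:
            raise ValueError("need >=3 paired samples for correlation")
        X = mir_matrix.values.loc[:, shared]
        Y = mrna_matrix.values.loc[:, shared]
    elif axis == "condition_means":
        X = mir_matrix.condition_means()
        Y = mrna_matrix.condition_means()
        common = X.columns.intersection(Y.columns)
        if len(common) < 3:
            raise ValueError("need >=3 shared conditions for correlation")
        X, Y = X[common], Y[common]
    else:
        raise ValueError(f"unknown correlation axis {axis!r}")

    n = X.shape[1]
    missing_m = set(candidates["mir_id"]) - set(X.index)
    missing_g = set(candidates["mrna_id"]) - set(Y.index)
    if missing_m or missing_g:
        raise KeyError(
            f"candidates reference features absent from the matrices: "
            f"{sorted(missing_m)[:3] + sorted(missing_g)[:3]}"
        )

    mir_used = candidates["mir_id"].unique()
    mrna_used = candidates["mrna_id"].unique()
    rx_all = pd.DataFrame(
        stats.rankdata(X.loc[mir_used].to_numpy(), axis=1), index=mir_used)
    ry_all = pd.DataFrame(
        stats.rankdata(Y.loc[mrna_used].to_numpy(), axis=1), index=mrna_used)

    RX = rx_all.loc[candidates["mir_id"]].to_numpy()
    RY = ry_all.loc[candidates["mrna_id"]].to_numpy()
    cx = RX - RX.mean(axis=1, keepdims=True)
    cy = RY - RY.mean(axis=1, keepdims=True)
    sx = np.sqrt((cx ** 2).sum(axis=1))
    sy = np.sqrt((cy ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (cx * cy).sum(axis=1) / (sx * sy)
    rho = np.where((sx == 0) | (sy == 0), np.nan, rho)

    if n <= EXACT_PERM_MAX_N:
        p = np.array([
            _exact_perm_p(RX[i], RY[i], rho[i]) if np.isfinite(rho[i]) else np.nan
            for i in range(len(rho))
        ])
    else:
        r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isfinite(rho), p, np.nan)

    n_const = int(np.isnan(rho).sum())
    if n_const:
        logger.warning("%d candidate pairs with constant profiles (rho undefined)",
                       n_const)
    out = candidates.copy()
    out["rho"] = rho
    out["p_corr"] = p
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def integrate(correlations: pd.DataFrame, rho_cutoff: float = -0.9,
              q_cutoff: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Apply the anti-correlation filter to scored candidates.

    ``correlations`` is the output of :func:`spearman_pairs`.  Keeps exactly
    the pairs with rho < ``rho_cutoff`` and BH q < ``q_cutoff`` (both
    strict).  Returns the integrated edge table (with ``q_corr``) and a
    summary dict with edge / distinct-miR / distinct-mRNA counts.
    """
    if not -1 <= rho_cutoff <= 1:
        raise ValueError(f"rho_cutoff must lie in [-1, 1], got {rho_cutoff}")
    if not 0 < q_cutoff <= 1:
        raise ValueError(f"q_cutoff must lie in (0, 1], got {q_cutoff}")
    scored = correlations.copy()
    n_undefined = int(scored["rho"].isna().sum())
    if n_undefined:
        logger.warning("excluding %d pairs with undefined correlation", n_undefined)
    scored["q_corr"] = bh_adjust(scored["p_corr"].to_numpy())
    keep = (scored["rho"] < rho_cutoff) & (scored["q_corr"] < q_cutoff)
    keep &= scored["rho"].notna() & scored["q_corr"].notna()
    edges = scored.loc[keep].reset_index(drop=True)
    counts = {
        "n_edges": len(edges),
        "n_mirs": edges["mir_id"].nunique(),
        "n_mrnas": edges["mrna_id"].nunique(),
    }
    logger.info("integration: %(n_edges)d edges, %(n_mirs)d distinct miRs, "
                "%(n_mrnas)d distinct mRNAs", counts)
    return edges, counts
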