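"""Nodewise group inference with covariate adjustment and FDR control.

The omnibus test per node is an analysis of covariance: a linear model with
intercept, covariates (sex, age, education, head motion) and diagnosis
dummies, where the group factor is tested by the extra-sum-of-squares F
statistic (3 numerator degrees of freedom for four groups).  Benjamini-
Hochberg adjustment is applied across nodes within each metric-by-load
family.  Post hoc pairwise contrasts come from the same adjusted model.
Clinical/cognitive relations use partial correlations after residualizing
both variables on the covariates.  Summary-statistic recomputation of the
published group table (one-way ANOVA from printed moments, chi-square test
of the sex table) is also provided.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import GROUPS

COVARIATE_COLUMNS = ("sex", "age", "education", "head_motion")


def _design_matrices(
    diagnosis: np.ndarray, covariates: np.ndarray, groups: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full (intercept + covariates + group dummies) and reduced designs."""
    n = len(diagnosis)
    x_reduced = np.column_stack([np.ones(n), covariates])
    dummies = []
    names = []
    for g in groups[1:]:  # first group is the reference level
        dummies.append((diagnosis == g).astype(float))
        names.append(g)
    x_full = np.column_stack([x_reduced] + dummies)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        raise ValueError(
            "rank-deficient design matrix: check covariates for collinearity "
            f"(rank {rank} < {x_full.shape[1]} columns)"
        )
    return x_full, x_reduced, names


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise residual sum of squares of OLS fits y ~ x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _prepare(values, diagnosis, covariates):
    y = np.asarray(values, float)
    if y.ndim == 1:
        y = y[:, None]
    diagnosis = np.asarray(diagnosis)
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(float)
    elif isinstance(covariates, Mapping):
        cov = np.column_stack([np.asarray(v, float) for v in covariates.values()])
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size == 0:
            cov = np.empty((len(diagnosis), 0))
    if len(y) != len(diagnosis) or len(cov) != len(diagnosis):
        raise ValueError("values, diagnosis and covariates must have equal length")
    groups = [g for g in GROUPS if g in set(diagnosis)]
    if len(groups) < 2:
        raise ValueError("need at least 2 diagnostic groups")
    counts = pd.Series(diagnosis).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 subjects per group; too few in {small}")
    return y, diagnosis, cov, groups


def ancova_per_node(values, diagnosis, covariates) -> tuple[float, float]:
    """Covariate-adjusted omnibus group F test for one node.

    Returns the extra-sum-of-squares F statistic for the diagnosis factor
    and its p-value.  With all-constant (or empty) covariates this is
    exactly the one-way ANOVA F.
    """
    f, p = ancova_f(values, diagnosis, covariates)
    return float(f[0]), float(p[0])


def ancova_f(values, diagnosis, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized omnibus ANCOVA across many nodes at once.

    ``values`` may be (n_subjects,) or (n_subjects, n_nodes); returns per-
    node arrays (F, p).
    """
    y, diagnosis, cov, groups = _prepare(values, diagnosis, covariates)
    # drop constant covariate columns (no information; keeps design full rank)
    keep = np.ptp(cov, axis=0) > 0 if cov.size else np.zeros(0, bool)
    cov = cov[:, keep] if cov.size else cov
    x_full, x_reduced, _ = _design_matrices(diagnosis, cov, groups)
    rss_full = _rss(x_full, y)
    rss_reduced = _rss(x_reduced, y)
    df1 = len(groups) - 1
    df2 = len(y) - x_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough observations for the model")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    f = np.where(rss_full == 0, np.inf, f)
    p = stats.f.sf(f, df1, df2)
    return f, p


def ancova_table(
    values: np.ndarray,
    diagnosis,
    covariates,
    metric: str,
    load: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nodewise omnibus table with BH-FDR across nodes (one family)."""
    f, p = ancova_f(values, diagnosis, covariates)
    q = fdr_bh(p)
    return pd.DataFrame(
        {
            "node_id": np.arange(len(f)),
            "metric": metric,
            "load": load,
            "F": f,
            "p": p,
            "q": q,
            "detected": q < alpha,
        }
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def posthoc_pairwise(
    values,
    diagnosis,
    covariates,
    detected_nodes: Sequence[int],
    family: str = "per_node",
) -> pd.DataFrame:
    """All pairwise group contrasts from the adjusted model, per detected node.

    The contrast for (g1, g2) estimates the adjusted mean difference
    g1 - g2; its standard error comes from the full-model coefficient
    covariance.  FDR is applied within the six contrasts of each node
    (``family='per_node'``) or across all contrasts of all detected nodes
    (``family='pooled'``).
    """
    if family not in ("per_node", "pooled"):
        raise ValueError("family must be 'per_node' or 'pooled'")
    detected_nodes = list(detected_nodes)
    cols = ["node_id", "group1", "group2", "estimate", "t", "p", "q"]
    if not detected_nodes:
        return pd.DataFrame(columns=cols)
    y, diagnosis, cov, groups = _prepare(values, diagnosis, covariates)
    keep = np.ptp(cov, axis=0) > 0 if cov.size else np.zeros(0, bool)
    cov = cov[:, keep] if cov.size else cov
    x_full, _, dummy_names = _design_matrices(diagnosis, cov, groups)
    n, k = x_full.shape
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    resid = y - x_full @ beta
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df

    # coefficient index of each group's dummy (reference group -> None)
    dummy_ix = {g: None for g in groups}
    offset = k - len(dummy_names)
    for j, g in enumerate(dummy_names):
        dummy_ix[g] = offset + j

    rows = []
    for node in detected_nodes:
        for g1, g2 in combinations(groups, 2):
            c = np.zeros(k)
            if dummy_ix[g1] is not None:
                c[dummy_ix[g1]] = 1.0
            if dummy_ix[g2] is not None:
                c[dummy_ix[g2]] -= 1.0
            est = float(c @ beta[:, node])
            se = float(np.sqrt(sigma2[node] * (c @ xtx_inv @ c)))
            t = est / se if se > 0 else np.inf * np.sign(est)
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append({"node_id": node, "group1": g1, "group2": g2,
                         "estimate": est, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if family == "per_node":
        out["q"] = out.groupby("node_id")["p"].transform(lambda s: fdr_bh(s.to_numpy()))
    else:
        out["q"] = fdr_bh(out["p"].to_numpy())
    return out[cols]


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized vectors.

    Both ``x`` and ``y`` are residualized on an intercept plus the
    covariates; the p-value uses the t transform with ``n - 2 - k`` degrees
    of freedom, ``k`` the number of covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(float)
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.size == 0:
            cov = np.empty((len(x), 0))
    k = cov.shape[1]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[ok], y[ok], cov[ok]
    n = len(x)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete observations, got {n}")
    design = np.column_stack([np.ones(n), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("residualized variable is constant; correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def correlate_clinical(
    values: np.ndarray,
    cohort: pd.DataFrame,
    nodes: Sequence[int],
    variables: Sequence[str],
    metric: str,
    load: str,
    covariate_columns: Sequence[str] = COVARIATE_COLUMNS,
    clinical_sample: str = "patients",
) -> pd.DataFrame:
    """Partial correlations between detected-node values and clinical scores.

    Clinical scales are correlated over the subjects possessing the scale
    (patients, under the default sample rule); task-performance measures over
    all participants.  FDR is applied across the whole node-by-variable
    family, mirroring a single reported correlation table.
    """
    from .synthetic import CLINICAL_COLUMNS

    rows = []
    cov_all = cohort[list(covariate_columns)]
    for node in nodes:
        v = values[:, node]
        for var in variables:
            score = cohort[var].to_numpy(float)
            sel = np.isfinite(score)
            if var in CLINICAL_COLUMNS and clinical_sample == "patients":
                sel &= (cohort["diagnosis"] != "HC").to_numpy()
            if sel.sum() < len(covariate_columns) + 3:
                continue
            r, p = partial_correlation(v[sel], score[sel], cov_all[sel])
            rows.append({"node_id": node, "metric": metric, "load": load,
                         "variable": var, "n": int(sel.sum()), "r": r, "p": p})
    out = pd.DataFrame(rows, columns=["node_id", "metric", "load", "variable", "n", "r", "p"])
    out["q"] = fdr_bh(out["p"].to_numpy()) if len(out) else np.nan
    return out


def anova_from_summary(means, sds, ns) -> tuple[float, int, int]:
    """One-way ANOVA F from group means, SDs and sizes (printed-table input).

    ``F = MSB / MSW`` with ``SSB = sum n_g (m_g - grand_mean)^2`` and
    ``SSW = sum (n_g - 1) s_g^2``.  Returns (F, df1, df2); F is inf when the
    within-group variance vanishes but the between-group variance does not.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    if np.any(ns < 2):
        raise ValueError("all group sizes must be >= 2")
    if np.any(sds < 0):
        raise ValueError("SDs must be nonnegative")
    k = len(means)
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(n_total - k)
    if ssw == 0:
        return (np.inf if ssb > 0 else 0.0), df1, df2
    return (ssb / df1) / (ssw / df2), df1, df2


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


__all__ = [
    "COVARIATE_COLUMNS",
    "ancova_f",
    "ancova_per_node",
    "ancova_table",
    "anova_from_summary",
    "chi_square_independence",
    "correlate_clinical",
    "fdr_bh",
    "partial_correlation",
    "posthoc_pairwise",
]
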