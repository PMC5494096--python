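"""Empirical-Bayes moderated two-sample differential expression.

The moderated t-statistic shrinks each feature's pooled sample variance s_g^2
toward a prior value s_0^2 estimated from the whole matrix:

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),      d_g = n_1 + n_2 - 2
    t_g    = (mean_case - mean_control) / sqrt(s~_g^2 (1/n_1 + 1/n_2))

and refers t_g to a t distribution with d_0 + d_g degrees of freedom.  The
hyperparameters (d_0, s_0^2) come from a method-of-moments fit on the
log sample variances: if s_g^2 ~ s_0^2 F(d_g, d_0) then z_g = log s_g^2 has

    Var(z)  = trigamma(d_g/2) + trigamma(d_0/2)
    E(z)    = log s_0^2 + [digamma(d_g/2) - log(d_g/2)] - [digamma(d_0/2) - log(d_0/2)]

so d_0 is the trigamma inverse of Var(z) - trigamma(d_g/2) and s_0^2 follows
from the mean.  When the observed log-variance spread is no larger than the
pure-sampling spread, d_0 = +inf and every feature shares one variance; in
that degenerate limit s_0^2 is taken as the geometric mean of the sample
variances, so identical inputs round-trip exactly.

At d_0 = 0 the statistic is the ordinary pooled two-sample t; at d_0 = +inf
it is a z-like statistic with a common variance.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

# Variance floor applied before taking logs; keeps the trigamma moments finite
# when a feature is constant within both groups.
VAR_FLOOR = 1e-12
# d0 above this is treated as infinite (normal reference distribution).
D0_INFINITE = 1e6

RESULT_COLUMNS = [
    "feature_id",
    "log_fc",
    "sample_var",
    "moderated_var",
    "t_mod",
    "df_total",
    "p_raw",
    "p_adj",
    "is_significant",
]


def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Force every sample (column) onto the common mean quantile profile.

    The reference profile is the across-sample mean of the column-sorted
    values; tied values within a column receive the mean of the reference
    values over their rank span.  Feature and sample order are preserved.
    """
    values = data.values
    if values.shape[1] == 1:
        warnings.warn("single-sample matrix: quantile normalization is the identity")
        return data.with_values(values.copy())
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(arr.shape[0])
        col[order] = reference
        # average the reference values across each tie span
        col = pd.Series(col).groupby(pd.Series(arr[:, j])).transform("mean").to_numpy()
        out[:, j] = col
    return data.with_values(pd.DataFrame(out, index=values.index, columns=values.columns))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x branch
    x = 0.5 + 1.0 / y
    for _ in range(50):
        f = float(special.polygamma(1, x)) - y
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * (1.0 + abs(x)):
            x = x_new
            break
        x = x_new
    return x


def estimate_eb_hyperparameters(
    sample_vars: Sequence[float] | np.ndarray, df_resid: float
) -> tuple[float, float]:
    """Fit (d0, s0_sq) by moments on log sample variances.

    Returns ``d0 = inf`` when the variances are under-dispersed relative to
    chi-square sampling noise (including the all-equal case, where
    ``s0_sq`` equals that common variance exactly).
    """
    v = np.asarray(sample_vars, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two sample variances")
    if not np.isfinite(v).all() or (v < 0).any():
        raise ValueError("sample variances must be finite and non-negative")
    if df_resid <= 0:
        raise ValueError("df_resid must be positive")
    z = np.log(np.maximum(v, VAR_FLOOR))
    var_z = float(np.var(z, ddof=1))
    mean_z = float(np.mean(z))
    if var_z < 1e-12:
        # literally identical variances: no sampling spread to deconvolve,
        # the common value itself is the only defensible prior variance
        return math.inf, float(math.exp(mean_z))
    trig_dg = float(special.polygamma(1, df_resid / 2.0))
    excess = var_z - trig_dg
    # in the infinite-d0 limit the log-variance sampling bias
    # digamma(dg/2) - log(dg/2) must still be removed from mean(z)
    log_s0_inf = mean_z - (
        float(special.digamma(df_resid / 2.0)) - math.log(df_resid / 2.0)
    )
    if excess <= 0:
        return math.inf, float(math.exp(log_s0_inf))
    d0 = 2.0 * _trigamma_inverse(excess)
    if d0 > D0_INFINITE:
        return math.inf, float(math.exp(log_s0_inf))
    log_s0 = (
        mean_z
        - (float(special.digamma(df_resid / 2.0)) - math.log(df_resid / 2.0))
        + (float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    )
    return d0, float(math.exp(log_s0))


def moderated_t_test(
    data: ExpressionDataset, d0: float, s0_sq: float
) -> pd.DataFrame:
    """Per-feature moderated t test of case vs control.

    Returns a DataFrame with the columns in :data:`RESULT_COLUMNS`
    (``p_adj``/``is_significant`` filled by :func:`run_differential`; here
    they are the BH adjustment at alpha 0.05 for standalone use).
    """
    case = data.values[data.group_columns("case")].to_numpy(dtype=float)
    ctrl = data.values[data.group_columns("control")].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    dg = n1 + n2 - 2
    log_fc = case.mean(axis=1) - ctrl.mean(axis=1)
    pooled = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / dg
    if math.isinf(d0):
        mod_var = np.full_like(pooled, s0_sq)
        df_total = math.inf
    else:
        mod_var = (d0 * s0_sq + dg * pooled) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(mod_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    t_mod = np.where(log_fc == 0, 0.0, t_mod)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "feature_id": data.feature_ids,
            "log_fc": log_fc,
            "sample_var": pooled,
            "moderated_var": mod_var,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_significant": np.asarray(p_adj) < 0.05,
        }
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Feature ids with BH-adjusted p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mask = results["p_adj"].to_numpy() < alpha
    return set(results.loc[mask, "feature_id"])


def moderated_t_test_paired(data: ExpressionDataset) -> pd.DataFrame:
    """One-sample moderated t on within-pair case-minus-control differences.

    Pairs are matched by column order within each group; both groups must have
    the same size.  Hyperparameters are fitted on the per-feature variances of
    the differences (residual df = n_pairs - 1).
    """
    case_cols = data.group_columns("case")
    ctrl_cols = data.group_columns("control")
    if len(case_cols) != len(ctrl_cols):
        raise ValueError("paired analysis needs equally sized groups")
    diffs = (
        data.values[case_cols].to_numpy(dtype=float)
        - data.values[ctrl_cols].to_numpy(dtype=float)
    )
    n = diffs.shape[1]
    dg = n - 1
    s_var = diffs.var(axis=1, ddof=1)
    d0, s0_sq = estimate_eb_hyperparameters(s_var, dg)
    log_fc = diffs.mean(axis=1)
    if math.isinf(d0):
        mod_var = np.full_like(s_var, s0_sq)
        df_total = math.inf
    else:
        mod_var = (d0 * s0_sq + dg * s_var) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(mod_var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    t_mod = np.where(log_fc == 0, 0.0, t_mod)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "feature_id": data.feature_ids,
            "log_fc": log_fc,
            "sample_var": s_var,
            "moderated_var": mod_var,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_significant": np.asarray(p_adj) < 0.05,
        }
    )


def run_differential(
    data: ExpressionDataset,
    alpha: float = 0.05,
    normalization: str = "quantile",
    paired: bool = False,
) -> tuple[pd.DataFrame, set[str]]:
    """Normalize, fit hyperparameters, test, adjust: the full DE stage."""
    if normalization == "quantile":
        data = quantile_normalize(data)
    elif normalization != "none":
        raise ValueError(f"unknown normalization: {normalization!r}")
    if paired:
        results = moderated_t_test_paired(data)
    else:
        n1 = len(data.group_columns("case"))
        n2 = len(data.group_columns("control"))
        dg = n1 + n2 - 2
        case = data.values[data.group_columns("case")].to_numpy(dtype=float)
        ctrl = data.values[data.group_columns("control")].to_numpy(dtype=float)
        pooled = (
            (n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)
        ) / dg
        d0, s0_sq = estimate_eb_hyperparameters(pooled, dg)
        results = moderated_t_test(data, d0, s0_sq)
    results["is_significant"] = results["p_adj"] < alpha
    return results, select_differential(results, alpha)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
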