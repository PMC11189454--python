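"""Two-group differential expression with empirical-Bayes variance moderation,
Benjamini-Hochberg adjustment, and hypergeometric over-representation.

The moderated t statistic shrinks each gene's pooled residual variance toward
a common prior fitted by method-of-moments on log sample variances under a
scaled-F model, then refers the shrunken t to a t distribution with
``prior_df + residual_df`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_model import ExpressionMatrix, ValidationError


@dataclass
class DeResult:
    table: pd.DataFrame  # per gene: log2fc, t, pvalue, adj_pvalue, s2, zero_variance
    n_a: int
    n_b: int
    prior_df: float
    prior_var: float


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior_var s0^2) for s2 ~ s0^2 F(df, d0).

    Works on log s2: E[log s2] and Var[log s2] are linear in digamma/trigamma
    terms, so d0 solves trigamma(d0/2) = var(log s2) - trigamma(df/2).
    """
    z = np.log(s2)
    e_mean = float(np.mean(z)) - float(special.digamma(df / 2)) + math.log(df / 2)
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2 * _inv_trigamma(e_var)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2) - math.log(d0 / 2))
    return d0, s0_sq


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return x


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D array of p-values")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def moderated_t(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    prior_df_override: float | None = None,
) -> DeResult:
    """Moderated two-sample t test per gene, groups given as ROI-id collections.

    ``prior_df_override`` fixes the prior degrees of freedom (0 recovers the
    ordinary pooled t exactly; large values shrink fully to the prior).
    """
    if expr.scale != "log2":
        raise ValidationError("moderated_t expects log2-scale expression")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 ROIs")
    missing = (set(group_a) | set(group_b)) - set(expr.roi_ids)
    if missing:
        raise ValidationError(f"ROI(s) not in expression matrix: {sorted(missing)}")

    a = expr.data[group_a].to_numpy()
    b = expr.data[group_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    zero_var = s2 <= 0
    if np.all(zero_var):
        raise ValidationError("all genes have zero residual variance; matrix is constant")
    floor = s2[~zero_var].min()
    s2_work = np.where(zero_var, floor, s2)

    if prior_df_override is not None:
        d0 = float(prior_df_override)
        s0_sq = float(np.median(s2_work)) if d0 > 0 else 1.0
    else:
        d0, s0_sq = _fit_f_dist(s2_work, df)

    if math.isinf(d0):
        s2_post = np.full_like(s2_work, s0_sq)
        total_df = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2_work) / (d0 + df)
        total_df = d0 + df

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = log2fc / se
    if math.isinf(total_df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), total_df)
    adj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2fc": log2fc,
            "t": t,
            "pvalue": p,
            "adj_pvalue": adj,
            "s2": s2,
            "zero_variance": zero_var,
        }
    ).set_index("gene")
    return DeResult(table=table, n_a=n_a, n_b=n_b, prior_df=d0, prior_var=s0_sq)


def enrich(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``gene_list`` in each set.

    Each gene set is intersected with the universe first; the p-value is the
    upper tail P(overlap >= observed).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    gene_list = set(gene_list)
    outside = gene_list - universe
    if outside:
        raise ValidationError(f"gene_list members outside universe: {sorted(outside)[:5]}")

    M = len(universe)
    N = len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        n = len(members)
        k = len(members & gene_list)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"gene_set": name, "set_size": n, "overlap": k, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
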