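"""Empirical-Bayes moderated-t differential expression.

Per gene, a pooled two-sample variance s_g^2 with d_g = nA + nB - 2 residual
degrees of freedom is shrunk toward a common prior: assuming
s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2(d_g)/d_g with a scaled inverse-chi-square
prior sigma_g^2 ~ s0^2 * d0 / chi2(d0), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t, Delta / (s~_g * sqrt(1/nA + 1/nB)), follows a
t-distribution with d0 + d_g degrees of freedom under the null.  The prior
(d0, s0^2) is estimated by matching the first two moments of log s_g^2 using
digamma/trigamma identities, the canonical closed-form fit.

Significance calling combines a Benjamini-Hochberg FDR cutoff with an
absolute fold-change floor (FC-abs = 2^{|log2 FC|}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

__all__ = [
    "ModeratedTTest",
    "DEResults",
    "squeeze_variances",
    "moderated_t_test",
    "bh_fdr",
    "call_de",
]


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene variances.

    Matches mean and variance of log s_g^2 using E[log chi2_k/k] =
    digamma(k/2) - log(k/2) and Var[log chi2_k/k] = trigamma(k/2).  Returns
    ``d0 = inf`` when the observed spread of log s^2 is no larger than the
    sampling spread (all genes share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 >= 0)]
    if s2.size < 2:
        raise ValidationError("need >= 2 finite gene variances to fit the prior")
    m = float(np.median(s2))
    if m == 0:
        raise ValidationError(
            "more than half the residual variances are exactly zero; "
            "the variance prior cannot be fit"
        )
    # offset exact zeros away from zero so log s^2 is defined
    x = np.maximum(s2, 1e-5 * m)
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array(e_var)))
        s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # observed spread no larger than sampling spread: one shared variance
        d0 = np.inf
        s0sq = float(np.mean(x))
    return d0, s0sq


def squeeze_variances(
    s2: np.ndarray, df: float, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward the fitted (or given) prior.

    Returns ``(s2_post, d0, s0sq)``.  ``prior_df=0`` disables moderation
    (posterior = sample variance); ``prior_df=inf`` collapses every gene to
    the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is not None and prior_df == 0:
        return s2.copy(), 0.0, float(np.nan)
    d0, s0sq = fit_variance_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        return np.full_like(s2, s0sq), d0, s0sq
    post = (d0 * s0sq + df * s2) / (d0 + df)
    return post, d0, s0sq


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` clipped at 1; invariant to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ModeratedTTest:
    """Two-group moderated-t model on log2 normalized expression.

    Parameters
    ----------
    log_expr
        genes x samples matrix of log2 expression (already normalized).
    groups
        Per-sample labels (Series or array aligned with the columns) with
        exactly two distinct values, or a pair ``(samples_a, samples_b)``.
    group_order
        Optional pair fixing which label is the comparison's A side; log2 FC
        is mean(A) - mean(B).  Defaults to order of first appearance.
    """

    def __init__(self, log_expr: pd.DataFrame, groups, group_order=None):
        self.log_expr = log_expr
        if isinstance(groups, (tuple, list)) and len(groups) == 2 and not np.isscalar(groups[0]):
            samples_a, samples_b = list(groups[0]), list(groups[1])
            labels = pd.Series(
                ["A"] * len(samples_a) + ["B"] * len(samples_b),
                index=samples_a + samples_b,
            )
            group_order = group_order or ("A", "B")
        else:
            labels = pd.Series(np.asarray(groups), index=log_expr.columns)
        uniq = list(dict.fromkeys(labels))
        if len(uniq) != 2:
            raise ValidationError(f"need exactly 2 groups, got {uniq}")
        if group_order is not None:
            uniq = list(group_order)
        self.group_a, self.group_b = uniq
        self.samples_a = list(labels.index[labels == self.group_a])
        self.samples_b = list(labels.index[labels == self.group_b])
        if len(self.samples_a) < 2 or len(self.samples_b) < 2:
            raise ValidationError("need >= 2 samples per group")

    def fit(self, prior_df: float | None = None) -> "DEResults":
        """Estimate the variance prior and compute per-gene statistics."""
        a = self.log_expr[self.samples_a].to_numpy(dtype=float)
        b = self.log_expr[self.samples_b].to_numpy(dtype=float)
        na, nb = a.shape[1], b.shape[1]
        df_resid = na + nb - 2
        if df_resid < 1:
            raise ValidationError("zero residual degrees of freedom")
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
            (b - mean_b[:, None]) ** 2
        ).sum(axis=1)
        s2 = ss / df_resid
        s2_post, d0, s0sq = squeeze_variances(s2, df_resid, prior_df=prior_df)

        delta = mean_a - mean_b
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t = np.zeros_like(delta)
        ok = se > 0
        t[ok] = delta[ok] / se[ok]
        t[~ok & (delta > 0)] = np.inf
        t[~ok & (delta < 0)] = -np.inf
        df_total = d0 + df_resid
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        # all-identical rows: delta 0 and zero variance -> t = 0, p = 1
        degenerate = (se == 0) & (delta == 0)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        p = np.where((se == 0) & (delta != 0), 0.0, p)
        q = bh_fdr(p)

        table = pd.DataFrame(
            {
                f"mean_{self.group_a}": mean_a,
                f"mean_{self.group_b}": mean_b,
                "log2fc": delta,
                "fc_abs": np.exp2(np.abs(delta)),
                "t_mod": t,
                "p_value": p,
                "q_value": q,
            },
            index=self.log_expr.index,
        )
        return DEResults(
            model=self,
            table=table,
            prior_df=d0,
            prior_var=s0sq,
            residual_df=float(df_resid),
            s2=pd.Series(s2, index=self.log_expr.index, name="s2"),
            s2_post=pd.Series(s2_post, index=self.log_expr.index, name="s2_post"),
        )


@dataclass
class DEResults:
    """Fitted moderated-t comparison.

    ``table`` holds per-gene group means, log2 FC, FC-abs, moderated t,
    p and BH q.  :meth:`call` adds the significance flag and up/down
    partition at the chosen thresholds.
    """

    model: ModeratedTTest
    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: float
    s2: pd.Series
    s2_post: pd.Series

    def call(self, alpha: float = 0.05, fc_min: float = 2.0) -> pd.DataFrame:
        """Flag genes with q <= alpha and FC-abs >= fc_min (boundaries in)."""
        return call_de(self.table, alpha=alpha, fc_min=fc_min)

    def up_down(self, alpha: float = 0.05, fc_min: float = 2.0):
        flagged = self.call(alpha, fc_min)
        sig = flagged[flagged["significant"]]
        up = sig.index[sig["log2fc"] > 0]
        down = sig.index[sig["log2fc"] < 0]
        return up, down

    def summary(self, alpha: float = 0.05, fc_min: float = 2.0) -> str:
        flagged = self.call(alpha, fc_min)
        up, down = self.up_down(alpha, fc_min)
        lines = [
            "Moderated-t differential expression",
            "=" * 35,
            f"comparison: {self.model.group_a} vs {self.model.group_b} "
            f"({len(self.model.samples_a)} vs {len(self.model.samples_b)} samples)",
            f"genes tested: {len(self.table)}",
            f"prior df d0: {self.prior_df:.4g}   prior variance s0^2: {self.prior_var:.4g}",
            f"residual df per gene: {self.residual_df:.0f}",
            f"significant (q<={alpha}, FC-abs>={fc_min}): "
            f"{int(flagged['significant'].sum())} ({len(up)} up, {len(down)} down)",
        ]
        return "\n".join(lines)


def moderated_t_test(
    log_expr: pd.DataFrame, samples_a, samples_b, prior_df: float | None = None
) -> DEResults:
    """Functional wrapper: moderated t of ``samples_a`` vs ``samples_b``."""
    return ModeratedTTest(log_expr, (samples_a, samples_b)).fit(prior_df=prior_df)


def call_de(table: pd.DataFrame, alpha: float = 0.05, fc_min: float = 2.0) -> pd.DataFrame:
    """Significance flags: q <= alpha AND FC-abs >= fc_min, boundaries included."""
    out = table.copy()
    out["significant"] = (out["q_value"] <= alpha) & (out["fc_abs"] >= fc_min)
    out["direction"] = np.select(
        [out["significant"] & (out["log2fc"] > 0), out["significant"] & (out["log2fc"] < 0)],
        ["up", "down"],
        default="ns",
    )
    return out
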