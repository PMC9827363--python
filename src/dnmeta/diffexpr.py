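"""Gene-wise two-group linear fits with empirical-Bayes variance moderation.

For each gene a least-squares fit of the DN-vs-control contrast yields an
effect beta_g (log2 fold-change), residual variance s2_g on d_g degrees of
freedom, and the usual unscaled coefficient variance v_g. The gene variances
are then shrunk toward a common prior: assuming s2_g | sigma2_g ~ scaled
chi^2 and 1/sigma2_g ~ scaled chi^2 with prior df d0 and scale s0^2, the
posterior variance is

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t-statistic t_g = beta_g / sqrt(v_g * s2_tilde_g) follows
a Student-t with d0 + d_g degrees of freedom. The hyperparameters (d0, s0^2)
are estimated by matching the first two moments of log s2_g to the implied
scaled-F distribution via digamma/trigamma inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import DataError, ExpressionDataset, UsageError


@dataclass
class ModeratedFit:
    """Per-gene moderated statistics plus the EB hyperparameters."""

    table: pd.DataFrame  # log2FC, s2, df, s2_post, t, p, q
    d0: float
    s0_2: float
    dataset_id: str = ""
    tissue: str = ""

    def significant(self, lfc_threshold: float = 1.5, fdr_threshold: float = 0.05):
        t = self.table
        return t[(t["q"] < fdr_threshold) & (t["log2FC"].abs() >= lfc_threshold)]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from observed gene variances at common df.

    Uses z_g = log s2_g: E[z] and Var[z] under the scaled-F model give two
    equations solved with digamma/trigamma functions. Infinite d0 (no excess
    variability of the variances) falls back to s0^2 = exp(mean adjusted z).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.all():
        smallest = s2[ok].min() if ok.any() else 1.0
        warnings.warn(
            f"{(~ok).sum()} genes with zero residual variance; "
            "assigned the smallest positive variance"
        )
        s2 = np.where(ok, s2, smallest)
    z = np.log(s2)
    if np.ptp(z) == 0:
        # degenerate: no spread at all, so the prior is the common variance
        return np.inf, float(s2[0])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = e.var(ddof=1) if n > 1 else 0.0
    e_var = e_var - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderate(s2: np.ndarray, df: float, d0: float, s0_2: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def fit_moderated(
    dataset: ExpressionDataset,
    condition_col: str = "condition",
    d0_override: float | None = None,
) -> ModeratedFit:
    """Moderated DN - control contrast for every gene of one dataset.

    ``d0_override`` forces the prior df (0 recovers the ordinary t-test;
    used for testing the no-shrinkage limit).
    """
    cond = dataset.meta[condition_col]
    dn = dataset.expr.loc[:, (cond == "DN").to_numpy()]
    ctl = dataset.expr.loc[:, (cond == "control").to_numpy()]
    n1, n2 = dn.shape[1], ctl.shape[1]
    if n1 < 2 or n2 < 2:
        raise UsageError(
            f"fit_moderated: dataset {dataset.dataset_id} needs >= 2 samples "
            f"per condition (got DN={n1}, control={n2})"
        )
    x1, x2 = dn.to_numpy(float), ctl.to_numpy(float)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    v = 1.0 / n1 + 1.0 / n2  # unscaled variance of the contrast

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            s0_2 = float(np.median(s2))  # irrelevant: weight is zero
            s2_post = s2.copy()
        else:
            _, s0_2 = fit_prior(s2, df)
            s2_post = moderate(s2, df, d0, s0_2)
    else:
        d0, s0_2 = fit_prior(s2, df)
        s2_post = moderate(s2, df, d0, s0_2)

    bad = s2_post <= 0
    if bad.any():
        s2_post = np.where(bad, s2_post[~bad].min(), s2_post)
    t = lfc / np.sqrt(v * s2_post)
    df_total = d0 + df
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FC": lfc,
            "s2": s2,
            "df": float(df),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": q,
        },
        index=dataset.expr.index,
    )
    tissue = dataset.meta["tissue"].iloc[0] if "tissue" in dataset.meta else ""
    return ModeratedFit(table, float(d0), float(s0_2), dataset.dataset_id, tissue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
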