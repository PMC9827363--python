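"""Empirical-Bayes location/scale batch adjustment (parametric ComBat).

Model per gene g, sample i of batch b:

    x_gib = alpha_g + X_i beta_g + gamma_gb + delta_gb * eps_gib

gamma_gb (additive) and delta_gb^2 (multiplicative) batch effects are
estimated per gene, then shrunk toward batch-level priors: a normal prior
for gamma with moments (gamma_bar_b, tau2_b) and an inverse-gamma prior for
delta^2 with parameters (lambda_b, theta_b), both fitted from the empirical
across-gene distributions by moment matching. The adjusted value removes
the shrunken batch effects while preserving the covariate (condition)
effects X beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DataError, ExpressionDataset, UsageError


@dataclass
class BatchModel:
    """Estimated and shrunken batch parameters, for inspection/serialization."""

    batches: list
    gamma_hat: pd.DataFrame      # genes x batches, least-squares additive
    delta2_hat: pd.DataFrame     # genes x batches, variance ratios
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    tau2: pd.Series
    lambda_: pd.Series
    theta: pd.Series
    alpha: pd.Series             # gene grand means (weighted)
    sigma2: pd.Series            # pooled gene variances
    beta: pd.DataFrame | None    # covariate coefficients
    n_iterations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "batches": list(self.batches),
            "gamma_bar": self.gamma_bar.round(6).to_dict(),
            "tau2": self.tau2.round(6).to_dict(),
            "lambda": self.lambda_.round(6).to_dict(),
            "theta": self.theta.round(6).to_dict(),
            "n_iterations": self.n_iterations,
            "mean_gamma_star": self.gamma_star.mean().round(6).to_dict(),
            "mean_delta2_star": self.delta2_star.mean().round(6).to_dict(),
        }


def merge_common_genes(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate datasets on their common gene set; dataset id becomes the
    batch label of each column."""
    if len(datasets) < 2:
        raise UsageError("merge_common_genes: need >= 2 datasets")
    common = datasets[0].genes
    for d in datasets[1:]:
        common = common.intersection(d.genes)
    if len(common) == 0:
        raise DataError("merge_common_genes: empty gene intersection")
    expr = pd.concat([d.expr.loc[common] for d in datasets], axis=1)
    meta = pd.concat([d.meta for d in datasets], axis=0)
    meta = meta.assign(batch=meta["dataset"])
    return ExpressionDataset("combined", expr, meta)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)


def _postvar(sum_sq, n, lam, theta):
    return (0.5 * sum_sq + theta) / (n / 2.0 + lam - 1.0)


def combat_adjust(
    bundle: ExpressionDataset,
    batch_col: str = "batch",
    covariate_col: str | None = "condition",
    mean_only: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ExpressionDataset, BatchModel | None]:
    """Adjust a combined bundle for batch effects, preserving the condition
    contrast.

    Single-batch input is returned unchanged (with a warning). A batch of
    size 1 has no variance estimate and is an error. Batches lacking one of
    the two conditions trigger a confounding warning but are processed.
    """
    meta = bundle.meta
    batches = list(dict.fromkeys(meta[batch_col]))
    if len(batches) < 2:
        warnings.warn("combat_adjust: single batch, returning input unchanged")
        return bundle, None
    sizes = meta[batch_col].value_counts()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2].tolist()
        raise DataError(f"combat_adjust: batches of size 1: {bad}")

    x = bundle.expr.to_numpy(dtype=float)
    genes = bundle.expr.index
    n_total = x.shape[1]
    batch_of = meta[batch_col].to_numpy()
    batch_idx = {b: np.flatnonzero(batch_of == b) for b in batches}
    n_b = np.array([len(batch_idx[b]) for b in batches], dtype=float)

    # design: batch indicators plus (optionally) condition covariate
    design_cols = [np.isin(np.arange(n_total), batch_idx[b]).astype(float)
                   for b in batches]
    cov = None
    if covariate_col is not None:
        levels = list(dict.fromkeys(meta[covariate_col]))
        if len(levels) > 1:
            cov = np.column_stack(
                [(meta[covariate_col] == lv).to_numpy(float) for lv in levels[1:]]
            )
            for b in batches:
                if meta.iloc[batch_idx[b]][covariate_col].nunique() < 2:
                    warnings.warn(
                        f"combat_adjust: batch {b} lacks both conditions "
                        "(partial confounding)"
                    )
    design = np.column_stack(design_cols + ([cov] if cov is not None else []))

    # gene-wise least squares for batch means + covariate effects
    b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    b_hat = b_hat.T                                    # genes x params
    gamma_hat_ls = b_hat[:, : len(batches)]
    grand = gamma_hat_ls @ (n_b / n_total)             # weighted grand mean
    if cov is not None:
        beta = b_hat[:, len(batches):]
        covar_fit = beta @ cov.T
    else:
        beta = None
        covar_fit = 0.0

    stand_mean = grand[:, None] + covar_fit
    # pooled variance of the fully fitted model residuals
    fitted = (design @ b_hat.T).T
    sigma2 = ((x - fitted) ** 2).mean(axis=1)
    sigma2 = np.maximum(sigma2, 1e-12)
    sd = np.sqrt(sigma2)

    z = (x - stand_mean) / sd[:, None]

    gamma_hat = np.column_stack(
        [z[:, batch_idx[b]].mean(axis=1) for b in batches]
    )
    delta2_hat = np.column_stack(
        [z[:, batch_idx[b]].var(axis=1, ddof=1) for b in batches]
    )
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    # EB hyperpriors by moment matching across genes
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_bar = delta2_hat.mean(axis=0)
    d_var = delta2_hat.var(axis=0, ddof=1)
    lam = (2 * d_var + d_bar**2) / np.maximum(d_var, 1e-12)
    theta = (d_bar * d_var + d_bar**3) / np.maximum(d_var, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iterations = {}
    for k, b in enumerate(batches):
        idx = batch_idx[b]
        n = float(len(idx))
        zb = z[:, idx]
        if mean_only:
            g_new = _postmean(gamma_hat[:, k], gamma_bar[k], n, 1.0, tau2[k])
            d_new = np.ones(len(genes))
            n_iterations[b] = 0
        else:
            g_old = gamma_hat[:, k].copy()
            d_old = delta2_hat[:, k].copy()
            count = 0
            while count < max_iter:
                g_new = _postmean(gamma_hat[:, k], gamma_bar[k], n, d_old, tau2[k])
                sum_sq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = _postvar(sum_sq, n, lam[k], theta[k])
                change = np.abs(d_new - d_old).sum()
                g_old, d_old = g_new, d_new
                count += 1
                if change < tol:
                    break
            n_iterations[b] = count
        gamma_star[:, k] = g_new
        delta2_star[:, k] = np.maximum(d_new, 1e-12)

    adjusted = z.copy()
    for k, b in enumerate(batches):
        idx = batch_idx[b]
        adjusted[:, idx] = (
            z[:, idx] - gamma_star[:, k][:, None]
        ) / np.sqrt(delta2_star[:, k])[:, None]
    adjusted = adjusted * sd[:, None] + stand_mean

    out = ExpressionDataset(
        bundle.dataset_id,
        pd.DataFrame(adjusted, index=genes, columns=bundle.expr.columns),
        bundle.meta,
    )
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=genes, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=genes, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=genes, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        lambda_=pd.Series(lam, index=batches),
        theta=pd.Series(theta, index=batches),
        alpha=pd.Series(grand, index=genes),
        sigma2=pd.Series(sigma2, index=genes),
        beta=pd.DataFrame(beta, index=genes) if beta is not None else None,
        n_iterations=n_iterations,
    )
    return out, model
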