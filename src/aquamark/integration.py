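"""Cross-platform integration via parametric empirical-Bayes batch adjustment.

The LFQ and TMT platforms measure overlapping proteins on shifted and
rescaled log2 intensity scales.  The adjustment follows the standard
parametric location/scale batch model: per-protein standardization
(after removing the grand mean and any protected covariate fit, e.g.
disease group), method-of-moments priors — normal on the per-batch
location ``gamma`` and inverse-gamma on the per-batch scale ``delta`` —
shrunken by an iterative conditional-expectation scheme, then
back-transformation.  Only proteins quantified in every batch are
integrated (the model needs complete rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters (one row per batch x protein)."""

    batches: list[str]
    grand_mean: np.ndarray  # per protein
    var_pooled: np.ndarray  # per protein
    gamma_hat: np.ndarray  # batches x proteins, raw location
    delta_hat: np.ndarray  # batches x proteins, raw scale
    gamma_star: np.ndarray  # shrunken
    delta_star: np.ndarray  # shrunken
    prior_gamma: list[tuple[float, float]] = field(default_factory=list)
    prior_delta: list[tuple[float, float]] = field(default_factory=list)
    n_iterations: list[int] = field(default_factory=list)
    dropped_proteins: list[str] = field(default_factory=list)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _shrink_batch(s_data: np.ndarray, tol: float, max_iter: int):
    """Iterative conditional-expectation shrinkage for one batch.

    ``s_data`` is proteins x samples of standardized data restricted to
    the batch.  Returns (gamma_star, delta_star, prior params, n_iter).
    """
    n = s_data.shape[1]
    gamma_hat = s_data.mean(axis=1)
    delta_hat = s_data.var(axis=1, ddof=1)
    gamma_bar = float(gamma_hat.mean())
    t2 = float(gamma_hat.var(ddof=1))
    m = float(delta_hat.mean())
    s2 = float(delta_hat.var(ddof=1))
    # inverse-gamma moment-matched hyperparameters
    a_prior = (2.0 * s2 + m**2) / s2 if s2 > 0 else 2.0
    b_prior = (m * s2 + m**3) / s2 if s2 > 0 else m
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_new = _postmean(gamma_hat, gamma_bar, n, d_old, t2)
        sum_sq = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum_sq, n, a_prior, b_prior)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, (gamma_bar, t2), (a_prior, b_prior), n_iter


def combat_adjust(
    matrix_union: pd.DataFrame,
    batch_labels: pd.Series,
    covariates: pd.DataFrame | pd.Series | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    shrink: bool = True,
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove batch location/scale effects from a proteins x samples matrix.

    ``covariates`` (e.g. the disease-group label per sample) are
    protected: their fitted contribution is removed before
    standardization and restored afterwards, so biological signal is not
    absorbed into the batch terms.  Proteins with missing values in any
    sample or zero pooled variance are dropped with a log message.
    A single batch is a no-op (a copy is returned).
    """
    batch_labels = batch_labels.reindex(matrix_union.columns)
    if batch_labels.isna().any():
        raise ValueError("every sample needs a batch label")
    batches = list(pd.unique(batch_labels))
    complete = matrix_union.dropna(axis=0)
    dropped = [str(p) for p in matrix_union.index.difference(complete.index)]
    if dropped:
        logger.info("dropping %d protein(s) not complete in all batches", len(dropped))
    if len(batches) < 2:
        model = BatchModel(
            batches=[str(b) for b in batches],
            grand_mean=complete.mean(axis=1).to_numpy(),
            var_pooled=complete.var(axis=1, ddof=1).to_numpy(),
            gamma_hat=np.zeros((1, len(complete))),
            delta_hat=np.ones((1, len(complete))),
            gamma_star=np.zeros((1, len(complete))),
            delta_star=np.ones((1, len(complete))),
            dropped_proteins=dropped,
        )
        return complete.copy(), model
    counts = batch_labels.value_counts()
    singletons = counts.index[counts < 2]
    if len(singletons):
        raise ValueError(f"singleton batch(es): {list(map(str, singletons))}")

    data = complete.to_numpy(dtype=float)  # G x N
    n_array = data.shape[1]
    batch_onehot = pd.get_dummies(batch_labels, dtype=float)[batches]
    design_parts = [batch_onehot]
    if covariates is not None:
        cov = covariates if isinstance(covariates, pd.DataFrame) else covariates.to_frame()
        cov = cov.reindex(matrix_union.columns)
        for col in cov.columns:
            series = cov[col]
            if series.dtype == object or str(series.dtype) == "category":
                design_parts.append(
                    pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
                )
            else:
                design_parts.append(series.astype(float).to_frame())
    design = pd.concat(design_parts, axis=1).to_numpy(dtype=float)  # N x P
    n_batch = len(batches)

    b_hat, *_ = np.linalg.lstsq(design, data.T, rcond=None)  # P x G
    batch_frac = (counts[batches] / n_array).to_numpy(dtype=float)
    grand_mean = batch_frac @ b_hat[:n_batch]  # per protein
    fitted = design @ b_hat  # N x G
    # residual variance with the model's degrees of freedom removed, so a
    # second (no-shrinkage) pass reproduces its input exactly
    dof = n_array - np.linalg.matrix_rank(design)
    var_pooled = ((data.T - fitted) ** 2).sum(axis=0) / max(dof, 1)

    keep = var_pooled > 0
    if not np.all(keep):
        zeroed = [str(p) for p in complete.index[~keep]]
        logger.info("dropping %d zero-variance protein(s)", len(zeroed))
        dropped += zeroed
        complete = complete.loc[keep]
        data = data[keep]
        b_hat = b_hat[:, keep]
        grand_mean = grand_mean[keep]
        var_pooled = var_pooled[keep]
        fitted = fitted[:, keep]

    # protected-covariate contribution (batch columns zeroed)
    design_cov = design.copy()
    design_cov[:, :n_batch] = 0.0
    stand_mean = grand_mean[:, None] + (design_cov @ b_hat).T  # G x N
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (data - stand_mean) / sd

    gamma_hat = np.empty((n_batch, data.shape[0]))
    delta_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(gamma_hat)
    model = BatchModel(
        batches=[str(b) for b in batches],
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        dropped_proteins=dropped,
    )
    adjusted = np.empty_like(s_data)
    for i, batch in enumerate(batches):
        cols = (batch_labels == batch).to_numpy()
        sb = s_data[:, cols]
        gamma_hat[i] = sb.mean(axis=1)
        delta_hat[i] = sb.var(axis=1, ddof=1)
        if shrink:
            g_star, d_star, prior_g, prior_d, n_iter = _shrink_batch(sb, tol, max_iter)
        else:
            g_star, d_star = gamma_hat[i].copy(), delta_hat[i].copy()
            prior_g, prior_d, n_iter = (np.nan, np.nan), (np.nan, np.nan), 0
        gamma_star[i] = g_star
        delta_star[i] = d_star
        model.prior_gamma.append(prior_g)
        model.prior_delta.append(prior_d)
        model.n_iterations.append(n_iter)
        adjusted[:, cols] = (sb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    adjusted = adjusted * sd + stand_mean
    out = pd.DataFrame(adjusted, index=complete.index, columns=complete.columns)
    return out, model


def integration_qc(
    adjusted: pd.DataFrame,
    batch_labels: pd.Series,
    group_labels: pd.Series,
    *,
    before: pd.DataFrame | None = None,
) -> dict:
    """Diagnostics for the integrated matrix.

    Per-protein one-way batch F statistic (and its p value) on the
    adjusted — and optionally pre-adjustment — data, the mean pairwise
    Pearson correlation between samples of the same group, and the top-2
    principal directions for plotting.
    """
    batch_labels = batch_labels.reindex(adjusted.columns)
    group_labels = group_labels.reindex(adjusted.columns)

    def batch_f(matrix: pd.DataFrame) -> pd.DataFrame:
        groups = [
            matrix.loc[:, (batch_labels == b).to_numpy()].to_numpy()
            for b in pd.unique(batch_labels)
        ]
        f, p = _st.f_oneway(*[g.T for g in groups], axis=0)
        return pd.DataFrame({"F": f, "p": p}, index=matrix.index)

    report: dict = {"batch_f_after": batch_f(adjusted)}
    if before is not None:
        report["batch_f_before"] = batch_f(before.loc[adjusted.index])

    corr = np.corrcoef(adjusted.to_numpy().T)
    within = []
    cols = list(adjusted.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if group_labels.iloc[i] == group_labels.iloc[j]:
                within.append(corr[i, j])
    report["mean_within_group_correlation"] = float(np.mean(within)) if within else np.nan

    centered = adjusted.to_numpy() - adjusted.to_numpy().mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    report["pc_scores"] = pd.DataFrame(
        (vt[:2].T * s[:2]), index=adjusted.columns, columns=["PC1", "PC2"]
    )
    report["pc_variance_fraction"] = (s[:2] ** 2 / (s**2).sum()).tolist()
    return report
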