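"""Cross-cohort harmonization of expression matrices.

Expression from different sequencing efforts is made comparable in two steps:
each sample's gene expression values are replaced by within-sample gene ranks
(which removes library-size and per-sample distributional differences and is
invariant to any strictly monotone per-sample transform), and the rank matrix
is then adjusted for residual per-gene cohort effects with a parametric
empirical-Bayes location/scale model (the ComBat algorithm): per-gene batch
means and variances are estimated, shrunk toward common batch-level priors
(normal prior on the location, inverse-gamma prior on the scale), and removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["rank_transform", "combat_adjust", "BatchEffectModel"]


def rank_transform(x: pd.DataFrame) -> pd.DataFrame:
    """Convert a gene-by-sample expression matrix to per-sample gene ranks.

    Within each sample (column) the gene with the smallest value receives
    rank 1 and ties receive the average of their rank span, so each column of
    the result sums to G(G+1)/2 for G genes. Gene and sample order are
    preserved.

    Parameters
    ----------
    x
        Nonnegative gene-by-sample matrix with unique gene and sample ids.

    Returns
    -------
    DataFrame of the same shape holding ranks in 1..G (tied averages).
    """
    if x.shape[0] < 2:
        raise ValueError("rank_transform requires at least 2 genes")
    if x.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    if x.index.has_duplicates or x.columns.has_duplicates:
        raise ValueError("gene and sample identifiers must be unique")
    return x.rank(axis=0, method="average")


@dataclass
class BatchEffectModel:
    """Fitted per-gene location/scale batch model.

    Holds the grand mean and pooled variance used for standardization, the
    raw per-gene batch estimates (``gamma_hat``, ``delta2_hat``) and their
    empirical-Bayes posterior means (``gamma_star``, ``delta2_star``), plus
    the batch-level hyperparameters of the normal / inverse-gamma priors.
    """

    batches: list
    grand_mean: np.ndarray          # per gene
    pooled_var: np.ndarray          # per gene
    gamma_hat: np.ndarray           # genes x batches
    delta2_hat: np.ndarray          # genes x batches
    gamma_star: np.ndarray          # genes x batches
    delta2_star: np.ndarray         # genes x batches
    gamma_bar: np.ndarray           # per batch (normal prior mean)
    tau2: np.ndarray                # per batch (normal prior variance)
    a_prior: np.ndarray             # per batch (inverse-gamma shape)
    b_prior: np.ndarray             # per batch (inverse-gamma scale)
    n_iter: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    floored_genes: list = field(default_factory=list)


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = float(np.mean(delta2)), float(np.var(delta2, ddof=1))
    if s2 == 0:  # degenerate prior; handled downstream by skipping shrinkage
        return np.inf
    return (2.0 * s2 + m * m) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = float(np.mean(delta2)), float(np.var(delta2, ddof=1))
    if s2 == 0:
        return np.inf
    return (m * s2 + m ** 3) / s2


def _eb_iterate(z_b, gamma_hat, delta2_hat, gamma_bar, tau2, a, b,
                conv: float, max_iter: int):
    """Iterate the coupled posterior-mean updates for one batch to a fixed
    point; mirrors the standard parametric empirical-Bayes solution.

    A degenerate scale prior (all per-gene variance estimates identical, so
    the inverse-gamma moment estimators are undefined) disables shrinkage of
    the scale: the raw estimates are kept and only the location is updated.
    """
    n = z_b.shape[1]
    degenerate_scale = not (np.isfinite(a) and np.isfinite(b))
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        if degenerate_scale:
            d_new = delta2_hat.copy()
        else:
            sum2 = ((z_b - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        denom_g = np.where(np.abs(g_old) > 1e-12, np.abs(g_old), 1e-12)
        change = max(np.max(np.abs(g_new - g_old) / denom_g),
                     np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def combat_adjust(
    r: pd.DataFrame,
    batches,
    *,
    conv: float = 1e-4,
    max_iter: int = 100,
    var_floor: float = 1e-8,
    return_model: bool = False,
):
    """Remove per-gene batch location/scale effects by empirical Bayes.

    Per gene, the data are standardized by the grand mean (sample-size
    weighted mean of batch means) and the pooled residual variance; batch
    location (``gamma``) and scale (``delta^2``) are estimated on the
    standardized data, shrunk to their parametric posterior means under a
    normal / inverse-gamma prior whose hyperparameters are estimated across
    genes within each batch, and divided out; the result is transformed back
    to the original frame's mean and variance.

    Parameters
    ----------
    r
        Gene-by-sample matrix (typically per-sample gene ranks).
    batches
        Batch label per sample, aligned with ``r``'s columns (a sequence or
        a Series indexed by sample id).
    conv, max_iter
        Relative-change tolerance and iteration cap for the coupled
        posterior updates.
    var_floor
        Genes with zero variance within a batch have their scale estimate
        floored here and are flagged on the model.
    return_model
        Also return the fitted :class:`BatchEffectModel`.

    Returns
    -------
    Adjusted matrix (same shape/labels), or ``(adjusted, model)``.
    """
    batches = pd.Series(np.asarray(batches), index=r.columns)
    if batches.isna().any():
        raise ValueError("every sample must carry a batch label")
    levels = sorted(batches.unique().tolist())
    counts = batches.value_counts()
    singletons = [b for b in levels if counts[b] < 2]
    if singletons:
        raise ValueError(
            f"batches with a single sample cannot be adjusted: {singletons}"
        )
    if len(levels) == 1:
        warnings.warn(
            "only one batch present; returning input unchanged", stacklevel=2
        )
        return (r.copy(), None) if return_model else r.copy()

    x = r.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    n_genes, n_samples = x.shape
    idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}
    n_b = np.array([len(idx[b]) for b in levels], dtype=float)

    # standardization: weighted grand mean, pooled residual variance (1/N)
    batch_means = np.column_stack([x[:, idx[b]].mean(axis=1) for b in levels])
    grand_mean = batch_means @ (n_b / n_samples)
    fitted = np.empty_like(x)
    for j, b in enumerate(levels):
        fitted[:, idx[b]] = batch_means[:, [j]]
    pooled_var = ((x - fitted) ** 2).mean(axis=1)
    floored = np.flatnonzero(pooled_var < var_floor)
    if floored.size:
        logger.warning("flooring pooled variance for %d gene(s)", floored.size)
        pooled_var = np.maximum(pooled_var, var_floor)
    z = (x - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    gamma_hat = np.column_stack([z[:, idx[b]].mean(axis=1) for b in levels])
    delta2_hat = np.column_stack(
        [z[:, idx[b]].var(axis=1, ddof=1) for b in levels]
    )
    zero_var = np.flatnonzero((delta2_hat < var_floor).any(axis=1))
    delta2_hat = np.maximum(delta2_hat, var_floor)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.array([_aprior(delta2_hat[:, j]) for j in range(len(levels))])
    b_prior = np.array([_bprior(delta2_hat[:, j]) for j in range(len(levels))])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iters = np.zeros(len(levels), dtype=int)
    for j, b in enumerate(levels):
        gamma_star[:, j], delta2_star[:, j], iters[j] = _eb_iterate(
            z[:, idx[b]], gamma_hat[:, j], delta2_hat[:, j],
            gamma_bar[j], tau2[j], a_prior[j], b_prior[j], conv, max_iter,
        )
    delta2_star = np.maximum(delta2_star, var_floor)

    adj = np.empty_like(z)
    for j, b in enumerate(levels):
        adj[:, idx[b]] = (
            (z[:, idx[b]] - gamma_star[:, [j]]) / np.sqrt(delta2_star[:, [j]])
        )
    out = adj * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]
    adjusted = pd.DataFrame(out, index=r.index, columns=r.columns)

    if not return_model:
        return adjusted
    model = BatchEffectModel(
        batches=levels,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=iters,
        floored_genes=sorted(
            set(r.index[floored]) | set(r.index[zero_var])
        ),
    )
    return adjusted, model
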