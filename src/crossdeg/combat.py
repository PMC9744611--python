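"""Location/scale batch-effect adjustment with parametric empirical Bayes.

ComBat-style procedure on a log-scale expression matrix: per-gene
standardization (retaining the case/control signal as a protected covariate
by default), per-batch location and scale estimates, parametric shrinkage of
those estimates across genes (normal prior on locations, inverse-gamma prior
on scales, hyperparameters by method of moments), then adjustment and
back-transformation restoring the grand mean and covariate effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import validate_metadata

_CONV = 1e-4
_MAX_ITER = 100


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch: np.ndarray, g_hat, d_hat, g_bar, t2, a, b) -> tuple[np.ndarray, np.ndarray]:
    """Coupled EB updates for one batch's location/scale, iterated to convergence."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(_MAX_ITER):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < _CONV:
            break
    return g_old, d_old


def combat_adjust(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    protect_group: bool = True,
) -> pd.DataFrame:
    """Remove per-batch location/scale effects from ``matrix``.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples, log2 scale.
    meta : DataFrame
        Sample metadata with ``sample_id``, ``group`` and ``batch`` columns;
        every matrix column must appear exactly once.
    protect_group : bool
        Keep case/control as a covariate during standardization so the
        biological signal is not absorbed into the batch estimates.

    A single batch is a no-op (the empirical-Bayes machinery is degenerate
    there).  Every batch must contain at least two samples; with
    ``protect_group`` the group must not be perfectly confounded with batch.
    """
    validate_metadata(meta, matrix)
    meta = meta.set_index("sample_id").loc[list(matrix.columns)]
    batches = meta["batch"].to_numpy()
    batch_levels = list(pd.unique(batches))
    n_batch = len(batch_levels)
    if n_batch == 1:
        return matrix.copy()

    counts = pd.Series(batches).value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(
            f"combat_adjust: batch(es) with fewer than 2 samples: {singletons.index.tolist()}"
        )

    y = matrix.to_numpy(float)  # genes x samples
    n_samples = y.shape[1]
    batch_onehot = np.stack([(batches == b).astype(float) for b in batch_levels], axis=1)
    design_cols = [batch_onehot]
    if protect_group:
        group = (meta["group"].to_numpy() == "case").astype(float)
        design = np.column_stack([batch_onehot, group])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "combat_adjust: case/control status is confounded with batch; "
                "cannot protect the group effect"
            )
        design_cols.append(group[:, None])
    design = np.column_stack(design_cols)

    # gene-wise least squares for batch + covariate effects
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (p, genes)
    batch_sizes = batch_onehot.sum(axis=0)
    grand = (batch_sizes / n_samples) @ beta[:n_batch]  # per-gene grand mean
    fitted = (design @ beta).T
    var_pooled = ((y - fitted) ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand[:, None], (1, n_samples))
    if protect_group:
        stand_mean = stand_mean + np.outer(beta[n_batch], group)  # genes x samples
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(z)
    for j, b in enumerate(batch_levels):
        cols = batches == b
        zb = z[:, cols]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        adjusted[:, cols] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
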