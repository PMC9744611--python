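"""Cross-projection and Spearman-based direction inference.

Held-out patients of one disease are scored by both diseases' encoders; the
Spearman rank correlation between the two pseudogene score vectors gives the
direction of the transcriptomic association.  The counterfactual score — a
patient of disease A pushed through the encoder trained on disease B — tracks
how the disease-B dysregulation axis responds to disease-A severity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .autoencoder import TrainedEncoder


@dataclass
class AssociationResult:
    """Spearman correlation of paired pseudogene scores and the direction call."""

    cohort: str
    n: int
    rho: float
    p: float
    alpha: float
    direction: str  # positive | inverse | indeterminate

    def __str__(self) -> str:
        return (
            f"cohort {self.cohort}: rho = {self.rho:.3f}, p = {self.p:.3g} "
            f"(n = {self.n}) -> {self.direction}"
        )


def cross_project(
    enc_a: TrainedEncoder,
    enc_b: TrainedEncoder,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    split: pd.Series,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Score held-out samples of one cohort under both encoders.

    Returns a DataFrame indexed by sample_id with columns ``score_a`` and
    ``score_b``.  By default only held-out cases are scored (the association
    is evaluated among patients); ``include_controls`` adds the held-out
    controls for sensitivity analysis.
    """
    groups = meta.set_index("sample_id")["group"]
    ids = [
        s
        for s in split.index
        if split.loc[s] == "holdout"
        and s in matrix.columns
        and (include_controls or groups.loc[s] == "case")
    ]
    if not ids:
        raise ValueError("cross_project: no held-out samples to score")
    sub = matrix[ids]
    return pd.DataFrame(
        {"score_a": enc_a.encode(sub), "score_b": enc_b.encode(sub)}, index=pd.Index(ids, name="sample_id")
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for small n (enumerates n! orders)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(np.mean(rx[list(perm)] * ry))
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman(x, y, p_method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  ``p_method="t"`` uses the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n - 2 df; ``"exact"``
    enumerates all rank permutations (only sensible for n < 10).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("spearman: input vectors must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"spearman: need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman: correlation undefined for a constant input vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if p_method == "exact":
        if n > 9:
            raise ValueError("spearman: exact permutation p only supported for n <= 9")
        return rho, _exact_spearman_p(x, y, rho)
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def infer_direction(
    rho: float, p: float, n: int, alpha: float = 0.05, cohort: str = ""
) -> AssociationResult:
    """Direction call: positive / inverse when significant at ``alpha``."""
    if p < alpha and rho > 0:
        direction = "positive"
    elif p < alpha and rho < 0:
        direction = "inverse"
    else:
        direction = "indeterminate"
    return AssociationResult(cohort=cohort, n=n, rho=rho, p=p, alpha=alpha, direction=direction)


def associate(
    scores: pd.DataFrame, alpha: float = 0.05, cohort: str = "", p_method: str = "t"
) -> AssociationResult:
    """Spearman + direction call on a paired score table from cross_project.

    A degenerate (constant) score vector — e.g. a counterfactual projection
    saturating the encoder — yields an indeterminate call with rho = nan
    rather than an error, so a pipeline run always produces a report.
    """
    x = np.asarray(scores["score_a"], float)
    y = np.asarray(scores["score_b"], float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            cohort=cohort, n=len(scores), rho=float("nan"), p=float("nan"),
            alpha=alpha, direction="indeterminate",
        )
    rho, p = spearman(x, y, p_method=p_method)
    return infer_direction(rho, p, n=len(scores), alpha=alpha, cohort=cohort)


def plot_association(scores: pd.DataFrame, result: AssociationResult, path, labels=("encoder A", "encoder B")):
    """Scatter of the paired pseudogene scores with rho/p annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(scores["score_a"], scores["score_b"], s=18, alpha=0.8, edgecolor="none")
    ax.set_xlabel(f"pseudogene score ({labels[0]})")
    ax.set_ylabel(f"pseudogene score ({labels[1]})")
    ax.set_title(
        f"{result.cohort}: Spearman rho = {result.rho:.3f}, p = {result.p:.2g}", fontsize=10
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
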