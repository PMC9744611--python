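"""Two-group differential expression with empirical-Bayes moderated t-tests.

Per-gene pooled-variance fits, moment-matched estimation of the variance
prior (d0, s0^2) from the distribution of log sample variances, moderated
t-statistics with d0 + d_g degrees of freedom, Benjamini-Hochberg adjustment,
threshold-based DEG calls, and cross-cohort overlap/direction classification.

The moderated statistic shrinks each gene's pooled variance toward a prior:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t~_g   = logFC_g / (s~_g * sqrt(1/n_case + 1/n_control))

with ``logFC = mean(case) - mean(control)`` on log2 values throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import validate_metadata

FDR_CUTOFF = 0.05
LFC_CUTOFF = 0.5


@dataclass(frozen=True)
class VariancePrior:
    """Prior degrees of freedom (possibly infinite) and prior variance."""

    d0: float
    s02: float

    def __post_init__(self):
        # d0 = 0 is the no-moderation limit (ordinary pooled t)
        if not self.d0 >= 0:
            raise ValueError(f"VariancePrior.d0 must be >= 0, got {self.d0}")
        if not self.s02 > 0:
            raise ValueError(f"VariancePrior.s02 must be > 0, got {self.s02}")


def _groups(matrix: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    validate_metadata(meta, matrix)
    cases = meta.loc[meta["group"] == "case", "sample_id"]
    controls = meta.loc[meta["group"] == "control", "sample_id"]
    for name, ids in (("case", cases), ("control", controls)):
        if len(ids) < 2:
            raise ValueError(f"fit_two_group: {name} group has {len(ids)} sample(s); need >= 2")
    return matrix[list(cases)], matrix[list(controls)]


def fit_two_group(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene logFC, pooled residual variance and residual df.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``s2``,
    ``df``, ``n_case``, ``n_control``.
    """
    x_case, x_ctrl = _groups(matrix, meta)
    n1, n2 = x_case.shape[1], x_ctrl.shape[1]
    logfc = x_case.mean(axis=1) - x_ctrl.mean(axis=1)
    ss = x_case.sub(x_case.mean(axis=1), axis=0).pow(2).sum(axis=1) + x_ctrl.sub(
        x_ctrl.mean(axis=1), axis=0
    ).pow(2).sum(axis=1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {"logFC": logfc, "s2": ss / df, "df": df, "n_case": n1, "n_control": n2}
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    root is unique.  Newton steps on the reciprocal scale converge
    monotonically from the large-y asymptote x ~ 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_variance_prior(fits: pd.DataFrame) -> VariancePrior:
    """Moment-match the variance prior from the spread of log sample variances.

    Under the hierarchical model s_g^2 ~ s0^2 * chi^2_{d_g}/d_g scaled by an
    inverse-chi-square prior, ``log s_g^2`` is distributed as a constant plus
    the difference of two log-chi-square variables, so

        var(log s^2) = trigamma(d_g/2) + trigamma(d0/2).

    The excess of the empirical variance of ``log s^2`` over
    ``trigamma(d_g/2)`` is inverted through the (monotone) trigamma to give
    d0; the mean of ``log s^2`` then gives s0^2 through digamma terms.  Zero
    or negative excess yields d0 = +inf (no between-gene variance
    heterogeneity beyond sampling noise).
    """
    usable = fits.loc[fits["s2"] > 0]
    if len(usable) < 2:
        raise ValueError(
            f"estimate_variance_prior: need >= 2 genes with positive variance, got {len(usable)}"
        )
    dg = float(usable["df"].iloc[0])
    e = np.log(usable["s2"].to_numpy()) - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s02=math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s02 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return VariancePrior(d0=d0, s02=s02)


def moderated_t_table(
    fits: pd.DataFrame, prior: VariancePrior, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Moderated t and two-sided p per gene (no thresholds applied yet).

    Degenerate cases: a gene with posterior variance 0 and nonzero logFC gets
    t = +/-inf and p = 0; with logFC = 0 it gets t = 0, p = 1.
    """
    logfc = fits["logFC"].to_numpy(float)
    s2 = fits["s2"].to_numpy(float)
    dg = fits["df"].to_numpy(float)
    n1 = fits["n_case"].to_numpy(float)
    n2 = fits["n_control"].to_numpy(float)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s02)
        df_total = np.full_like(dg, np.inf)
    else:
        s2_post = (prior.d0 * prior.s02 + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.sign(logfc) * np.inf)
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0, np.minimum(p, 1.0), p)
    return pd.DataFrame({"logFC": logfc, "t": t, "p": p}, index=fits.index)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    fdr_cutoff: float = FDR_CUTOFF,
    lfc_cutoff: float = LFC_CUTOFF,
) -> pd.DataFrame:
    """Add ``fdr`` (if missing) and a direction call to a moderated-t table.

    ``up`` requires fdr < cutoff and logFC >= lfc_cutoff; ``down`` requires
    fdr < cutoff and logFC <= -lfc_cutoff; everything else is ``none``.
    """
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"])
    sig = out["fdr"] < fdr_cutoff
    direction = np.where(
        sig & (out["logFC"] >= lfc_cutoff),
        "up",
        np.where(sig & (out["logFC"] <= -lfc_cutoff), "down", "none"),
    )
    out["direction"] = direction
    return out


def deg_table(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_cutoff: float = FDR_CUTOFF,
    lfc_cutoff: float = LFC_CUTOFF,
) -> pd.DataFrame:
    """Convenience: fit, moderate, adjust and call in one step."""
    fits = fit_two_group(matrix, meta)
    prior = estimate_variance_prior(fits)
    table = moderated_t_table(fits, prior, meta)
    return call_degs(table, fdr_cutoff, lfc_cutoff)


@dataclass
class OverlapClassification:
    """Shared DEGs of two cohorts classified by direction pair."""

    table: pd.DataFrame  # gene, dir_A, dir_B, class
    n_co_up: int
    n_co_down: int
    n_inverse: int

    @property
    def n_shared(self) -> int:
        return self.n_co_up + self.n_co_down + self.n_inverse

    @property
    def concordant_fraction(self) -> float:
        if self.n_shared == 0:
            return float("nan")
        return (self.n_co_up + self.n_co_down) / self.n_shared


def classify_overlap(deg_a: pd.DataFrame, deg_b: pd.DataFrame) -> OverlapClassification:
    """Classify genes called in both cohorts as co-up, co-down or inverse."""
    a = deg_a.loc[deg_a["direction"] != "none", "direction"]
    b = deg_b.loc[deg_b["direction"] != "none", "direction"]
    shared = sorted(set(a.index) & set(b.index))
    rows = []
    for g in shared:
        da, db = a.loc[g], b.loc[g]
        cls = "co-up" if (da, db) == ("up", "up") else "co-down" if (da, db) == ("down", "down") else "inverse"
        rows.append((g, da, db, cls))
    table = pd.DataFrame(rows, columns=["gene", "dir_A", "dir_B", "class"]).set_index("gene")
    counts = table["class"].value_counts() if len(table) else pd.Series(dtype=int)
    return OverlapClassification(
        table=table,
        n_co_up=int(counts.get("co-up", 0)),
        n_co_down=int(counts.get("co-down", 0)),
        n_inverse=int(counts.get("inverse", 0)),
    )
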