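"""Synthetic paired case/control cohorts with a planted association sign.

The generator emulates the statistical structure the downstream pipeline
assumes: two cohorts measured on a common gene universe, a subset of genes
dysregulated in each cohort (some shared between the cohorts, concordantly or
inversely), additive per-study batch effects, and a continuous per-sample
latent severity ``z`` that drives the dysregulation.

The generative model for sample ``i`` of cohort ``c`` is

    x_gi = mu_g + lambda_g^c * z_i + gamma_{g, b(i)} + eps_gi

with ``z_i ~ Normal(case_latent_mean * 1[case], latent_sd^2)``,
``eps_gi ~ Normal(0, noise_sd^2)`` and a shared per-gene baseline
``mu_g ~ Normal(7, 1)`` (log2 scale).  The true association sign is the sign
of ``sum_g lambda_g^A * lambda_g^B`` over the shared dysregulated genes, so
``frac_concordant = 1`` plants a positive association and ``0`` an inverse
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SyntheticConfig:
    """Parameters of the paired-cohort generator.

    Defaults describe a moderately sized two-study comparison: 2,000 genes,
    200 shared dysregulated genes plus 100 private ones per cohort, unit
    latent loadings (log2 units), a one-unit case shift on the latent
    severity, three batches per cohort and microarray-like residual noise.
    """

    n_genes: int = 2000
    n_shared_deg: int = 200
    frac_concordant: float = 0.5
    n_private_deg_per_cohort: int = 100
    effect_sd: float = 1.0
    case_latent_mean: float = 1.0
    latent_sd: float = 0.5
    n_batches_per_cohort: int = 3
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.0  # lognormal sd of a per-batch residual scale factor
    noise_sd: float = 1.0
    n_cases: int = 60
    n_controls: int = 60
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": (self.n_genes, 1),
            "n_shared_deg": (self.n_shared_deg, 0),
            "n_private_deg_per_cohort": (self.n_private_deg_per_cohort, 0),
            "n_batches_per_cohort": (self.n_batches_per_cohort, 1),
            "n_cases": (self.n_cases, 1),
            "n_controls": (self.n_controls, 1),
        }
        for name, (value, lo) in counts.items():
            if int(value) != value or value < lo:
                raise ValueError(f"SyntheticConfig.{name} must be an integer >= {lo}, got {value}")
        if not 0.0 <= self.frac_concordant <= 1.0:
            raise ValueError(
                f"SyntheticConfig.frac_concordant must be in [0, 1], got {self.frac_concordant}"
            )
        if self.n_shared_deg + 2 * self.n_private_deg_per_cohort > self.n_genes:
            raise ValueError(
                "SyntheticConfig: n_shared_deg + 2 * n_private_deg_per_cohort "
                f"({self.n_shared_deg} + 2*{self.n_private_deg_per_cohort}) exceeds n_genes "
                f"({self.n_genes})"
            )
        for name in ("effect_sd", "latent_sd", "batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"SyntheticConfig.{name} must be >= 0, got {getattr(self, name)}")


def _directions(loadings: pd.Series) -> pd.Series:
    out = pd.Series("none", index=loadings.index, dtype=object)
    out[loadings > 0] = "up"
    out[loadings < 0] = "down"
    return out


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort pair."""

    loadings_a: pd.Series
    loadings_b: pd.Series
    batch_offsets: pd.DataFrame  # genes x batch ids (both cohorts' batches)
    latent_a: pd.Series = field(repr=False, default=None)
    latent_b: pd.Series = field(repr=False, default=None)
    config: SyntheticConfig | None = None

    @property
    def planted_direction_a(self) -> pd.Series:
        return _directions(self.loadings_a)

    @property
    def planted_direction_b(self) -> pd.Series:
        return _directions(self.loadings_b)

    @property
    def shared_genes(self) -> pd.Index:
        both = (self.loadings_a != 0) & (self.loadings_b != 0)
        return self.loadings_a.index[both]

    @property
    def true_sign(self) -> int:
        dot = float((self.loadings_a * self.loadings_b).sum())
        return int(np.sign(dot))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config) if self.config else None,
            "true_sign": self.true_sign,
            "loadings_a": self.loadings_a.round(6).to_dict(),
            "loadings_b": self.loadings_b.round(6).to_dict(),
            "batch_offsets": self.batch_offsets.round(6).to_dict(),
            "latent_a": self.latent_a.round(6).to_dict(),
            "latent_b": self.latent_b.round(6).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _simulate_cohort(
    cohort: str,
    mu: np.ndarray,
    loadings: np.ndarray,
    genes: pd.Index,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    n = cfg.n_cases + cfg.n_controls
    is_case = np.r_[np.ones(cfg.n_cases, bool), np.zeros(cfg.n_controls, bool)]
    sample_ids = [
        f"{cohort}_{'case' if c else 'ctrl'}_{i:03d}"
        for i, c in zip(np.r_[np.arange(cfg.n_cases), np.arange(cfg.n_controls)], is_case)
    ]
    batch_names = [f"{cohort}{b + 1}" for b in range(cfg.n_batches_per_cohort)]
    batch_of = np.array([batch_names[i % cfg.n_batches_per_cohort] for i in range(n)])

    z = rng.normal(cfg.case_latent_mean * is_case, cfg.latent_sd)
    gamma = rng.normal(0.0, cfg.batch_shift_sd, size=(len(genes), cfg.n_batches_per_cohort))
    scale = (
        np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=cfg.n_batches_per_cohort))
        if cfg.batch_scale_sd > 0
        else np.ones(cfg.n_batches_per_cohort)
    )
    eps = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    b_idx = np.array([batch_names.index(b) for b in batch_of])
    x = (
        mu[:, None]
        + loadings[:, None] * z[None, :]
        + gamma[:, b_idx]
        + eps * scale[b_idx][None, :]
    )
    expr = pd.DataFrame(x, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort,
            "group": np.where(is_case, "case", "control"),
            "batch": batch_of,
        }
    )
    offsets = pd.DataFrame(gamma, index=genes, columns=batch_names)
    return expr, meta, offsets, pd.Series(z, index=sample_ids, name="latent")


def generate_cohort_pair(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate two case/control cohorts over one gene universe.

    Returns ``(expr_a, meta_a, expr_b, meta_b, truth)``.  Samples are assigned
    round-robin to batches within each cohort.  Bit-reproducible for a given
    config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)], name="gene")

    mu = rng.normal(7.0, 1.0, size=config.n_genes)

    lam_a = np.zeros(config.n_genes)
    lam_b = np.zeros(config.n_genes)
    deg_idx = rng.permutation(config.n_genes)
    shared = deg_idx[: config.n_shared_deg]
    priv_a = deg_idx[config.n_shared_deg : config.n_shared_deg + config.n_private_deg_per_cohort]
    priv_b = deg_idx[
        config.n_shared_deg
        + config.n_private_deg_per_cohort : config.n_shared_deg
        + 2 * config.n_private_deg_per_cohort
    ]

    def magnitudes(k: int) -> np.ndarray:
        return config.effect_sd * rng.uniform(0.8, 1.2, size=k)

    sign_a = rng.choice([-1.0, 1.0], size=config.n_shared_deg)
    n_conc = int(round(config.frac_concordant * config.n_shared_deg))
    conc = np.zeros(config.n_shared_deg, bool)
    conc[rng.permutation(config.n_shared_deg)[:n_conc]] = True
    sign_b = np.where(conc, sign_a, -sign_a)
    lam_a[shared] = sign_a * magnitudes(config.n_shared_deg)
    lam_b[shared] = sign_b * magnitudes(config.n_shared_deg)
    lam_a[priv_a] = rng.choice([-1.0, 1.0], size=priv_a.size) * magnitudes(priv_a.size)
    lam_b[priv_b] = rng.choice([-1.0, 1.0], size=priv_b.size) * magnitudes(priv_b.size)

    expr_a, meta_a, off_a, z_a = _simulate_cohort("A", mu, lam_a, genes, config, rng)
    expr_b, meta_b, off_b, z_b = _simulate_cohort("B", mu, lam_b, genes, config, rng)

    truth = SyntheticTruth(
        loadings_a=pd.Series(lam_a, index=genes, name="loading_a"),
        loadings_b=pd.Series(lam_b, index=genes, name="loading_b"),
        batch_offsets=pd.concat([off_a, off_b], axis=1),
        latent_a=z_a,
        latent_b=z_b,
        config=config,
    )
    return expr_a, meta_a, expr_b, meta_b, truth
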