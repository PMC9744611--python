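"""Model/Results facade for the full cross-disease association analysis.

:class:`CrossDiseaseModel` is constructed from two case/control cohorts on a
common gene universe; :meth:`CrossDiseaseModel.fit` runs batch adjustment,
DEG calling, overlap classification, feature selection, the two autoencoder
trainings, cross-projection and the Spearman direction call, and returns a
:class:`CrossDiseaseResults` carrying every intermediate plus a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import degs as _degs
from .association import AssociationResult, associate, cross_project, plot_association
from .autoencoder import AeConfig, HyperGrid, TrainedEncoder, fit_encoder, fit_standardizer, grid_search, split_train_holdout
from .combat import combat_adjust
from .degs import OverlapClassification
from .enrichment import hypergeom_ora
from .io import align_cohorts, validate_expression, validate_metadata


@dataclass
class CrossDiseaseResults:
    """Fitted artifacts of a cross-disease association analysis."""

    model: "CrossDiseaseModel" = field(repr=False)
    deg_a: pd.DataFrame = field(repr=False, default=None)
    deg_b: pd.DataFrame = field(repr=False, default=None)
    overlap: OverlapClassification = None
    feature_genes_a: list[str] = None
    feature_genes_b: list[str] = None
    encoder_a: TrainedEncoder = field(repr=False, default=None)
    encoder_b: TrainedEncoder = field(repr=False, default=None)
    split_a: pd.Series = field(repr=False, default=None)
    split_b: pd.Series = field(repr=False, default=None)
    scores_a: pd.DataFrame = field(repr=False, default=None)  # cohort A holdout cases
    scores_b: pd.DataFrame = field(repr=False, default=None)
    association_a: AssociationResult = None
    association_b: AssociationResult = None

    @property
    def direction(self) -> str:
        """Consensus direction: the two per-cohort calls if they agree,
        otherwise the significant one, otherwise indeterminate."""
        calls = {self.association_a.direction, self.association_b.direction}
        calls.discard("indeterminate")
        if len(calls) == 1:
            return calls.pop()
        return "indeterminate"

    def summary(self) -> str:
        ov = self.overlap
        lines = [
            "Cross-disease transcriptomic association",
            "=" * 56,
            f"cohort A DEGs: {int((self.deg_a['direction'] != 'none').sum())} "
            f"(up {int((self.deg_a['direction'] == 'up').sum())}, "
            f"down {int((self.deg_a['direction'] == 'down').sum())})",
            f"cohort B DEGs: {int((self.deg_b['direction'] != 'none').sum())} "
            f"(up {int((self.deg_b['direction'] == 'up').sum())}, "
            f"down {int((self.deg_b['direction'] == 'down').sum())})",
            f"shared DEGs: {ov.n_shared} (co-up {ov.n_co_up}, co-down {ov.n_co_down}, "
            f"inverse {ov.n_inverse}; concordant fraction {ov.concordant_fraction:.2f})",
            f"feature genes: A {len(self.feature_genes_a)}, B {len(self.feature_genes_b)}",
            "-" * 56,
            str(self.association_a),
            str(self.association_b),
            "-" * 56,
            f"direction of association: {self.direction}",
        ]
        return "\n".join(lines)

    def plot_scores(self, cohort: str, path) -> None:
        scores, result = (
            (self.scores_a, self.association_a) if cohort == "A" else (self.scores_b, self.association_b)
        )
        plot_association(scores, result, path)


class CrossDiseaseModel:
    """Dual-autoencoder direction-of-association model for two cohorts.

    Parameters
    ----------
    expr_a, meta_a, expr_b, meta_b
        Gene x sample log2 expression and metadata for the two cohorts.
    adjust_batches : bool
        Run per-cohort ComBat before the DEG stage (skipped automatically
        for single-batch cohorts).
    fdr_cutoff, lfc_cutoff
        DEG thresholds (defaults 0.05 and 0.5).
    feature_set : {"shared-degs", "pathway-genes"}
        Genes the autoencoders are trained on: the shared DEGs of the two
        cohorts, or each cohort's enriched-pathway genes (requires
        ``gene_sets``).
    gene_sets : dict, optional
        Name -> member set, for the pathway-genes variant.
    ae_config : AeConfig
        Autoencoder hyperparameters; ``grid`` instead runs a grid search.
    alpha : float
        Significance level of the direction call.
    split_seed, train_seed : int
        Seeds of the 3:2 split and the network initialization/training.
    """

    def __init__(
        self,
        expr_a: pd.DataFrame,
        meta_a: pd.DataFrame,
        expr_b: pd.DataFrame,
        meta_b: pd.DataFrame,
        *,
        adjust_batches: bool = True,
        protect_group: bool = True,
        fdr_cutoff: float = 0.05,
        lfc_cutoff: float = 0.5,
        feature_set: str = "shared-degs",
        gene_sets: dict[str, set[str]] | None = None,
        ora_fdr_cutoff: float = 0.2,
        ae_config: AeConfig | None = None,
        grid: HyperGrid | None = None,
        alpha: float = 0.05,
        include_controls: bool = False,
        split_seed: int = 0,
        train_seed: int = 0,
    ):
        validate_expression(expr_a, "cohort A")
        validate_expression(expr_b, "cohort B")
        validate_metadata(meta_a, expr_a)
        validate_metadata(meta_b, expr_b)
        if feature_set not in ("shared-degs", "pathway-genes"):
            raise ValueError(f"unknown feature_set {feature_set!r}")
        if feature_set == "pathway-genes" and not gene_sets:
            raise ValueError("feature_set='pathway-genes' requires gene_sets")
        self.expr_a, self.expr_b = align_cohorts(expr_a, expr_b)
        self.meta_a, self.meta_b = meta_a, meta_b
        self.adjust_batches = adjust_batches
        self.protect_group = protect_group
        self.fdr_cutoff, self.lfc_cutoff = fdr_cutoff, lfc_cutoff
        self.feature_set = feature_set
        self.gene_sets = gene_sets
        self.ora_fdr_cutoff = ora_fdr_cutoff
        self.ae_config = ae_config or AeConfig()
        self.grid = grid
        self.alpha = alpha
        self.include_controls = include_controls
        self.split_seed = split_seed
        self.train_seed = train_seed

    @classmethod
    def from_tsv(cls, expr_a, meta_a, expr_b, meta_b, **kwargs) -> "CrossDiseaseModel":
        from .io import read_expression

        ea, ma = read_expression(expr_a, meta_a)
        eb, mb = read_expression(expr_b, meta_b)
        return cls(ea, ma, eb, mb, **kwargs)

    # -- stages ------------------------------------------------------------

    def _maybe_adjust(self, expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
        if not self.adjust_batches or meta["batch"].nunique() < 2:
            return expr
        return combat_adjust(expr, meta, protect_group=self.protect_group)

    def _pathway_genes(self, deg: pd.DataFrame, universe) -> list[str]:
        hits = deg.index[deg["direction"] != "none"]
        table = hypergeom_ora(hits, self.gene_sets, universe, fdr_cutoff=self.ora_fdr_cutoff)
        significant = table.loc[table["significant"], "set"]
        members: set[str] = set()
        for name in significant:
            members |= self.gene_sets[name]
        selected = sorted(members & set(universe))
        if not selected:
            raise ValueError("pathway-genes feature set is empty (no enriched set)")
        return selected

    def fit(self) -> CrossDiseaseResults:
        res = CrossDiseaseResults(model=self)

        adj_a = self._maybe_adjust(self.expr_a, self.meta_a)
        adj_b = self._maybe_adjust(self.expr_b, self.meta_b)

        res.deg_a = _degs.deg_table(adj_a, self.meta_a, self.fdr_cutoff, self.lfc_cutoff)
        res.deg_b = _degs.deg_table(adj_b, self.meta_b, self.fdr_cutoff, self.lfc_cutoff)
        res.overlap = _degs.classify_overlap(res.deg_a, res.deg_b)

        if self.feature_set == "shared-degs":
            shared = list(res.overlap.table.index)
            if len(shared) < 2:
                raise ValueError(
                    f"only {len(shared)} shared DEG(s); cannot train autoencoders"
                )
            res.feature_genes_a = res.feature_genes_b = shared
        else:
            universe = list(adj_a.index)
            res.feature_genes_a = self._pathway_genes(res.deg_a, universe)
            res.feature_genes_b = self._pathway_genes(res.deg_b, universe)

        res.split_a = split_train_holdout(self.meta_a, self.split_seed)
        res.split_b = split_train_holdout(self.meta_b, self.split_seed + 1)

        cfg = self.ae_config
        if self.grid is not None:
            z_a = fit_standardizer(adj_a.loc[res.feature_genes_a], res.split_a).transform(
                adj_a.loc[res.feature_genes_a]
            )
            cfg, _ = grid_search(z_a, res.split_a, self.grid, self.ae_config)
        from dataclasses import replace

        res.encoder_a = fit_encoder(
            adj_a.loc[res.feature_genes_a], self.meta_a, res.split_a,
            replace(cfg, seed=self.train_seed),
        )
        res.encoder_b = fit_encoder(
            adj_b.loc[res.feature_genes_b], self.meta_b, res.split_b,
            replace(cfg, seed=self.train_seed + 1),
        )

        res.scores_a = cross_project(
            res.encoder_a, res.encoder_b, adj_a, self.meta_a, res.split_a,
            include_controls=self.include_controls,
        )
        res.scores_b = cross_project(
            res.encoder_a, res.encoder_b, adj_b, self.meta_b, res.split_b,
            include_controls=self.include_controls,
        )
        res.association_a = associate(res.scores_a, alpha=self.alpha, cohort="A")
        res.association_b = associate(res.scores_b, alpha=self.alpha, cohort="B")
        return res
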