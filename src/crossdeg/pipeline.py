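"""Configuration-driven orchestration of the full analysis flow.

A :class:`RunConfig` (usually loaded from YAML) names the inputs (real TSV
cohorts or a synthetic-cohort configuration), the thresholds and seeds, and
an output directory.  :func:`run_pipeline` executes the stages

    ingest -> batch adjust (per cohort) -> DEGs (per cohort) -> overlap
    -> feature selection -> split -> train two autoencoders
    -> cross-project -> correlate -> direction call
    [-> enrichment, hub genes when gene sets / edge lists are given]

writing every intermediate into the output directory together with a JSON
run manifest.  Stages are cached: rerunning with an unchanged configuration
reloads completed intermediates instead of recomputing them.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import associate, cross_project, plot_association
from .autoencoder import AeConfig, HyperGrid, fit_encoder, fit_standardizer, grid_search, split_train_holdout
from .combat import combat_adjust
from .degs import classify_overlap, deg_table
from .enrichment import hub_genes_by_degree, hypergeom_ora
from .io import read_edge_list, read_expression, read_gmt, write_expression, write_metadata
from .model import CrossDiseaseModel  # noqa: F401  (re-exported convenience)
from .simulate import SyntheticConfig, generate_cohort_pair


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str
    # either four paths ...
    expr_a: str | None = None
    meta_a: str | None = None
    expr_b: str | None = None
    meta_b: str | None = None
    # ... or a synthetic generator config
    synthetic: dict | None = None
    gene_sets: str | None = None  # GMT path
    edge_list: str | None = None
    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 0.5
    alpha: float = 0.05
    ora_fdr_cutoff: float = 0.2
    confidence_threshold: float = 0.7
    hub_top_k: int = 50
    feature_set: str = "shared-degs"
    adjust_batches: bool = True
    protect_group: bool = True
    include_controls: bool = False
    run_grid_search: bool = False
    ae: dict = field(default_factory=dict)
    split_seed: int = 0
    train_seed: int = 0
    simulation_seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        has_paths = all(p for p in (self.expr_a, self.meta_a, self.expr_b, self.meta_b))
        if not has_paths and self.synthetic is None:
            raise ValueError("RunConfig needs either four input paths or a synthetic block")
        for name in ("fdr_cutoff", "lfc_cutoff", "alpha", "ora_fdr_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"RunConfig.{name} must be in (0, 1), got {v}")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("RunConfig.confidence_threshold must be in [0, 1]")

    def ae_config(self) -> AeConfig:
        cfg = AeConfig(**{k: tuple(v) if k == "hidden_widths" else v for k, v in self.ae.items()})
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Stage:
    """File-backed stage cache: outputs are reused when the run config and
    stage name match a previous completed run."""

    def __init__(self, outdir: Path, name: str, digest: str, manifest: dict):
        self.dir = outdir / name
        self.name = name
        self.digest = digest
        self.manifest = manifest
        self.marker = self.dir / ".done.json"

    def cached(self) -> bool:
        if not self.marker.exists():
            return False
        try:
            return json.loads(self.marker.read_text()).get("digest") == self.digest
        except (json.JSONDecodeError, OSError):
            return False

    def __enter__(self):
        self.dir.mkdir(parents=True, exist_ok=True)
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            self.marker.write_text(json.dumps({"digest": self.digest}))
            self.manifest["stages"][self.name] = {
                "seconds": round(time.time() - self.t0, 3),
                "cached": False,
            }
        return False

    def mark_cached(self):
        self.manifest["stages"][self.name] = {"seconds": 0.0, "cached": True}


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write artifacts under ``config.output_dir`` and
    return the run manifest (also written as ``manifest.json``)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "digest": digest,
        "stages": {},
    }

    def stage(name):
        return _Stage(outdir, name, digest, manifest)

    # -- ingest ------------------------------------------------------------
    st = stage("ingest")
    if st.cached():
        st.mark_cached()
        expr_a = _read_matrix(st.dir / "expr_A.tsv")
        meta_a = pd.read_csv(st.dir / "meta_A.tsv", sep="\t", dtype=str)
        expr_b = _read_matrix(st.dir / "expr_B.tsv")
        meta_b = pd.read_csv(st.dir / "meta_B.tsv", sep="\t", dtype=str)
    else:
        with st:
            if config.synthetic is not None:
                sim_cfg = SyntheticConfig(**{**config.synthetic, "seed": config.simulation_seed})
                expr_a, meta_a, expr_b, meta_b, truth = generate_cohort_pair(sim_cfg)
                truth.to_json(st.dir / "truth.json")
            else:
                expr_a, meta_a = read_expression(config.expr_a, config.meta_a)
                expr_b, meta_b = read_expression(config.expr_b, config.meta_b)
            write_expression(expr_a, st.dir / "expr_A.tsv")
            write_metadata(meta_a, st.dir / "meta_A.tsv")
            write_expression(expr_b, st.dir / "expr_B.tsv")
            write_metadata(meta_b, st.dir / "meta_B.tsv")
    manifest["n_genes"] = int(expr_a.shape[0])
    manifest["n_samples"] = {"A": int(expr_a.shape[1]), "B": int(expr_b.shape[1])}

    # -- batch adjustment --------------------------------------------------
    st = stage("adjust")
    if st.cached():
        st.mark_cached()
        adj_a = _read_matrix(st.dir / "adjusted_A.tsv")
        adj_b = _read_matrix(st.dir / "adjusted_B.tsv")
    else:
        with st:
            adj_a, adj_b = expr_a, expr_b
            if config.adjust_batches:
                if meta_a["batch"].nunique() > 1:
                    adj_a = combat_adjust(expr_a, meta_a, protect_group=config.protect_group)
                if meta_b["batch"].nunique() > 1:
                    adj_b = combat_adjust(expr_b, meta_b, protect_group=config.protect_group)
            write_expression(adj_a, st.dir / "adjusted_A.tsv")
            write_expression(adj_b, st.dir / "adjusted_B.tsv")

    # -- DEGs and overlap --------------------------------------------------
    st = stage("degs")
    if st.cached():
        st.mark_cached()
        deg_a = _read_matrix(st.dir / "deg_A.tsv")
        deg_b = _read_matrix(st.dir / "deg_B.tsv")
    else:
        with st:
            deg_a = deg_table(adj_a, meta_a, config.fdr_cutoff, config.lfc_cutoff)
            deg_b = deg_table(adj_b, meta_b, config.fdr_cutoff, config.lfc_cutoff)
            deg_a.rename_axis("gene").to_csv(st.dir / "deg_A.tsv", sep="\t")
            deg_b.rename_axis("gene").to_csv(st.dir / "deg_B.tsv", sep="\t")

    overlap = classify_overlap(deg_a, deg_b)
    st = stage("overlap")
    if st.cached():
        st.mark_cached()
    else:
        with st:
            overlap.table.to_csv(st.dir / "overlap.tsv", sep="\t")
            (st.dir / "counts.json").write_text(
                json.dumps(
                    {
                        "co_up": overlap.n_co_up,
                        "co_down": overlap.n_co_down,
                        "inverse": overlap.n_inverse,
                        "shared": overlap.n_shared,
                    }
                )
            )
    manifest["overlap"] = {
        "co_up": overlap.n_co_up,
        "co_down": overlap.n_co_down,
        "inverse": overlap.n_inverse,
        "shared": overlap.n_shared,
    }

    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None

    # -- feature selection -------------------------------------------------
    if config.feature_set == "shared-degs":
        features_a = features_b = sorted(overlap.table.index)
    elif config.feature_set == "pathway-genes":
        if gene_sets is None:
            raise ValueError("feature_set='pathway-genes' requires a gene_sets GMT path")
        universe = list(adj_a.index)

        def pathway_genes(deg):
            hits = deg.index[deg["direction"] != "none"]
            tab = hypergeom_ora(hits, gene_sets, universe, fdr_cutoff=config.ora_fdr_cutoff)
            members: set[str] = set()
            for name in tab.loc[tab["significant"], "set"]:
                members |= gene_sets[name]
            return sorted(members & set(universe))

        features_a, features_b = pathway_genes(deg_a), pathway_genes(deg_b)
    else:
        raise ValueError(f"unknown feature_set {config.feature_set!r}")
    if len(features_a) < 2 or len(features_b) < 2:
        raise ValueError("pipeline aborted at feature selection: fewer than 2 feature genes")
    manifest["n_features"] = {"A": len(features_a), "B": len(features_b)}

    # -- split, train, associate -------------------------------------------
    split_a = split_train_holdout(meta_a, config.split_seed)
    split_b = split_train_holdout(meta_b, config.split_seed + 1)

    ae_cfg = config.ae_config()
    if config.run_grid_search:
        z = fit_standardizer(adj_a.loc[features_a], split_a).transform(adj_a.loc[features_a])
        ae_cfg, grid_records = grid_search(z, split_a, HyperGrid(), ae_cfg)
        grid_records.to_csv(outdir / "grid_search.tsv", sep="\t", index=False)

    from dataclasses import replace

    st = stage("train")
    with st:
        enc_a = fit_encoder(adj_a.loc[features_a], meta_a, split_a, replace(ae_cfg, seed=config.train_seed))
        enc_b = fit_encoder(adj_b.loc[features_b], meta_b, split_b, replace(ae_cfg, seed=config.train_seed + 1))
        enc_a.history.to_csv(st.dir / "history_A.csv", index=False)
        enc_b.history.to_csv(st.dir / "history_B.csv", index=False)
        enc_a.save(st.dir / "encoder_A.npz", st.dir / "encoder_A.yaml")
        enc_b.save(st.dir / "encoder_B.npz", st.dir / "encoder_B.yaml")

    st = stage("associate")
    with st:
        scores_a = cross_project(enc_a, enc_b, adj_a, meta_a, split_a, config.include_controls)
        scores_b = cross_project(enc_a, enc_b, adj_b, meta_b, split_b, config.include_controls)
        assoc_a = associate(scores_a, alpha=config.alpha, cohort="A")
        assoc_b = associate(scores_b, alpha=config.alpha, cohort="B")
        scores_a.to_csv(st.dir / "scores_A.tsv", sep="\t")
        scores_b.to_csv(st.dir / "scores_B.tsv", sep="\t")
        result = {
            "A": asdict(assoc_a),
            "B": asdict(assoc_b),
        }
        calls = {assoc_a.direction, assoc_b.direction} - {"indeterminate"}
        result["direction"] = calls.pop() if len(calls) == 1 else "indeterminate"
        (st.dir / "association.json").write_text(json.dumps(result, indent=1))
        if config.make_plots:
            plot_association(scores_a, assoc_a, st.dir / "scores_A.png")
            plot_association(scores_b, assoc_b, st.dir / "scores_B.png")
    manifest["association"] = result

    # -- enrichment and hubs (optional inputs) ------------------------------
    if gene_sets is not None:
        st = stage("enrich")
        with st:
            hits = sorted(overlap.table.index)
            if hits:
                tab = hypergeom_ora(hits, gene_sets, list(adj_a.index), fdr_cutoff=config.ora_fdr_cutoff)
                tab.to_csv(st.dir / "ora.tsv", sep="\t", index=False)
    if config.edge_list:
        st = stage("hubs")
        with st:
            edges = read_edge_list(config.edge_list)
            hubs = hub_genes_by_degree(edges, config.confidence_threshold, config.hub_top_k)
            hubs.to_csv(st.dir / "hub_genes.tsv", sep="\t", index=False)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
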