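"""Shared fixtures: tiny deterministic cohorts and frozen reference data."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


def make_cohort(
    n_genes=30,
    n_cases=6,
    n_controls=6,
    n_batches=2,
    effect_genes=(),
    effect=1.0,
    seed=0,
    cohort="X",
):
    """Small deterministic cohort: baseline 7, additive case effect on
    ``effect_genes``, round-robin batches, unit noise."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    n = n_cases + n_controls
    samples = [f"{cohort}s{i:02d}" for i in range(n)]
    group = np.array(["case"] * n_cases + ["control"] * n_controls)
    batch = np.array([f"{cohort}b{i % n_batches}" for i in range(n)])
    x = rng.normal(7.0, 1.0, (n_genes, n))
    for g in effect_genes:
        x[genes.index(g)] += effect * (group == "case")
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    meta = pd.DataFrame(
        {"sample_id": samples, "cohort": cohort, "group": group, "batch": batch}
    )
    return expr, meta


@pytest.fixture
def tiny_cohort():
    return make_cohort()


@pytest.fixture(scope="session")
def combat_fixture(data_dir):
    expr = pd.read_csv(data_dir / "combat_fixture_expr.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(data_dir / "combat_fixture_meta.tsv", sep="\t", dtype=str)
    return expr, meta


@pytest.fixture(scope="session")
def limma_fixture(data_dir):
    expr = pd.read_csv(data_dir / "limma_fixture_expr.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(data_dir / "limma_fixture_meta.tsv", sep="\t", dtype=str)
    return expr, meta
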