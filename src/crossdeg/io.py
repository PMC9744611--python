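"""Reading, validation and alignment of cohort inputs.

Expression matrices are plain ``pandas.DataFrame`` objects with gene (or
probe) identifiers as the index and sample identifiers as columns, values on
the log2 scale.  Sample metadata is a DataFrame with columns ``sample_id``,
``cohort``, ``group`` (``case``/``control``) and ``batch``.  All on-disk
formats are tab-delimited text.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
METADATA_COLUMNS = ("sample_id", "cohort", "group", "batch")


class ParseError(ValueError):
    """A malformed input table (duplicate ids, bad values, missing columns)."""


def validate_expression(matrix: pd.DataFrame, name: str = "expression") -> pd.DataFrame:
    """Check an expression matrix for duplicate labels and non-finite values."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][:5].tolist()
        raise ParseError(f"{name}: duplicate row ids, e.g. {dup}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][:5].tolist()
        raise ParseError(f"{name}: duplicate sample ids, e.g. {dup}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = matrix.columns[
            [not np.issubdtype(dt, np.number) for dt in matrix.dtypes]
        ].tolist()
        raise ParseError(f"{name}: non-numeric columns {bad[:5]}")
    if not np.isfinite(values).all():
        rows, cols = np.nonzero(~np.isfinite(values))
        loc = (matrix.index[rows[0]], matrix.columns[cols[0]])
        raise ParseError(f"{name}: non-finite value at gene {loc[0]!r}, sample {loc[1]!r}")
    return matrix


def validate_metadata(meta: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check metadata columns, uniqueness, group levels and matrix coverage."""
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ParseError(f"metadata: missing columns {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"metadata: duplicate sample_id {dup!r}")
    bad_group = sorted(set(meta["group"]) - set(GROUPS))
    if bad_group:
        raise ParseError(
            f"metadata: unknown group value(s) {bad_group}; expected one of {list(GROUPS)}"
        )
    if matrix is not None:
        absent = [s for s in meta["sample_id"] if s not in matrix.columns]
        if absent:
            raise ParseError(
                f"metadata lists sample(s) not present in the matrix: {absent[:5]}"
            )
    return meta


def read_expression(path: str | Path, metadata_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample TSV and its metadata table; validate the pair.

    The expression file has a header row of sample ids and gene ids in the
    first column.  Samples present in the metadata but absent from the matrix
    are an error; extra matrix columns without metadata are permitted (and
    ignored downstream).
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell in expression matrix ({exc})") from None
    validate_expression(matrix, name=str(path))
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    validate_metadata(meta, matrix)
    return matrix, meta


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample matrix as TSV (first column ``gene``)."""
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6f")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.loc[:, list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column probe -> gene symbol TSV; returns a Series indexed by probe."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs two columns (probe_id, gene_symbol)")
    probes, genes = table.iloc[:, 0], table.iloc[:, 1]
    if probes.duplicated().any():
        raise ParseError(f"{path}: duplicate probe id {probes[probes.duplicated()].iloc[0]!r}")
    return pd.Series(genes.values, index=probes.values, name="gene_symbol")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members; tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, members = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = set(members)
    return sets


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an interaction edge list TSV: gene1, gene2, confidence in [0, 1]."""
    edges = pd.read_csv(path, sep="\t")
    if edges.shape[1] < 3:
        raise ParseError(f"{path}: edge list needs columns gene1, gene2, confidence")
    edges = edges.iloc[:, :3].set_axis(["gene1", "gene2", "confidence"], axis=1)
    conf = edges["confidence"].astype(float)
    if ((conf < 0) | (conf > 1)).any():
        bad = conf[(conf < 0) | (conf > 1)].index[0]
        raise ParseError(f"{path}: confidence outside [0, 1] at row {bad}")
    edges["confidence"] = conf
    return edges


def _group_columns(meta: pd.DataFrame) -> tuple[list[str], list[str]]:
    cases = meta.loc[meta["group"] == "case", "sample_id"].tolist()
    controls = meta.loc[meta["group"] == "control", "sample_id"].tolist()
    return cases, controls


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe rows to one row per gene, keeping the probe with the
    largest absolute log-fold change between cases and controls.

    Ties on \\|logFC| keep the lexicographically smallest probe id.  Probes
    absent from the map are dropped (count logged).
    """
    cases, controls = _group_columns(meta)
    if not cases or not controls:
        raise ValueError("collapse_probes: both case and control groups must be non-empty")
    mapped = matrix.index.intersection(probe_map.index)
    n_dropped = matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probe(s)", n_dropped)
    sub = matrix.loc[mapped]
    logfc = sub[cases].mean(axis=1) - sub[controls].mean(axis=1)
    choice = (
        pd.DataFrame(
            {"gene": probe_map.loc[mapped].values, "abs_lfc": logfc.abs().values},
            index=mapped,
        )
        .rename_axis("probe")
        .reset_index()
        # sort so the best probe per gene is first: largest |logFC|, then
        # smallest probe id for deterministic tie-breaking
        .sort_values(["gene", "abs_lfc", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    collapsed = sub.loc[choice["probe"]]
    collapsed.index = pd.Index(choice["gene"].values, name="gene")
    return collapsed.sort_index()


def align_cohorts(m1: pd.DataFrame, m2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their sorted gene intersection, same row order."""
    shared = sorted(set(m1.index) & set(m2.index))
    if not shared:
        raise ValueError("align_cohorts: the two cohorts share no genes")
    return m1.loc[shared], m2.loc[shared]
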