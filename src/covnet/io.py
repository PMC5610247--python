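"""Reading and writing the pipeline's delimited-text formats.

Inputs are plain delimited text (comma or tab, header row, first column the
sample identifier): a samples-by-metabolites concentration table and a
samples-by-covariables table.  Outputs are TSV matrices, edge lists and
reports, plus optional GraphML for thresholded networks.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .corrnet import AdjacencyMatrix, IntensityMatrix
from .tables import Covariable, DesignTable, SampleTable

__all__ = [
    "read_sample_table",
    "read_design_table",
    "read_tables",
    "write_matrix",
    "write_edge_list",
    "write_graphml",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return frame


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a samples x metabolites concentration matrix.

    Every cell must be numeric and present; the error names the offending
    sample/metabolite cell otherwise.
    """
    frame = _read_delimited(path)
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad) > 0:
            raise ValueError(
                f"{path}: non-numeric or missing value at sample {bad[0]!r}, "
                f"metabolite {col!r}"
            )
        frame[col] = numeric
    return SampleTable.from_frame(frame)


def read_design_table(
    path: str | Path,
    target: str,
    categorical: list[str] | None = None,
    references: dict[str, object] | None = None,
    columns: list[str] | None = None,
) -> DesignTable:
    """Read a samples x covariables table.

    Non-numeric columns and any column listed in ``categorical`` (always
    including the target) are treated as categorical; the rest are
    continuous.  ``references`` optionally declares the reference level per
    categorical column (default: first level in sorted order).
    """
    frame = _read_delimited(path)
    if columns is not None:
        missing = set(columns) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: covariables not found: {sorted(missing)}")
        frame = frame[columns]
    if target not in frame.columns:
        raise ValueError(f"{path}: target covariable {target!r} not found")
    categorical = set(categorical or []) | {target}
    references = references or {}
    covs = []
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if col in categorical or numeric.isna().any():
            if frame[col].isna().any():
                bad = frame.index[frame[col].isna()][0]
                raise ValueError(f"{path}: missing value at sample {bad!r}, column {col!r}")
            covs.append(Covariable(col, "categorical", reference=references.get(col)))
        else:
            if numeric.isna().any():
                bad = frame.index[numeric.isna()][0]
                raise ValueError(f"{path}: missing value at sample {bad!r}, column {col!r}")
            frame[col] = numeric
            covs.append(Covariable(col, "continuous"))
    return DesignTable(
        list(frame.index), frame.reset_index(drop=True), covs, target
    )


def read_tables(
    samples_path: str | Path,
    design_path: str | Path,
    target: str,
    **design_kwargs,
) -> tuple[SampleTable, DesignTable]:
    """Read and align the two input tables by sample id."""
    samples = read_sample_table(samples_path)
    design = read_design_table(design_path, target, **design_kwargs)
    return samples, design.align_to(samples)


def write_matrix(
    M: IntensityMatrix | pd.DataFrame, path: str | Path
) -> None:
    """Write a node x node matrix (or any DataFrame) as TSV."""
    if isinstance(M, IntensityMatrix):
        frame = pd.DataFrame(M.weights, index=M.node_ids, columns=M.node_ids)
        frame.to_csv(path, sep="\t", index_label="node")
    else:
        M.to_csv(path, sep="\t", index=False)


def write_edge_list(
    W: IntensityMatrix,
    path: str | Path,
    adjacency: AdjacencyMatrix | None = None,
    min_weight: float = 0.0,
) -> None:
    """Write ``node_a, node_b, weight`` rows (upper triangle) as TSV.

    With an adjacency given, only its edges are written; otherwise all pairs
    with weight above ``min_weight``.
    """
    rows = []
    p = W.n_nodes
    keep = adjacency.entries if adjacency is not None else None
    for i in range(p):
        for j in range(i + 1, p):
            w = W.weights[i, j]
            if keep is not None:
                if not keep[i, j]:
                    continue
            elif w <= min_weight:
                continue
            rows.append((W.node_ids[i], W.node_ids[j], w))
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(
    W: IntensityMatrix,
    adjacency: AdjacencyMatrix,
    path: str | Path,
    modules=None,
) -> None:
    """Export a thresholded network (edge weights, optional module colors)."""
    G = nx.Graph()
    for i, node in enumerate(W.node_ids):
        attrs = {}
        if modules is not None:
            attrs["module"] = int(modules.labels[i])
            attrs["color"] = modules.color(int(modules.labels[i]))
        G.add_node(node, **attrs)
    idx = np.argwhere(np.triu(adjacency.entries, k=1))
    for i, j in idx:
        G.add_edge(W.node_ids[i], W.node_ids[j], weight=float(W.weights[i, j]))
    nx.write_graphml(G, path)
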