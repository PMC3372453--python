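"""Delimited-text readers/writers for expression data, networks and results.

All on-disk formats are plain text: expression matrices as TSV/CSV with a
gene-id column and time-point columns, networks either as dense adjacency
CSV (header row and index column of gene ids) or as signed edge-list TSV
(source, target, weight), communities as two-column TSV.  Floats are
written with 17 significant digits so numeric payloads round-trip exactly.
Delimiters are inferred from the file extension (.csv comma, anything else
tab).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import CommunityPartition
from .synthetic import ExpressionMatrix, GRNMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_communities",
    "write_communities",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x time-points matrix (first column: gene ids)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 time-point columns")
    try:
        X = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if np.any(~np.isfinite(X)):
        bad = int(np.argwhere(~np.isfinite(X))[0][0])
        raise ValueError(f"{path}: non-finite value in row {bad + 2}")
    return ExpressionMatrix(X, [str(g) for g in df.index])


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        X.X, index=X.gene_ids, columns=[f"t{k}" for k in range(X.m)]
    )
    df.index.name = "gene"
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)


def read_network(path: str | Path, kind: str | None = None) -> GRNMatrix:
    """Read a network from dense adjacency CSV or signed edge-list TSV.

    ``kind`` is "adjacency" or "edgelist"; by default .csv files are read
    as adjacency and anything else as an edge list.
    """
    if kind is None:
        kind = "adjacency" if str(path).lower().endswith(".csv") else "edgelist"
    if kind == "adjacency":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
        A = df.to_numpy(dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"{path}: adjacency must be square, got {A.shape}")
        return GRNMatrix(A, [str(g) for g in df.index])
    if kind != "edgelist":
        raise ValueError(f"unknown network kind {kind!r}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = {"source", "target", "weight"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    ids: list[str] = []
    for g in pd.concat([df["source"], df["target"]]).astype(str):
        if g not in ids:
            ids.append(g)
    pos = {g: i for i, g in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        s, t = str(row["source"]), str(row["target"])
        if (s, t) in seen:
            raise ValueError(f"{path}: duplicate edge {s} -> {t}")
        seen.add((s, t))
        A[pos[t], pos[s]] = float(row["weight"])
    return GRNMatrix(A, ids)


def write_network(
    net: GRNMatrix,
    path: str | Path,
    kind: str | None = None,
    sign_threshold: float = 1e-4,
) -> None:
    """Write as dense adjacency CSV or as signed edge-list TSV.

    The edge list keeps off-diagonal entries with magnitude above
    ``sign_threshold`` (source, target, weight; edge source -> target means
    the source gene regulates the target).
    """
    if kind is None:
        kind = "adjacency" if str(path).lower().endswith(".csv") else "edgelist"
    if kind == "adjacency":
        df = pd.DataFrame(net.A, index=net.gene_ids, columns=net.gene_ids)
        df.index.name = "gene"
        df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)
        return
    if kind != "edgelist":
        raise ValueError(f"unknown network kind {kind!r}")
    rows = []
    for t, s in zip(*np.nonzero(net.support(sign_threshold))):
        rows.append(
            {
                "source": net.gene_ids[s],
                "target": net.gene_ids[t],
                "weight": net.A[t, s],
            }
        )
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    df = df.sort_values(["source", "target"], kind="stable")
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def write_communities(
    part: CommunityPartition, gene_ids: list[str], path: str | Path
) -> None:
    """Two-column TSV (gene_id, community_id); outliers get id -1."""
    lab = part.labels(len(gene_ids))
    df = pd.DataFrame({"gene_id": gene_ids, "community_id": lab})
    df.to_csv(path, sep="\t", index=False)


def read_communities(path: str | Path) -> tuple[CommunityPartition, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "community_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns gene_id, community_id")
    ids = [str(g) for g in df["gene_id"]]
    labels = df["community_id"].to_numpy(dtype=int)
    groups = [
        sorted(np.nonzero(labels == c)[0].tolist())
        for c in sorted(set(labels[labels >= 0]))
    ]
    outliers = sorted(np.nonzero(labels < 0)[0].tolist())
    return CommunityPartition(groups=groups, outliers=outliers), ids


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration mapping (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
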