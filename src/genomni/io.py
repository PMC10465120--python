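"""Plain-text I/O: adjacency matrices, edge lists, embeddings, configs."""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .models import GraphCollection, LatentDistribution
from .omnibus import EmbeddingBlocks

__all__ = [
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "write_collection",
    "read_collection",
    "write_embedding_csv",
    "load_model_config",
]


def write_adjacency_csv(A: np.ndarray, path: str | Path) -> None:
    """Dense 0/1 CSV with a header row of 0-based vertex ids."""
    A = np.asarray(A)
    pd.DataFrame(A, columns=[str(i) for i in range(A.shape[0])]).to_csv(
        path, index=False
    )


def read_adjacency_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int8)


def write_edgelist_tsv(graphs: GraphCollection, path: str | Path) -> None:
    """3-column TSV (u, v, graph_index), vertices 0-based, undirected edges
    stored once with u < v."""
    rows = []
    for k in range(graphs.m):
        u, v = np.nonzero(np.triu(graphs[k], k=1))
        rows.append(np.column_stack([u, v, np.full(u.size, k)]))
    arr = np.vstack(rows) if rows else np.empty((0, 3), dtype=int)
    pd.DataFrame(arr, columns=["u", "v", "graph_index"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist_tsv(path: str | Path, n: int | None = None) -> GraphCollection:
    df = pd.read_csv(path, sep="\t")
    m = int(df["graph_index"].max()) + 1 if len(df) else 1
    if n is None:
        n = int(max(df["u"].max(), df["v"].max())) + 1
    A = np.zeros((m, n, n), dtype=np.int8)
    for u, v, k in df.itertuples(index=False):
        A[k, u, v] = A[k, v, u] = 1
    return GraphCollection(A)


def write_collection(graphs: GraphCollection, outdir: str | Path) -> None:
    """One dense CSV per graph (``graph_000.csv``, ...) in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k in range(graphs.m):
        write_adjacency_csv(graphs[k], outdir / f"graph_{k:03d}.csv")


def read_collection(indir: str | Path) -> GraphCollection:
    paths = sorted(Path(indir).glob("graph_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no graph_*.csv files in {indir}")
    return GraphCollection(np.stack([read_adjacency_csv(p) for p in paths]))


def write_embedding_csv(blocks: EmbeddingBlocks, path: str | Path) -> None:
    """Embedding CSV with columns (graph_index, vertex_id, dim_1..dim_d)."""
    m, n, d = blocks.m, blocks.n, blocks.d
    gi = np.repeat(np.arange(m), n)
    vid = np.tile(np.arange(n), m)
    df = pd.DataFrame(blocks.stacked, columns=[f"dim_{j + 1}" for j in range(d)])
    df.insert(0, "vertex_id", vid)
    df.insert(0, "graph_index", gi)
    df.to_csv(path, index=False)


def load_model_config(path: str | Path) -> dict:
    """Load a JSON/YAML model config and normalise it.

    Fields: ``gram_matrix`` or ``atoms``+``weights``; ``n``; ``model`` in
    {iid, forward, generator, pair} with its parameter (``rho_steps``,
    ``nu``, ``rho``, or ``m``); optional ``seed``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "gram_matrix" in cfg:
        F = LatentDistribution.from_gram(
            np.asarray(cfg["gram_matrix"], float), cfg.get("weights")
        )
    elif "atoms" in cfg:
        F = LatentDistribution(
            atoms=np.asarray(cfg["atoms"], float),
            weights=np.asarray(cfg["weights"], float),
        )
    else:
        raise ValueError("config must provide gram_matrix or atoms+weights")
    model = cfg.get("model", "iid")
    if model not in ("iid", "forward", "generator", "pair"):
        raise ValueError(f"unknown model {model!r}")
    return {
        "F": F,
        "n": int(cfg["n"]),
        "m": int(cfg.get("m", 1)),
        "model": model,
        "rho_steps": cfg.get("rho_steps"),
        "nu": cfg.get("nu"),
        "rho": cfg.get("rho"),
        "seed": cfg.get("seed"),
    }
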