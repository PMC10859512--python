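"""CSV / GraphML serialization for survey tables and networks."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .estimation import NetworkModel, infer_communities
from .synthetic import MISSING_CODES, NODE_NAMES, TrueNetwork


def write_survey_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_survey_csv(path, column_map: dict[str, str] | None = None,
                    missing_codes=MISSING_CODES) -> pd.DataFrame:
    """Read a raw survey table; ``column_map`` renames file columns to the
    canonical names (participant_id, age, dm_diagnosed, CESD1..GAD7)."""
    raw = pd.read_csv(path, dtype=object, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=column_map)
    for col in ("participant_id", "age", "dm_diagnosed"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return raw


def write_edge_list(model_or_net, path) -> None:
    if isinstance(model_or_net, TrueNetwork):
        rows = model_or_net.edges()
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    else:
        df = model_or_net.edge_list()
    df.to_csv(path, index=False)


def write_node_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_true_network(edge_path, node_path) -> TrueNetwork:
    """Round-trip a TrueNetwork from its edge-list and node CSVs."""
    nodes = pd.read_csv(node_path)
    names = tuple(nodes["name"])
    communities = tuple(nodes["community"])
    idx = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    edges = pd.read_csv(edge_path)
    for _, r in edges.iterrows():
        i, j = idx[r["node_a"]], idx[r["node_b"]]
        W[i, j] = W[j, i] = float(r["weight"])
    return TrueNetwork(W, names, communities)


def write_true_network(net: TrueNetwork, edge_path, node_path) -> None:
    write_edge_list(net, edge_path)
    pd.DataFrame({"name": net.node_names,
                  "community": net.communities}).to_csv(node_path, index=False)


def to_graph(model: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    for name, comm in zip(model.node_names, model.communities):
        G.add_node(name, community=comm)
    for _, r in model.edge_list().iterrows():
        G.add_edge(r["node_a"], r["node_b"], weight=float(r["weight"]))
    return G


def write_graphml(model: NetworkModel, path) -> None:
    nx.write_graphml(to_graph(model), path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    return cfg
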