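"""Degree-based hub and terminal-regulator analysis of gene networks.

Consumes an undirected gene-interaction edge list (RiceNet-style TSV
export; evidence scores, if present, are ignored and multi-evidence
edges are deduplicated).  Hubs are the most-connected nodes; terminal
regulators are regulatory nodes (TFs or signaling genes) that connect
directly to non-regulatory genes without touching any other regulator —
candidate intervention points at the end of signaling cascades.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def load_edge_list(path=None, lines=None) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph.

    Self-loops are dropped (count logged); duplicate undirected edges
    collapse.  Extra columns (e.g. evidence scores) are ignored.
    """
    if (path is None) == (lines is None):
        raise ValueError("give exactly one of path or lines")
    if path is not None:
        with open(path) as fh:
            lines = fh.read().splitlines()
    graph = nx.Graph()
    self_loops = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"malformed edge list at line {lineno}: {raw!r}")
        a, b = fields[0], fields[1]
        if a == b:
            self_loops += 1
            graph.add_node(a)
            continue
        graph.add_edge(a, b)
    if self_loops:
        logger.info("dropped %d self-loop(s)", self_loops)
    return graph


def load_roles(path) -> dict[str, str]:
    """Optional node-role sidecar TSV (node, role)."""
    roles = pd.read_csv(path, sep="\t", header=None, names=["node", "role"])
    return dict(zip(roles["node"], roles["role"]))


def top_hubs(graph: nx.Graph, k: int) -> list[tuple[str, int]]:
    """The k most-connected nodes, degree descending, ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(graph.degree, key=lambda item: (-item[1], str(item[0])))
    return [(node, int(deg)) for node, deg in ranked[:k]]


def terminal_regulators(graph: nx.Graph, regulator_set) -> dict[str, list[str]]:
    """Regulators connected only to non-regulators.

    Returns each qualifying regulator (degree >= 1, no regulator among
    its neighbors) with its sorted neighbor list.
    """
    regulators = set(regulator_set)
    unknown = regulators - set(graph.nodes)
    if unknown:
        raise ValueError(f"regulators not in the network: {sorted(unknown)}")
    out = {}
    for node in sorted(regulators):
        neighbors = set(graph.neighbors(node))
        if neighbors and not (neighbors & regulators):
            out[node] = sorted(neighbors)
    return out


def hubs_table(graph: nx.Graph, k: int) -> pd.DataFrame:
    return pd.DataFrame(top_hubs(graph, k), columns=["node", "degree"])
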