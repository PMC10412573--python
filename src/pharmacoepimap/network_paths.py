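"""Signalling-network evidence: K-shortest loopless paths from a biomarker
gene to the targets of its associated drug.

Edges are directed (source activates/regulates target); by default every
edge has unit weight, so path cost is hop count.  Yen's K-shortest simple
paths are enumerated with a deterministic tie-break: among equal-cost paths
the lexicographically smaller node sequence comes first.  When no forward
path exists the search is repeated from the drug target back to the gene
(signalling direction reversed), and the biomarker is called
network-supported iff any path is found either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SignalingNetwork:
    """A directed gene-gene graph without self-loops; parallel edges are
    collapsed keeping the minimum weight."""

    graph: nx.DiGraph

    @property
    def nodes(self):
        return self.graph.nodes

    @classmethod
    def from_edge_frame(cls, edges: pd.DataFrame) -> "SignalingNetwork":
        g = nx.DiGraph()
        n_self = 0
        for row in edges.itertuples(index=False):
            src, dst = str(row.source), str(row.target)
            w = float(getattr(row, "weight", 1.0))
            if src == dst:
                n_self += 1
                continue
            if g.has_edge(src, dst):
                g[src][dst]["weight"] = min(g[src][dst]["weight"], w)
            else:
                g.add_edge(src, dst, weight=w)
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        return cls(graph=g)


def read_network(edge_list_path: str | Path) -> SignalingNetwork:
    """Read a TSV edge list (columns ``source``, ``target``, optional
    ``weight``); malformed rows are fatal with their line number."""
    path = Path(edge_list_path)
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "source" not in header or "target" not in header:
                    raise ValueError(
                        f"{path}:{lineno}: header must contain 'source' "
                        f"and 'target', got {header}")
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            rows.append(dict(zip(header, fields)))
    df = pd.DataFrame(rows, columns=header)
    if "weight" in df.columns:
        try:
            df["weight"] = df["weight"].astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric weight: {exc}") from exc
    return SignalingNetwork.from_edge_frame(df)


def _path_weight(graph: nx.DiGraph, path: Sequence[str]) -> float:
    return sum(graph[a][b].get("weight", 1.0)
               for a, b in zip(path[:-1], path[1:]))


def yen_k_shortest(
    network: SignalingNetwork,
    source: str,
    target: str,
    k: int = 10,
) -> list[list[str]]:
    """Up to ``k`` loopless directed paths in non-decreasing total weight.

    Equal-weight paths are ordered lexicographically by node sequence.
    ``source == target`` yields the single zero-length path; an unreachable
    target yields an empty list.
    """
    g = network.graph
    if source not in g or target not in g:
        raise KeyError(f"node missing from network: "
                       f"{source if source not in g else target!r}")
    if source == target:
        return [[source]]
    collected: list[tuple[float, list[str]]] = []
    try:
        gen = nx.shortest_simple_paths(g, source, target, weight="weight")
        for path in gen:
            w = _path_weight(g, path)
            collected.append((w, list(path)))
            # stop once the k-th best weight can no longer change
            if len(collected) >= k and w > collected[k - 1][0]:
                break
    except nx.NetworkXNoPath:
        return []
    collected.sort(key=lambda item: (item[0], item[1]))
    return [p for _, p in collected[:k]]


def connect_biomarker_to_targets(
    network: SignalingNetwork,
    biomarker_gene: str,
    drug_targets: Sequence[str],
    k: int = 10,
) -> dict[str, Any]:
    """Path evidence connecting a biomarker gene to each drug target.

    Forward (gene -> target) paths are tried first; the reversed direction
    (target -> gene) only when no forward path exists.  The report lists,
    per target, the direction used and the paths, plus the induced
    subnetwork of traversed nodes/edges; the biomarker is
    ``network_supported`` iff any path was found.
    """
    report: dict[str, Any] = {
        "biomarker": biomarker_gene,
        "targets": {},
        "network_supported": False,
        "reason": "",
        "subnetwork_nodes": [],
        "subnetwork_edges": [],
    }
    g = network.graph
    if biomarker_gene not in g:
        report["reason"] = "node_missing"
        return report

    sub_nodes: set[str] = set()
    sub_edges: set[tuple[str, str]] = set()
    for target in drug_targets:
        entry: dict[str, Any] = {"direction": "forward", "paths": []}
        if target not in g:
            entry["direction"] = "none"
            report["targets"][target] = entry
            continue
        paths = yen_k_shortest(network, biomarker_gene, target, k)
        if not paths:
            reverse = yen_k_shortest(network, target, biomarker_gene, k)
            if reverse:
                entry["direction"] = "reverse"
                paths = reverse
            else:
                entry["direction"] = "none"
        entry["paths"] = paths
        if paths:
            entry["shortest_hops"] = len(paths[0]) - 1
            report["network_supported"] = True
            for p in paths:
                sub_nodes.update(p)
                sub_edges.update(zip(p[:-1], p[1:]))
        report["targets"][target] = entry
    if not report["network_supported"]:
        report["reason"] = "no_path"
    report["subnetwork_nodes"] = sorted(sub_nodes)
    report["subnetwork_edges"] = sorted(sub_edges)
    return report


def write_subnetwork_sif(report: dict[str, Any], path: str | Path) -> None:
    """SIF-style TSV (source, interaction, target) of the traversed edges."""
    with open(path, "w") as fh:
        fh.write("source\tinteraction\ttarget\n")
        for src, dst in report["subnetwork_edges"]:
            fh.write(f"{src}\tdirected\t{dst}\n")
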