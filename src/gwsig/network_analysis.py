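"""Signature-induced interaction subnetwork and hub detection.

Edges come from a three-column tab-separated list (gene_a, gene_b, score);
only edges with both endpoints in the signature are kept, nodes are the
endpoints of kept edges (so every node has degree >= 1), and hubs are the
nodes whose degree strictly exceeds a threshold (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from gwsig.errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.4
DEFAULT_HUB_THRESHOLD = 10


class Edge(NamedTuple):
    """Undirected scored edge, stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    score: float


@dataclass
class EdgeList:
    """Simple undirected scored graph as a list of canonical edges."""

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        canonical: list[Edge] = []
        for e in self.edges:
            a, b = str(e[0]), str(e[1])
            if a == b:
                raise ConfigurationError(f"self-loop on '{a}' is not allowed")
            if a > b:
                a, b = b, a
            if (a, b) in seen:
                raise ConfigurationError(f"duplicate undirected edge ({a}, {b})")
            seen.add((a, b))
            canonical.append(Edge(a, b, float(e[2])))
        self.edges = canonical

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.gene_a)
            out.add(e.gene_b)
        return out


@dataclass
class InducedNetwork:
    """Signature-restricted graph; isolated signature genes listed separately."""

    graph: nx.Graph
    isolates: list[str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])


def read_edge_list(
    path: str | Path, min_score: float = DEFAULT_MIN_SCORE
) -> EdgeList:
    """Read a three-column TSV edge list, dropping edges below min_score.

    Duplicate undirected pairs are collapsed keeping the maximum score;
    self-loops are dropped with a warning.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ConfigurationError(f"min_score must lie in [0, 1], got {min_score}")
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    n_loops = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b, raw = fields
            try:
                score = float(raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from None
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key not in best or score > best[key]:
                best[key] = score
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    edges = [
        Edge(a, b, s) for (a, b), s in sorted(best.items()) if s >= min_score
    ]
    return EdgeList(edges=edges)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.score!r}\n")


def induce_subnetwork(edges: EdgeList, signature: Iterable[str]) -> InducedNetwork:
    """Keep exactly the edges whose both endpoints lie in the signature.

    Signature genes with no kept edge are excluded from the graph but
    reported as isolates.
    """
    sig = set(signature)
    if not sig:
        raise ConfigurationError("signature is empty; cannot induce a subnetwork")
    graph = nx.Graph()
    for e in edges:
        if e.gene_a in sig and e.gene_b in sig:
            graph.add_edge(e.gene_a, e.gene_b, score=e.score)
    isolates = sorted(sig - set(graph.nodes))
    return InducedNetwork(graph=graph, isolates=isolates)


def compute_degrees(network: InducedNetwork) -> pd.DataFrame:
    """Degree table (distinct neighbours), sorted descending, ties by gene id."""
    rows = [(g, int(d)) for g, d in network.graph.degree]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def identify_hubs(
    degree_table: pd.DataFrame, threshold: int = DEFAULT_HUB_THRESHOLD
) -> list[str]:
    """Genes with degree strictly greater than threshold, degree-descending."""
    if threshold < 0:
        raise ConfigurationError(f"hub threshold must be >= 0, got {threshold}")
    hubs = degree_table[degree_table["degree"] > threshold]
    return [str(g) for g in hubs["gene"]]


def write_sif(network: InducedNetwork, path: str | Path) -> None:
    """Cytoscape SIF export: geneA <tab> pp <tab> geneB per edge."""
    lines = sorted(
        f"{min(a, b)}\tpp\t{max(a, b)}" for a, b in network.graph.edges
    )
    Path(path).write_text(
        "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
    )


def write_node_attributes(
    network: InducedNetwork,
    path: str | Path,
    threshold: int = DEFAULT_HUB_THRESHOLD,
) -> None:
    table = compute_degrees(network)
    table["is_hub"] = table["degree"] > threshold
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_hub_table(
    network: InducedNetwork,
    path: str | Path,
    threshold: int = DEFAULT_HUB_THRESHOLD,
) -> None:
    table = compute_degrees(network)
    table[table["degree"] > threshold].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
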