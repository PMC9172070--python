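"""Template network construction and first-order local neighborhoods.

The template ("global") network is an undirected graph on gene symbols
built from a STRING-style edge list, thresholded on the interaction
confidence score. Identifiers are assumed to be pre-mapped to gene
symbols; no protein/gene ID conversion is attempted here.

Score scales
------------
STRING distributes ``combined_score`` on an integer 0-1000 scale while
confidence levels are usually quoted on [0, 1] (0.800 on the unit scale
corresponds to 800 in a STRING file). ``score_scale="string-1000"``
divides raw scores by 1000 before thresholding so the threshold is
always expressed on [0, 1].
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "GeneNetwork",
    "LocalNeighborhood",
    "load_edge_list",
    "restrict_to_genes",
    "neighborhood",
    "write_edge_list",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class LocalNeighborhood:
    """First-order neighborhood of a center gene.

    ``neighbors`` is lexicographically sorted so that weight-vector
    indexing is reproducible across runs.
    """

    center: str
    neighbors: tuple[str, ...]

    @property
    def M(self) -> int:
        return len(self.neighbors)


class GeneNetwork:
    """Undirected, pruned gene network.

    Invariants: no self-loops, no duplicate edges, every node has
    degree >= 1, and every retained edge had source confidence at or
    above ``confidence_threshold``.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], confidence_threshold: float = 0.0):
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        self._graph = g
        self.confidence_threshold = float(confidence_threshold)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges as order-normalized (min, max) gene-symbol pairs."""
        return frozenset(tuple(sorted(e)) for e in self._graph.edges)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def degree(self, gene: str) -> int:
        return self._graph.degree[gene]

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self):  # pragma: no cover - sets of networks are unusual
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return (
            f"GeneNetwork({self._graph.number_of_nodes()} nodes, "
            f"{self._graph.number_of_edges()} edges, "
            f"threshold={self.confidence_threshold})"
        )


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _split_row(line: str) -> list[str]:
    if "," in line and "\t" not in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def load_edge_list(
    path: str | Path,
    score_column: str | None = None,
    threshold: float = 0.0,
    score_scale: str = "unit",
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from a delimited edge-list file.

    Parameters
    ----------
    path:
        Whitespace-, tab- or comma-delimited file with columns
        ``protein1 protein2 [combined_score]``; optional header row;
        transparently gunzipped.
    score_column:
        Name of the score column in the header. When absent, the third
        column is used if present; two-column files get implicit score 1.
    threshold:
        Minimum confidence on the unit scale, in [0, 1].
    score_scale:
        ``"unit"`` (scores already in [0, 1]) or ``"string-1000"``
        (raw STRING integers, divided by 1000).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    if score_scale not in ("unit", "string-1000"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1] on the unit scale, got {threshold}")
    divisor = 1000.0 if score_scale == "string-1000" else 1.0

    header_names = {"protein1", "protein2", "gene1", "gene2", "node1", "node2", "source", "target"}
    edges: list[tuple[str, str]] = []
    score_idx: int | None = None
    with _open_text(path) as fh:
        first = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            if first:
                first = False
                is_header = (score_column is not None and score_column in fields) or (
                    fields[0].lower() in header_names
                )
                if not is_header and len(fields) >= 3:
                    try:
                        float(fields[2])
                    except ValueError:
                        is_header = True
                if is_header:
                    if score_column is not None and score_column in fields:
                        score_idx = fields.index(score_column)
                    elif len(fields) >= 3:
                        score_idx = 2
                    continue
                score_idx = 2 if len(fields) >= 3 else None
            a, b = fields[0], fields[1]
            if score_idx is not None:
                if len(fields) <= score_idx:
                    raise ValueError(f"{path}:{lineno}: missing score column")
                try:
                    score = float(fields[score_idx]) / divisor
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: score {fields[score_idx]!r} is not a number"
                    ) from None
            else:
                score = 1.0
            if score >= threshold:
                edges.append((a, b))
    return GeneNetwork(edges, confidence_threshold=threshold)


def restrict_to_genes(net: GeneNetwork, genes: set[str] | frozenset[str]) -> GeneNetwork:
    """Induced subgraph on ``genes``, with isolated nodes re-pruned."""
    if not genes:
        raise ValueError("gene set for restriction is empty")
    keep = net.nodes & frozenset(genes)
    if not keep:
        raise ValueError(
            f"no overlap between network ({len(net.nodes)} genes) and "
            f"expression genes ({len(genes)} genes)"
        )
    sub = net.graph.subgraph(keep)
    restricted = GeneNetwork(sub.edges, confidence_threshold=net.confidence_threshold)
    if len(restricted) == 0:
        raise ValueError(
            f"restriction to {len(genes)} genes left no connected pairs "
            f"(all {len(keep)} overlapping genes became isolated)"
        )
    return restricted


def neighborhood(net: GeneNetwork, gene: str) -> LocalNeighborhood:
    """First-order neighborhood of ``gene``, neighbors sorted lexicographically."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} is not in the network")
    return LocalNeighborhood(center=gene, neighbors=tuple(sorted(net.graph.neighbors(gene))))


def write_edge_list(net: GeneNetwork, path: str | Path, score: float = 1.0) -> None:
    """Write a three-column edge list readable by :func:`load_edge_list`."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\t{score:g}\n")


def write_sif(net: GeneNetwork, path: str | Path, interaction: str = "pp") -> None:
    """Write the network as a Cytoscape SIF file (nodeA<TAB>type<TAB>nodeB)."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_graphml(
    net: GeneNetwork,
    path: str | Path,
    node_attrs: dict[str, dict[str, float]] | None = None,
    edge_attrs: dict[str, dict[tuple[str, str], float]] | None = None,
) -> None:
    """Write GraphML with optional per-node / per-edge numeric attributes.

    ``edge_attrs`` keys are order-normalized (min, max) node pairs.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(net.edges))
    for name, values in (node_attrs or {}).items():
        nx.set_node_attributes(g, values, name)
    for name, values in (edge_attrs or {}).items():
        nx.set_edge_attributes(g, {tuple(k): v for k, v in values.items()}, name)
    nx.write_graphml(g, path)
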