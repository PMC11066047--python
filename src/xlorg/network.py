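"""Protein–protein interaction network from inter-protein cross-links.

Each unordered protein pair connected by at least one inter-protein
cross-link becomes an edge, weighted by the number of unique residue
pairs supporting it.  Intra-protein links never create edges (no
self-loops): the interactome is a PPI network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .xl_io import CrossLinkTable

__all__ = [
    "InteractionNetwork",
    "build_network",
    "residue_edge_table",
    "write_residue_edge_table",
    "export_graph",
    "import_graph",
]


@dataclass
class InteractionNetwork:
    nodes: set[str] = field(default_factory=set)
    # unordered pair (sorted tuple) -> list of residue pairs (ra, rb) aligned
    # with the sorted protein order; csm totals kept as an attribute
    edges: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)
    csm_totals: dict[tuple[str, str], int] = field(default_factory=dict)

    def n_unique_links(self, pair: tuple[str, str]) -> int:
        return len(self.edges[pair])


def build_network(
    table: CrossLinkTable, min_links: int = 1, keep_isolated: bool = False
) -> InteractionNetwork:
    """Build the interactome from a deduplicated cross-link table.

    Edges come from inter-protein links only; edges supported by fewer
    than ``min_links`` unique residue pairs are dropped.  By default the
    node set is restricted to proteins with surviving edges, matching a
    drawable interactome; ``keep_isolated`` retains every accession seen.
    """
    if not table.deduplicated:
        raise ValueError("build_network expects a deduplicated table")
    edges: dict[tuple[str, str], list[tuple[int, int]]] = {}
    csm: dict[tuple[str, str], int] = {}
    all_proteins: set[str] = set()
    for rec in table.records:
        all_proteins.update((rec.protein_a, rec.protein_b))
        if rec.is_intra:
            continue
        pair = (rec.protein_a, rec.protein_b)  # already canonically ordered
        edges.setdefault(pair, []).append((rec.residue_a, rec.residue_b))
        csm[pair] = csm.get(pair, 0) + rec.csm_count
    edges = {p: sorted(rps) for p, rps in edges.items() if len(rps) >= min_links}
    csm = {p: csm[p] for p in edges}
    nodes = set(all_proteins) if keep_isolated else {p for pair in edges for p in pair}
    return InteractionNetwork(nodes=nodes, edges=edges, csm_totals=csm)


def residue_edge_table(network: InteractionNetwork) -> list[dict]:
    """Expand the network into residue-to-residue rows, one per unique pair."""
    rows = []
    for edge_id, pair in enumerate(sorted(network.edges)):
        for ra, rb in network.edges[pair]:
            rows.append(
                {
                    "protein_a": pair[0],
                    "residue_a": ra,
                    "protein_b": pair[1],
                    "residue_b": rb,
                    "edge_id": edge_id,
                }
            )
    return rows


def write_residue_edge_table(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(
            handle,
            fieldnames=["protein_a", "residue_a", "protein_b", "residue_b", "edge_id"],
            delimiter="\t",
            lineterminator="\n",
        )
        writer.writeheader()
        for row in residue_edge_table(network):
            writer.writerow(row)


def _to_networkx(network: InteractionNetwork) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(sorted(network.nodes))
    for pair in sorted(network.edges):
        graph.add_edge(
            pair[0],
            pair[1],
            weight=len(network.edges[pair]),
            csm_total=network.csm_totals.get(pair, 0),
            residue_pairs=";".join(f"{a}-{b}" for a, b in network.edges[pair]),
        )
    return graph


def export_graph(network: InteractionNetwork, path: str | Path, format: str) -> None:
    """Write the network as ``graphml``, ``sif`` or edge-list ``tsv``.

    GraphML and TSV round-trip through :func:`import_graph`; SIF uses the
    interaction type ``xl`` (``A xl B``).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_networkx(network), path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as handle:
            for pair in sorted(network.edges):
                handle.write(f"{pair[0]} xl {pair[1]}\n")
            for node in sorted(network.nodes - {p for e in network.edges for p in e}):
                handle.write(f"{node}\n")
    elif format == "tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["protein_a", "protein_b", "n_unique_links", "csm_total", "residue_pairs"]
            )
            for pair in sorted(network.edges):
                writer.writerow(
                    [
                        pair[0],
                        pair[1],
                        len(network.edges[pair]),
                        network.csm_totals.get(pair, 0),
                        ";".join(f"{a}-{b}" for a, b in network.edges[pair]),
                    ]
                )
    else:
        raise ValueError(f"unknown export format {format!r}")


def _parse_residue_pairs(text: str) -> list[tuple[int, int]]:
    if not text:
        return []
    return [tuple(int(x) for x in pair.split("-")) for pair in text.split(";")]


def import_graph(path: str | Path, format: str) -> InteractionNetwork:
    """Read a network written by :func:`export_graph` (graphml or tsv)."""
    path = Path(path)
    network = InteractionNetwork()
    if format == "graphml":
        graph = nx.read_graphml(path)
        network.nodes = set(graph.nodes)
        for a, b, data in graph.edges(data=True):
            pair = tuple(sorted((a, b)))
            network.edges[pair] = _parse_residue_pairs(data.get("residue_pairs", ""))
            network.csm_totals[pair] = int(data.get("csm_total", 0))
    elif format == "tsv":
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                pair = tuple(sorted((row["protein_a"], row["protein_b"])))
                network.nodes.update(pair)
                network.edges[pair] = _parse_residue_pairs(row["residue_pairs"])
                network.csm_totals[pair] = int(row["csm_total"])
    else:
        raise ValueError(f"cannot import format {format!r}")
    return network
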