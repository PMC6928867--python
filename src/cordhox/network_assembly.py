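"""Assembly and export of the typed regulatory network.

Three evidence layers are merged into one graph: physical protein-protein
interactions (undirected, stored with endpoints order-normalized), curated
transcriptional repression (directed TF -> silenced target), and predicted
TF binding from promoter-motif scans (directed TF -> predicted target).
Each edge keeps a free-text provenance; duplicate (source, target, type)
triples merge by concatenating provenances.

Exports: GraphML (via networkx, with edge ``type`` and ``provenance``
attributes and a node ``role`` attribute) and SIF (``source<TAB>type<TAB>
target``); both re-import to the identical typed edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from .io_formats import normalize_symbol

EdgeType = Literal["physical", "repression", "predicted_binding"]
EDGE_TYPES: tuple[str, ...] = ("physical", "repression", "predicted_binding")
UNDIRECTED_TYPES = {"physical"}

# (source, target, type) with raw-input orientation for directed types
EdgeSpec = tuple[str, str] | tuple[str, str, str]


@dataclass(frozen=True)
class TypedEdge:
    source: str
    target: str
    type: str
    provenance: str = ""

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.type)


@dataclass
class RegulatoryNetwork:
    """Typed multigraph: nodes with role tags, edges of three evidence types."""

    nodes: dict[str, str] = field(default_factory=dict)  # symbol -> role
    edges: set[TypedEdge] = field(default_factory=set)

    def edge_triples(self) -> set[tuple[str, str, str]]:
        return {e.triple for e in self.edges}

    def edges_of_type(self, edge_type: str) -> set[TypedEdge]:
        return {e for e in self.edges if e.type == edge_type}

    def layer_counts(self) -> dict[str, int]:
        return {t: len(self.edges_of_type(t)) for t in EDGE_TYPES}


def _normalize_edge(source: str, target: str, edge_type: str,
                    provenance: str) -> TypedEdge:
    if edge_type not in EDGE_TYPES:
        raise ValueError(f"unknown edge type {edge_type!r}; expected one of {EDGE_TYPES}")
    s, t = normalize_symbol(source), normalize_symbol(target)
    if edge_type in UNDIRECTED_TYPES and s > t:
        s, t = t, s
    return TypedEdge(source=s, target=t, type=edge_type, provenance=provenance)


def assemble(physical: Iterable[EdgeSpec] = (),
             repression: Iterable[EdgeSpec] = (),
             predicted: Iterable[EdgeSpec] = (),
             roles: Mapping[str, str] | None = None) -> RegulatoryNetwork:
    """Merge the three evidence layers into one typed network.

    Each layer is an iterable of (source, target) or (source, target,
    provenance) tuples.  Nodes are auto-declared from edge endpoints; a
    ``roles`` mapping (symbol -> hox | tf | pathway_member | receptor) tags
    them, defaulting to "gene".  Same-triple duplicates with different
    provenance merge into one edge with concatenated provenance.
    """
    merged: dict[tuple[str, str, str], list[str]] = {}
    for layer, edge_type in ((physical, "physical"), (repression, "repression"),
                             (predicted, "predicted_binding")):
        for spec in layer:
            prov = spec[2] if len(spec) > 2 else ""
            e = _normalize_edge(spec[0], spec[1], edge_type, prov)
            provs = merged.setdefault(e.triple, [])
            if e.provenance and e.provenance not in provs:
                provs.append(e.provenance)

    roles = {normalize_symbol(k): v for k, v in (roles or {}).items()}
    net = RegulatoryNetwork()
    for (s, t, typ), provs in merged.items():
        net.edges.add(TypedEdge(s, t, typ, "; ".join(provs)))
        for node in (s, t):
            net.nodes.setdefault(node, roles.get(node, "gene"))
    return net


def to_networkx(net: RegulatoryNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for node, role in sorted(net.nodes.items()):
        g.add_node(node, role=role)
    for e in sorted(net.edges, key=lambda e: e.triple):
        g.add_edge(e.source, e.target, key=e.type, type=e.type,
                   provenance=e.provenance,
                   directed=e.type not in UNDIRECTED_TYPES)
    return g


def export_network(net: RegulatoryNetwork, path: str | Path,
                   format: Literal["graphml", "sif"] = "graphml") -> Path:
    """Write the network as GraphML (full attributes) or SIF (typed triples)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif format == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for s, t, typ in sorted(net.edge_triples()):
                fh.write(f"{s}\t{typ}\t{t}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_network(path: str | Path,
                   format: Literal["graphml", "sif"] = "graphml") -> RegulatoryNetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    net = RegulatoryNetwork()
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for node, data in g.nodes(data=True):
            net.nodes[node] = data.get("role", "gene")
        for s, t, data in g.edges(data=True):
            net.edges.add(TypedEdge(s, t, data["type"], data.get("provenance", "")))
    elif format == "sif":
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: SIF line needs 3 fields")
            s, typ, t = parts
            net.edges.add(_normalize_edge(s, t, typ, ""))
            for node in (s, t):
                net.nodes.setdefault(normalize_symbol(node), "gene")
    else:
        raise ValueError(f"unknown format {format!r}")
    return net
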