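"""Serialization: graph export/import, omics-table reading, run configuration.

All writers emit elements in lexicographic id order, so output is
deterministic and GraphML survives an export -> import -> export
round trip byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape, quoteattr

import pandas as pd
import yaml

from .metabolomics_stats import OmicsTable
from .network_builder import Edge, NetworkGraph, Node
from .omics_overlay import AnnotatedGraph, style_attributes

__all__ = [
    "GRAPH_FORMATS",
    "RunConfig",
    "export_graph",
    "import_graphml",
    "read_omics_table",
    "write_omics_table",
]

GRAPH_FORMATS = ("graphml", "sif", "cx-json", "edge-tsv")

_NODE_KEYS = [
    ("kind", "string"),
    ("name", "string"),
    ("measured", "boolean"),
    ("log2fc", "double"),
    ("q", "double"),
    ("shape", "string"),
    ("fill", "string"),
    ("size", "double"),
    ("outline", "string"),
]
_EDGE_KEYS = [
    ("role", "string"),
    ("directed_edge", "boolean"),
    ("reaction_id", "string"),
]


@dataclass
class RunConfig:
    """Thresholds, seeds, and paths for a pipeline run.

    Round-trips unchanged through YAML serialization.
    """

    q_threshold_metabolite: float = 0.1
    q_threshold_gene: float = 0.05
    flic_threshold: float = 40.0
    flic_min_run: int = 5
    max_missing_frac: float = 0.5
    missing_filter_mode: str = "all-groups"
    seed: int = 0
    input_paths: dict[str, str] = field(default_factory=dict)
    dialect: str = "native-tsv"
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("q_threshold_metabolite", "q_threshold_gene", "flic_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flic_min_run < 1:
            raise ValueError("flic_min_run must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _graph_and_attrs(g: NetworkGraph | AnnotatedGraph):
    if isinstance(g, AnnotatedGraph):
        return g.graph, style_attributes(g)
    return g, {}


def _fmt_value(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_graphml(graph: NetworkGraph, attrs: dict, path: Path) -> None:
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
    ]
    for key, typ in _NODE_KEYS:
        lines.append(
            f'  <key id="n_{key}" for="node" attr.name="{key}" attr.type="{typ}"/>'
        )
    for key, typ in _EDGE_KEYS:
        lines.append(
            f'  <key id="e_{key}" for="edge" attr.name="{key}" attr.type="{typ}"/>'
        )
    gtype = escape(graph.graph_type)
    lines.append(f'  <graph edgedefault="directed" id={quoteattr(gtype)}>')
    for node in graph.sorted_nodes():
        lines.append(f"    <node id={quoteattr(node.id)}>")
        node_attrs: dict[str, object] = {"kind": node.kind, "name": node.name}
        node_attrs.update(attrs.get(node.id, {}))
        for key, _typ in _NODE_KEYS:
            if key in node_attrs:
                lines.append(
                    f'      <data key="n_{key}">{escape(_fmt_value(node_attrs[key]))}</data>'
                )
        lines.append("    </node>")
    for edge in graph.sorted_edges():
        lines.append(
            f"    <edge source={quoteattr(edge.source)} target={quoteattr(edge.target)}>"
        )
        edge_attrs: dict[str, object] = {"role": edge.role, "directed_edge": edge.directed}
        if edge.reaction_id:
            edge_attrs["reaction_id"] = edge.reaction_id
        for key, _typ in _EDGE_KEYS:
            if key in edge_attrs:
                lines.append(
                    f'      <data key="e_{key}">{escape(_fmt_value(edge_attrs[key]))}</data>'
                )
        lines.append("    </edge>")
    lines.append("  </graph>")
    lines.append("</graphml>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def import_graphml(path: str | Path) -> NetworkGraph:
    """Read a GraphML file written by :func:`export_graph` back into a graph."""
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    tree = ET.parse(path)
    root = tree.getroot()
    graph_el = root.find("g:graph", ns)
    if graph_el is None:
        raise ValueError(f"{path}: no <graph> element")
    g = NetworkGraph(graph_type=graph_el.get("id", "CREG"), provenance=f"graphml:{path}")
    for node_el in graph_el.findall("g:node", ns):
        data = {
            d.get("key", ""): d.text or ""
            for d in node_el.findall("g:data", ns)
        }
        g.add_node(
            Node(
                id=node_el.get("id", ""),
                kind=data.get("n_kind", "compound"),
                name=data.get("n_name", node_el.get("id", "")),
            )
        )
    for edge_el in graph_el.findall("g:edge", ns):
        data = {
            d.get("key", ""): d.text or ""
            for d in edge_el.findall("g:data", ns)
        }
        g.add_edge(
            Edge(
                source=edge_el.get("source", ""),
                target=edge_el.get("target", ""),
                directed=data.get("e_directed_edge", "true") == "true",
                role=data.get("e_role", "compound-compound"),
                reaction_id=data.get("e_reaction_id") or None,
            )
        )
    return g


def export_graph(
    g: NetworkGraph | AnnotatedGraph, fmt: str, path: str | Path
) -> Path:
    """Write *g* to *path* in one of :data:`GRAPH_FORMATS`.

    GraphML carries node kind/style/measurement attributes; SIF uses the
    edge role as the interaction type; CX-JSON emits nodes/edges/
    nodeAttributes aspects; edge-TSV is a flat edge list.
    """
    graph, attrs = _graph_and_attrs(g)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        _write_graphml(graph, attrs, path)
    elif fmt == "sif":
        lines = []
        linked = set()
        for e in graph.sorted_edges():
            lines.append(f"{e.source}\t{e.role}\t{e.target}")
            linked.update((e.source, e.target))
        for node in graph.sorted_nodes():
            if node.id not in linked:
                lines.append(node.id)
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "cx-json":
        nodes_aspect = [
            {"@id": i, "n": node.id, "r": node.name}
            for i, node in enumerate(graph.sorted_nodes())
        ]
        index = {node.id: i for i, node in enumerate(graph.sorted_nodes())}
        edges_aspect = [
            {
                "@id": j,
                "s": index[e.source],
                "t": index[e.target],
                "i": e.role,
            }
            for j, e in enumerate(graph.sorted_edges())
        ]
        node_attrs = []
        for node in graph.sorted_nodes():
            merged: dict[str, object] = {"kind": node.kind}
            merged.update(attrs.get(node.id, {}))
            for key, value in sorted(merged.items()):
                node_attrs.append(
                    {"po": index[node.id], "n": key, "v": _fmt_value(value)}
                )
        doc = [
            {"metaData": [{"name": "nodes"}, {"name": "edges"}, {"name": "nodeAttributes"}]},
            {"nodes": nodes_aspect},
            {"edges": edges_aspect},
            {"nodeAttributes": node_attrs},
        ]
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    elif fmt == "edge-tsv":
        lines = ["source\ttarget\tdirected\trole\treaction_id"]
        for e in graph.sorted_edges():
            lines.append(
                f"{e.source}\t{e.target}\t{_fmt_value(e.directed)}\t{e.role}\t{e.reaction_id or ''}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    return path


# ---------------------------------------------------------------------------
# omics tables
# ---------------------------------------------------------------------------


def read_omics_table(
    path: str | Path, condition_map_path: str | Path
) -> OmicsTable:
    """Read a features-x-samples CSV/TSV plus a sample->condition sidecar.

    The first column holds feature ids, the header row sample ids; empty
    cells or ``NA`` are missing.  The sidecar is a two-column TSV
    (sample, condition).  Every sample in the table must appear in the
    sidecar, duplicated feature ids are an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    values = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=True)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.duplicated().any():
        dup = sorted(values.index[values.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicated feature id(s): {dup[:5]}")
    cond_map = pd.read_csv(condition_map_path, sep="\t", dtype=str)
    if list(cond_map.columns[:2]) != ["sample", "condition"]:
        raise ValueError(
            f"{condition_map_path}: expected columns (sample, condition), "
            f"got {list(cond_map.columns)}"
        )
    conditions = cond_map.set_index("sample")["condition"]
    unknown = [s for s in values.columns if s not in conditions.index]
    if unknown:
        raise ValueError(f"sample(s) missing from condition map: {unknown[:5]}")
    return OmicsTable(
        values=values.astype(float),
        conditions=conditions.reindex(values.columns),
        scale="raw",
    )


def write_omics_table(
    t: OmicsTable, path: str | Path, condition_map_path: str | Path
) -> None:
    """Inverse of :func:`read_omics_table` (missing cells become 'NA')."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    t.values.to_csv(path, sep=sep, na_rep="NA")
    pd.DataFrame(
        {"sample": t.samples, "condition": [t.conditions[s] for s in t.samples]}
    ).to_csv(condition_map_path, sep="\t", index=False)
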