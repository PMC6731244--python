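"""Overlay of differential omics results onto a network, with visual styles.

The categorical encoding: compounds are hexagons (red when measured,
salmon when not), genes are circles (blue / light blue), enzymes green
squares, reactions gray diamonds.  Node size grows linearly with
|log2 fold change| and is clipped; a green outline marks significance
at the configured q threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .network_builder import NetworkGraph
from .pathway_db import MetabolicDatabase, resolve_identifiers

__all__ = [
    "Measurement",
    "NodeStyle",
    "MatchReport",
    "AnnotatedGraph",
    "attach_omics",
    "style_nodes",
    "BASE_SIZE",
    "MAX_SIZE_FACTOR",
]

logger = logging.getLogger(__name__)

BASE_SIZE = 30.0
MAX_SIZE_FACTOR = 4.0

SHAPES = {"compound": "hexagon", "gene": "circle", "enzyme": "square", "reaction": "diamond"}

FILLS = {
    ("compound", True): "measured-red",
    ("compound", False): "unmeasured-salmon",
    ("gene", True): "measured-blue",
    ("gene", False): "unmeasured-lightblue",
    ("enzyme", True): "enzyme-green",
    ("enzyme", False): "enzyme-green",
    ("reaction", True): "reaction-gray",
    ("reaction", False): "reaction-gray",
}


@dataclass(frozen=True)
class Measurement:
    log2_fold_change: float | None
    q_value: float | None
    measured: bool

    @staticmethod
    def unmeasured() -> "Measurement":
        return Measurement(None, None, False)


@dataclass(frozen=True)
class NodeStyle:
    shape: str
    fill: str
    size: float
    outline: str  # "significant-green" | "none"


@dataclass
class MatchReport:
    matched: dict[str, int] = field(default_factory=dict)
    unmatched: dict[str, int] = field(default_factory=dict)


@dataclass
class AnnotatedGraph:
    graph: NetworkGraph
    measurements: dict[str, Measurement]
    styles: dict[str, NodeStyle] = field(default_factory=dict)
    match_report: MatchReport = field(default_factory=MatchReport)

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.measurements)
        if missing:
            raise ValueError(f"nodes without measurement record: {sorted(missing)[:5]}")


def _check_result_table(table: pd.DataFrame, label: str) -> pd.DataFrame:
    required = {"feature", "log2fc", "q"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{label} table missing column(s) {sorted(missing)}")
    dup = table["feature"][table["feature"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{label} table has duplicate feature rows (pre-aggregate them): "
            f"{sorted(dup.unique())[:5]}"
        )
    return table.set_index("feature")


def attach_omics(
    g: NetworkGraph,
    compound_results: pd.DataFrame | None,
    gene_results: pd.DataFrame | None,
    db: MetabolicDatabase,
) -> AnnotatedGraph:
    """Join differential-result tables onto graph nodes.

    *compound_results* / *gene_results* need columns ``feature``,
    ``log2fc``, ``q``.  Feature ids are resolved against *db* (id, name,
    synonym, xref), then matched to nodes of the corresponding kind.
    Nodes with no matching row become unmeasured.  Duplicate feature
    rows are an error.
    """
    empty = pd.DataFrame(columns=["feature", "log2fc", "q"])
    tables = {
        "compound": _check_result_table(
            compound_results if compound_results is not None else empty, "compound"
        ),
        "gene": _check_result_table(
            gene_results if gene_results is not None else empty, "gene"
        ),
    }

    # feature -> node id, via the database resolver, restricted per kind
    node_hits: dict[str, Measurement] = {}
    report = MatchReport(
        matched={"compound": 0, "gene": 0}, unmatched={"compound": 0, "gene": 0}
    )
    for kind, table in tables.items():
        if table.empty:
            continue
        resolution = resolve_identifiers(db, [str(f) for f in table.index])
        for feature, row in table.iterrows():
            target = None
            for match in resolution.matches.get(str(feature), ()):
                if match.entity_class == kind and match.entity_id in g.nodes:
                    target = match.entity_id
                    break
            if target is None:
                report.unmatched[kind] += 1
                continue
            if target in node_hits:
                raise ValueError(
                    f"feature {feature!r} maps onto node {target!r} which already "
                    "carries a measurement; pre-aggregate duplicate features"
                )
            node_hits[target] = Measurement(
                float(row["log2fc"]), float(row["q"]), True
            )
            report.matched[kind] += 1

    measurements = {
        nid: node_hits.get(nid, Measurement.unmeasured()) for nid in g.nodes
    }
    return AnnotatedGraph(graph=g, measurements=measurements, match_report=report)


def _style_one(
    kind: str,
    m: Measurement,
    size_gain: float,
    q_threshold: float,
    base_size: float,
) -> NodeStyle:
    measured = m.measured
    l2fc = m.log2_fold_change
    if measured and (l2fc is None or not math.isfinite(l2fc)):
        logger.warning("non-finite fold change treated as unmeasured")
        measured = False
        l2fc = None
    if measured and l2fc is not None:
        size = base_size * (1.0 + size_gain * abs(l2fc))
        size = min(max(size, base_size), MAX_SIZE_FACTOR * base_size)
    else:
        size = base_size
    significant = (
        measured and m.q_value is not None and math.isfinite(m.q_value) and m.q_value < q_threshold
    )
    return NodeStyle(
        shape=SHAPES[kind],
        fill=FILLS[(kind, measured)],
        size=size,
        outline="significant-green" if significant else "none",
    )


def style_nodes(
    ag: AnnotatedGraph,
    size_gain: float = 0.5,
    q_threshold: float = 0.1,
    q_threshold_gene: float | None = 0.05,
    base_size: float = BASE_SIZE,
) -> AnnotatedGraph:
    """Fill every node's :class:`NodeStyle` from its measurement record.

    size = base * (1 + size_gain * |log2FC|), clipped to [base, 4*base];
    outline is green iff measured and q below the threshold for that
    node kind (compounds default 0.1, genes 0.05).  Pure function of
    (measurements, node kinds, parameters).
    """
    if size_gain <= 0:
        raise ValueError("size_gain must be positive")
    styles: dict[str, NodeStyle] = {}
    for nid, node in ag.graph.nodes.items():
        thr = q_threshold
        if node.kind == "gene" and q_threshold_gene is not None:
            thr = q_threshold_gene
        styles[nid] = _style_one(node.kind, ag.measurements[nid], size_gain, thr, base_size)
    return AnnotatedGraph(
        graph=ag.graph,
        measurements=dict(ag.measurements),
        styles=styles,
        match_report=ag.match_report,
    )


def style_attributes(ag: AnnotatedGraph) -> Mapping[str, dict[str, object]]:
    """Per-node attribute dict suitable for GraphML/CX export columns."""
    out: dict[str, dict[str, object]] = {}
    for nid in sorted(ag.graph.nodes):
        m = ag.measurements[nid]
        attrs: dict[str, object] = {"measured": m.measured}
        if m.measured and m.log2_fold_change is not None:
            attrs["log2fc"] = m.log2_fold_change
            attrs["q"] = m.q_value
        style = ag.styles.get(nid)
        if style is not None:
            attrs.update(
                shape=style.shape, fill=style.fill, size=style.size, outline=style.outline
            )
        out[nid] = attrs
    return out
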