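"""Construction of the four metabolic graph types (C, CR, CG, CREG).

Node kinds are ``compound``, ``reaction``, ``enzyme``, ``gene``.  Edges
between compounds and reactions are directed (substrate -> reaction,
reaction -> product); catalysis (reaction--enzyme) and encoding
(enzyme--gene) edges are undirected, as are the compound--gene edges of
the CG projection.  Compound (C) graphs carry one substrate->product
edge per generating reaction, undirected when the reaction is
reversible.  Nodes of the same kind are never joined in CR/CG/CREG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .pathway_db import MetabolicDatabase

__all__ = [
    "Node",
    "Edge",
    "NetworkGraph",
    "GRAPH_TYPES",
    "expand_seeds",
    "query_pathway",
    "build_network",
    "creg_to_cg",
    "extract_subnetwork",
]

GRAPH_TYPES = ("C", "CR", "CG", "CREG")

NODE_KINDS = ("compound", "reaction", "enzyme", "gene")

EDGE_ROLES = ("substrate", "product", "catalysis", "encoding", "compound-compound", "compound-gene")


@dataclass(frozen=True)
class Node:
    id: str
    kind: str
    name: str

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    directed: bool
    role: str
    reaction_id: str | None = None  # populated on C-graph edges only

    def __post_init__(self) -> None:
        if self.role not in EDGE_ROLES:
            raise ValueError(f"unknown edge role {self.role!r}")

    def key(self) -> tuple:
        if self.directed:
            return (self.source, self.target, self.role, self.reaction_id or "")
        a, b = sorted((self.source, self.target))
        return (a, b, self.role, self.reaction_id or "")


@dataclass
class NetworkGraph:
    """A typed-node graph of one of the four supported types."""

    graph_type: str
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.graph_type not in GRAPH_TYPES:
            raise ValueError(f"unknown graph type {self.graph_type!r}")

    # -- construction helpers -------------------------------------------------
    def add_node(self, node: Node) -> None:
        existing = self.nodes.get(node.id)
        if existing is not None and existing != node:
            raise ValueError(f"conflicting definitions for node {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: Edge) -> None:
        for end in (edge.source, edge.target):
            if end not in self.nodes:
                raise ValueError(f"edge endpoint {end!r} is not a node")
        if self.graph_type != "C":
            if self.nodes[edge.source].kind == self.nodes[edge.target].kind:
                raise ValueError(
                    f"same-kind edge {edge.source!r}--{edge.target!r} not allowed "
                    f"in {self.graph_type} graphs"
                )
        if edge.key() not in self._edge_keys():
            self.edges.append(edge)

    def _edge_keys(self) -> set[tuple]:
        return {e.key() for e in self.edges}

    # -- views ---------------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[Node]:
        return [n for n in self.sorted_nodes() if n.kind == kind]

    def sorted_nodes(self) -> list[Node]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=Edge.key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if node_id in (e.source, e.target))

    def neighbors(self, node_id: str) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            if e.source == node_id:
                out.add(e.target)
            elif e.target == node_id:
                out.add(e.source)
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        """Lossless conversion; undirected edges carry ``directed=False``."""
        g = nx.MultiDiGraph(graph_type=self.graph_type, provenance=self.provenance)
        for node in self.sorted_nodes():
            g.add_node(node.id, kind=node.kind, name=node.name)
        for e in self.sorted_edges():
            attrs = {"directed": e.directed, "role": e.role}
            if e.reaction_id:
                attrs["reaction_id"] = e.reaction_id
            g.add_edge(e.source, e.target, **attrs)
        return g

    def canonical(self) -> tuple:
        """Hashable canonical form: node set + edge key set (order-free)."""
        return (
            self.graph_type,
            tuple((n.id, n.kind, n.name) for n in self.sorted_nodes()),
            tuple(sorted(self._edge_keys())),
        )

    def is_equivalent(self, other: "NetworkGraph") -> bool:
        return self.canonical() == other.canonical()


def expand_seeds(
    db: MetabolicDatabase,
    compound_ids: Iterable[str] = (),
    gene_ids: Iterable[str] = (),
) -> set[str]:
    """Reactions incident to seed compounds or catalyzed via seed genes.

    One expansion step only: a reaction is included iff a seed compound
    is among its substrates/products, or a seed gene encodes an enzyme
    that catalyzes it.
    """
    compound_ids = list(compound_ids)
    gene_ids = list(gene_ids)
    bad = [c for c in compound_ids if c not in db.compounds]
    bad += [g for g in gene_ids if g not in db.genes]
    if bad:
        raise KeyError(f"unresolvable seed id(s): {sorted(bad)}")
    out: set[str] = set()
    for c in compound_ids:
        out |= db.compound_to_reactions.get(c, frozenset())
    for g in gene_ids:
        for e in db.gene_to_enzymes.get(g, frozenset()):
            out |= db.enzyme_to_reactions.get(e, frozenset())
    return out


def query_pathway(db: MetabolicDatabase, pathway_id: str) -> set[str]:
    """The reaction-id set of one pathway."""
    try:
        pw = db.pathways[pathway_id]
    except KeyError:
        raise KeyError(f"unknown pathway id {pathway_id!r}") from None
    return set(pw.reaction_ids)


def _compound_node(db: MetabolicDatabase, cid: str) -> Node:
    c = db.compounds[cid]
    return Node(c.id, "compound", c.name)


def build_network(
    db: MetabolicDatabase, reaction_ids: Iterable[str], graph_type: str
) -> NetworkGraph:
    """Build one of the four graph types from a reaction-id set.

    CREG closure: every compound, catalyzing enzyme, and encoding gene
    touched by the reactions.  CR drops enzymes/genes; CG keeps compounds
    and genes joined when a compound-reaction-enzyme-gene chain exists;
    C joins substrate->product compound pairs per reaction (undirected
    when the reaction is reversible), the generating reaction id stored
    on the edge.  An empty reaction set gives an empty graph.
    """
    if graph_type not in GRAPH_TYPES:
        raise ValueError(f"unknown graph type {graph_type!r}")
    rids = sorted(set(reaction_ids))
    missing = [r for r in rids if r not in db.reactions]
    if missing:
        raise KeyError(f"unknown reaction id(s): {missing}")
    g = NetworkGraph(graph_type=graph_type, provenance=f"build_network({graph_type}, {len(rids)} reactions)")

    for rid in rids:
        rxn = db.reactions[rid]
        subs = sorted(set(rxn.substrate_ids))
        prods = sorted(set(rxn.product_ids))
        enzymes = sorted(e for e in set(rxn.enzyme_ids) if e in db.enzymes)

        if graph_type == "C":
            for cid in subs + prods:
                g.add_node(_compound_node(db, cid))
            for s in subs:
                for p in prods:
                    g.add_edge(
                        Edge(s, p, directed=not rxn.reversible, role="compound-compound", reaction_id=rid)
                    )
            continue

        if graph_type in ("CR", "CREG"):
            g.add_node(Node(rid, "reaction", rid))
            for cid in subs + prods:
                g.add_node(_compound_node(db, cid))
            for s in subs:
                g.add_edge(Edge(s, rid, directed=True, role="substrate"))
            for p in prods:
                g.add_edge(Edge(rid, p, directed=True, role="product"))

        if graph_type == "CREG":
            for eid in enzymes:
                enz = db.enzymes[eid]
                g.add_node(Node(eid, "enzyme", enz.name or eid))
                g.add_edge(Edge(rid, eid, directed=False, role="catalysis"))
                for gid in sorted(set(enz.gene_ids)):
                    if gid not in db.genes:
                        continue
                    gene = db.genes[gid]
                    g.add_node(Node(gid, "gene", gene.symbol or gid))
                    g.add_edge(Edge(eid, gid, directed=False, role="encoding"))

        if graph_type == "CG":
            for cid in subs + prods:
                g.add_node(_compound_node(db, cid))
            gene_ids: set[str] = set()
            for eid in enzymes:
                for gid in db.enzymes[eid].gene_ids:
                    if gid in db.genes:
                        gene_ids.add(gid)
            for gid in sorted(gene_ids):
                gene = db.genes[gid]
                g.add_node(Node(gid, "gene", gene.symbol or gid))
                for cid in subs + prods:
                    g.add_edge(Edge(cid, gid, directed=False, role="compound-gene"))
    return g


def creg_to_cg(g: NetworkGraph) -> NetworkGraph:
    """Contract a CREG graph to its CG projection.

    A compound and a gene are joined iff a compound--reaction--enzyme--gene
    path exists in *g*.  Byte-identical (canonically) to building CG
    directly from the same reaction set.
    """
    if g.graph_type != "CREG":
        raise ValueError(f"creg_to_cg requires a CREG graph, got {g.graph_type!r}")
    out = NetworkGraph(graph_type="CG", provenance=f"creg_to_cg({g.provenance})")
    for node in g.sorted_nodes():
        if node.kind in ("compound", "gene"):
            out.add_node(node)
    # adjacency maps per role
    rxn_compounds: dict[str, set[str]] = {}
    rxn_enzymes: dict[str, set[str]] = {}
    enz_genes: dict[str, set[str]] = {}
    for e in g.edges:
        a, b = e.source, e.target
        ka, kb = g.nodes[a].kind, g.nodes[b].kind
        if {ka, kb} == {"compound", "reaction"}:
            rid = a if ka == "reaction" else b
            cid = b if ka == "reaction" else a
            rxn_compounds.setdefault(rid, set()).add(cid)
        elif {ka, kb} == {"reaction", "enzyme"}:
            rid = a if ka == "reaction" else b
            eid = b if ka == "reaction" else a
            rxn_enzymes.setdefault(rid, set()).add(eid)
        elif {ka, kb} == {"enzyme", "gene"}:
            eid = a if ka == "enzyme" else b
            gid = b if ka == "enzyme" else a
            enz_genes.setdefault(eid, set()).add(gid)
    for rid in sorted(rxn_compounds):
        genes: set[str] = set()
        for eid in rxn_enzymes.get(rid, ()):
            genes |= enz_genes.get(eid, set())
        for cid in sorted(rxn_compounds[rid]):
            for gid in sorted(genes):
                out.add_edge(Edge(cid, gid, directed=False, role="compound-gene"))
    return out


def extract_subnetwork(
    g: NetworkGraph,
    keep: str | Iterable[str],
    db: MetabolicDatabase,
) -> NetworkGraph:
    """Induced subgraph on a pathway's nodes or an explicit node-id set.

    Pathway mode (*keep* is a pathway id known to *db*) retains every
    node that the pathway's reactions would generate for this graph
    type; node-set mode keeps exactly the given ids.  Edges of *g* with
    both endpoints retained survive.  Graph type is preserved and
    provenance records the refinement.
    """
    if isinstance(keep, str):
        if keep not in db.pathways:
            raise KeyError(f"unknown pathway id {keep!r}")
        reference = build_network(db, query_pathway(db, keep), g.graph_type)
        node_ids = set(reference.nodes)
        label = f"pathway:{keep}"
    else:
        node_ids = set(keep)
        if not node_ids:
            raise ValueError("keep set must be non-empty")
        unknown = node_ids - set(g.nodes) - set(db.compounds) - set(db.reactions) - set(db.enzymes) - set(db.genes)
        if unknown:
            raise KeyError(f"unresolvable node id(s): {sorted(unknown)}")
        label = f"nodes:{len(node_ids)}"
    out = NetworkGraph(
        graph_type=g.graph_type,
        provenance=f"{g.provenance} | subnetwork({label})",
    )
    for node in g.sorted_nodes():
        if node.id in node_ids:
            out.add_node(node)
    for e in g.sorted_edges():
        if e.source in out.nodes and e.target in out.nodes:
            out.add_edge(e)
    return out
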