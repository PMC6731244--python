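"""Data model and flat-file I/O for a compound-reaction-enzyme-gene-pathway database.

Two dialects are supported:

``native-tsv``
    Five UTF-8 TSV tables (``compounds.tsv``, ``reactions.tsv``,
    ``enzymes.tsv``, ``genes.tsv``, ``pathways.tsv``) with a mandatory
    header row.  List-valued cells are pipe-delimited; cross-reference
    cells use ``namespace:value`` pairs.  Writing is canonical (entities
    sorted by id), so write -> load -> write is byte-identical.

``biocyc-subset``
    A minimal reader for the attribute-value record style of BioCyc
    ``.dat`` files, covering only the attributes that map onto the data
    model here (see :data:`_BIOCYC_FILES`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Compound",
    "Reaction",
    "Enzyme",
    "Gene",
    "Pathway",
    "MetabolicDatabase",
    "ValidationReport",
    "Violation",
    "ResolutionReport",
    "Match",
    "DatabaseLoadError",
    "load_database",
    "write_database",
    "validate_database",
    "resolve_identifiers",
]

LIST_SEP = "|"
XREF_SEP = ":"


class DatabaseLoadError(ValueError):
    """Raised for missing tables or malformed rows at load time."""


@dataclass(frozen=True)
class Compound:
    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    xrefs: Mapping[str, str] = field(default_factory=dict)
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if not self.name:
            raise ValueError(f"compound {self.id!r}: name must be non-empty")


@dataclass(frozen=True)
class Reaction:
    id: str
    substrate_ids: tuple[str, ...]
    product_ids: tuple[str, ...]
    reversible: bool = False
    enzyme_ids: tuple[str, ...] = ()
    pathway_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not (self.substrate_ids or self.product_ids):
            raise ValueError(f"reaction {self.id!r}: no substrates or products")
        both = set(self.substrate_ids) & set(self.product_ids)
        if both:
            raise ValueError(
                f"reaction {self.id!r}: compound(s) {sorted(both)} appear on "
                "both sides; self-converting reactions are rejected"
            )


@dataclass(frozen=True)
class Enzyme:
    id: str
    name: str = ""
    gene_ids: tuple[str, ...] = ()
    reaction_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("enzyme id must be non-empty")


@dataclass(frozen=True)
class Gene:
    id: str
    symbol: str = ""
    enzyme_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str = ""
    compound_ids: tuple[str, ...] = ()
    reaction_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pathway id must be non-empty")


@dataclass(frozen=True)
class Violation:
    """One referential-integrity failure: *entity.field* names *missing_id*."""

    entity_kind: str
    entity_id: str
    field: str
    missing_id: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


@dataclass(frozen=True)
class Match:
    entity_class: str  # compound | reaction | enzyme | gene | pathway
    entity_id: str
    kind: str  # id | name | synonym | xref


@dataclass
class ResolutionReport:
    matches: dict[str, tuple[Match, ...]] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)
    ambiguous: dict[str, tuple[Match, ...]] = field(default_factory=dict)

    def best(self, query: str) -> Match | None:
        """First match for *query* (compound before gene before the rest)."""
        hits = self.matches.get(query)
        return hits[0] if hits else None


class MetabolicDatabase:
    """Keyed collections of the five entity classes plus derived indices.

    Indices mirror the forward relationships stored on the entities and are
    rebuilt whenever the database is constructed; they are read-only views.
    """

    def __init__(
        self,
        compounds: Iterable[Compound] = (),
        reactions: Iterable[Reaction] = (),
        enzymes: Iterable[Enzyme] = (),
        genes: Iterable[Gene] = (),
        pathways: Iterable[Pathway] = (),
        provenance: str = "",
    ) -> None:
        self.compounds = self._keyed(compounds, "compound")
        self.reactions = self._keyed(reactions, "reaction")
        self.enzymes = self._keyed(enzymes, "enzyme")
        self.genes = self._keyed(genes, "gene")
        self.pathways = self._keyed(pathways, "pathway")
        self.provenance = provenance
        self._build_indices()

    @staticmethod
    def _keyed(entities: Iterable, kind: str) -> dict[str, object]:
        out: dict[str, object] = {}
        for e in entities:
            if e.id in out:
                raise ValueError(f"duplicate {kind} id {e.id!r}")
            out[e.id] = e
        return out

    def _build_indices(self) -> None:
        self.compound_to_reactions: dict[str, frozenset[str]] = {}
        self.enzyme_to_reactions: dict[str, frozenset[str]] = {}
        self.gene_to_enzymes: dict[str, frozenset[str]] = {}

        c2r: dict[str, set[str]] = {c: set() for c in self.compounds}
        e2r: dict[str, set[str]] = {e: set() for e in self.enzymes}
        g2e: dict[str, set[str]] = {g: set() for g in self.genes}
        for r in self.reactions.values():
            for c in (*r.substrate_ids, *r.product_ids):
                c2r.setdefault(c, set()).add(r.id)
            for e in r.enzyme_ids:
                e2r.setdefault(e, set()).add(r.id)
        for e in self.enzymes.values():
            for rid in e.reaction_ids:
                e2r[e.id].add(rid)
            for g in e.gene_ids:
                g2e.setdefault(g, set()).add(e.id)
        for g in self.genes.values():
            for eid in g.enzyme_ids:
                g2e[g.id].add(eid)
        self.compound_to_reactions = {k: frozenset(v) for k, v in c2r.items()}
        self.enzyme_to_reactions = {k: frozenset(v) for k, v in e2r.items()}
        self.gene_to_enzymes = {k: frozenset(v) for k, v in g2e.items()}

    def counts(self) -> dict[str, int]:
        return {
            "compounds": len(self.compounds),
            "reactions": len(self.reactions),
            "enzymes": len(self.enzymes),
            "genes": len(self.genes),
            "pathways": len(self.pathways),
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicDatabase):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.enzymes == other.enzymes
            and self.genes == other.genes
            and self.pathways == other.pathways
        )

    def __repr__(self) -> str:  # pragma: no cover
        c = self.counts()
        return (
            f"<MetabolicDatabase {c['compounds']}C/{c['reactions']}R/"
            f"{c['enzymes']}E/{c['genes']}G/{c['pathways']}P>"
        )


# ---------------------------------------------------------------------------
# native-tsv dialect
# ---------------------------------------------------------------------------

_TABLES = {
    "compounds": ("id", "name", "synonyms", "xrefs", "class_label"),
    "reactions": ("id", "substrates", "products", "reversible", "enzymes", "pathways"),
    "enzymes": ("id", "name", "genes", "reactions"),
    "genes": ("id", "symbol", "enzymes"),
    "pathways": ("id", "name", "compounds", "reactions"),
}


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(s for s in cell.split(LIST_SEP) if s) if cell else ()


def _join_list(items: Iterable[str]) -> str:
    return LIST_SEP.join(items)


def _parse_xrefs(cell: str, where: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in _split_list(cell):
        if XREF_SEP not in item:
            raise DatabaseLoadError(f"{where}: malformed xref {item!r} (need namespace:value)")
        ns, value = item.split(XREF_SEP, 1)
        out[ns] = value
    return out


def _format_xrefs(xrefs: Mapping[str, str]) -> str:
    return _join_list(f"{ns}{XREF_SEP}{v}" for ns, v in sorted(xrefs.items()))


def _parse_bool(cell: str, where: str) -> bool:
    low = cell.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no", ""}:
        return False
    raise DatabaseLoadError(f"{where}: cannot parse boolean {cell!r}")


def _read_table(path: Path, name: str) -> list[dict[str, str]]:
    fp = path / f"{name}.tsv"
    if not fp.exists():
        raise DatabaseLoadError(f"missing table file: {fp}")
    expected = _TABLES[name]
    rows: list[dict[str, str]] = []
    with fp.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DatabaseLoadError(f"{fp}: empty file, header row required") from None
        if tuple(header) != expected:
            raise DatabaseLoadError(
                f"{fp}: bad header {header!r}, expected {list(expected)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) != len(expected):
                raise DatabaseLoadError(
                    f"{fp}:{lineno}: expected {len(expected)} columns, got {len(row)}"
                )
            rows.append(dict(zip(expected, row)))
    return rows


def _load_native(path: Path) -> MetabolicDatabase:
    compounds = []
    for row in _read_table(path, "compounds"):
        try:
            compounds.append(
                Compound(
                    id=row["id"],
                    name=row["name"],
                    synonyms=_split_list(row["synonyms"]),
                    xrefs=_parse_xrefs(row["xrefs"], f"compound {row['id']!r}"),
                    class_label=row["class_label"] or None,
                )
            )
        except ValueError as exc:
            raise DatabaseLoadError(f"compounds.tsv: {exc}") from exc
    reactions = []
    for row in _read_table(path, "reactions"):
        try:
            reactions.append(
                Reaction(
                    id=row["id"],
                    substrate_ids=_split_list(row["substrates"]),
                    product_ids=_split_list(row["products"]),
                    reversible=_parse_bool(row["reversible"], f"reaction {row['id']!r}"),
                    enzyme_ids=_split_list(row["enzymes"]),
                    pathway_ids=_split_list(row["pathways"]),
                )
            )
        except ValueError as exc:
            raise DatabaseLoadError(f"reactions.tsv: {exc}") from exc
    enzymes = [
        Enzyme(
            id=row["id"],
            name=row["name"],
            gene_ids=_split_list(row["genes"]),
            reaction_ids=_split_list(row["reactions"]),
        )
        for row in _read_table(path, "enzymes")
    ]
    genes = [
        Gene(id=row["id"], symbol=row["symbol"], enzyme_ids=_split_list(row["enzymes"]))
        for row in _read_table(path, "genes")
    ]
    pathways = [
        Pathway(
            id=row["id"],
            name=row["name"],
            compound_ids=_split_list(row["compounds"]),
            reaction_ids=_split_list(row["reactions"]),
        )
        for row in _read_table(path, "pathways")
    ]
    return MetabolicDatabase(
        compounds, reactions, enzymes, genes, pathways, provenance=f"native-tsv:{path}"
    )


def write_database(db: MetabolicDatabase, path: str | Path) -> None:
    """Write *db* as the five native TSV tables under directory *path*.

    Output is canonical: rows sorted by id, list cells in stored order,
    xrefs sorted by namespace.  ``load_database(write_database(db))`` is
    entity-identical to *db* and byte-stable under repetition.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def _write(name: str, rows: Iterable[tuple[str, ...]]) -> None:
        with (path / f"{name}.tsv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TABLES[name])
            writer.writerows(rows)

    _write(
        "compounds",
        (
            (c.id, c.name, _join_list(c.synonyms), _format_xrefs(c.xrefs), c.class_label or "")
            for c in sorted(db.compounds.values(), key=lambda c: c.id)
        ),
    )
    _write(
        "reactions",
        (
            (
                r.id,
                _join_list(r.substrate_ids),
                _join_list(r.product_ids),
                "true" if r.reversible else "false",
                _join_list(r.enzyme_ids),
                _join_list(r.pathway_ids),
            )
            for r in sorted(db.reactions.values(), key=lambda r: r.id)
        ),
    )
    _write(
        "enzymes",
        (
            (e.id, e.name, _join_list(e.gene_ids), _join_list(e.reaction_ids))
            for e in sorted(db.enzymes.values(), key=lambda e: e.id)
        ),
    )
    _write(
        "genes",
        (
            (g.id, g.symbol, _join_list(g.enzyme_ids))
            for g in sorted(db.genes.values(), key=lambda g: g.id)
        ),
    )
    _write(
        "pathways",
        (
            (p.id, p.name, _join_list(p.compound_ids), _join_list(p.reaction_ids))
            for p in sorted(db.pathways.values(), key=lambda p: p.id)
        ),
    )


# ---------------------------------------------------------------------------
# biocyc-subset dialect
# ---------------------------------------------------------------------------

# file name -> entity class; attribute mapping documented in README
_BIOCYC_FILES = {
    "compounds.dat": "compound",
    "reactions.dat": "reaction",
    "enzymes.dat": "enzyme",
    "genes.dat": "gene",
    "pathways.dat": "pathway",
}


def _parse_dat(fp: Path) -> list[dict[str, list[str]]]:
    """Parse an attribute-value .dat file into one dict per record."""
    records: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] = {}
    with fp.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line == "//":
                if current:
                    records.append(current)
                current = {}
                continue
            if " - " not in line:
                raise DatabaseLoadError(f"{fp}:{lineno}: malformed attribute line {line!r}")
            attr, value = line.split(" - ", 1)
            current.setdefault(attr, []).append(value)
    if current:
        records.append(current)
    return records


def _one(rec: dict[str, list[str]], attr: str, default: str = "") -> str:
    vals = rec.get(attr, [])
    return vals[0] if vals else default


def _load_biocyc(path: Path) -> MetabolicDatabase:
    def recs(name: str) -> list[dict[str, list[str]]]:
        fp = path / name
        if not fp.exists():
            raise DatabaseLoadError(f"missing table file: {fp}")
        return _parse_dat(fp)

    compounds = []
    for rec in recs("compounds.dat"):
        xrefs: dict[str, str] = {}
        for link in rec.get("DBLINKS", []):
            # form: (NAMESPACE "value" ...)
            parts = link.strip("() ").replace('"', "").split()
            if len(parts) >= 2:
                xrefs[parts[0]] = parts[1]
        compounds.append(
            Compound(
                id=_one(rec, "UNIQUE-ID"),
                name=_one(rec, "COMMON-NAME", _one(rec, "UNIQUE-ID")),
                synonyms=tuple(rec.get("SYNONYMS", [])),
                xrefs=xrefs,
                class_label=_one(rec, "TYPES") or None,
            )
        )
    reactions = []
    for rec in recs("reactions.dat"):
        direction = _one(rec, "REACTION-DIRECTION", "LEFT-TO-RIGHT")
        reactions.append(
            Reaction(
                id=_one(rec, "UNIQUE-ID"),
                substrate_ids=tuple(rec.get("LEFT", [])),
                product_ids=tuple(rec.get("RIGHT", [])),
                reversible="REVERSIBLE" in direction,
                enzyme_ids=tuple(rec.get("ENZYME", [])),
                pathway_ids=tuple(rec.get("IN-PATHWAY", [])),
            )
        )
    enzymes = [
        Enzyme(
            id=_one(rec, "UNIQUE-ID"),
            name=_one(rec, "COMMON-NAME"),
            gene_ids=tuple(rec.get("GENE", [])),
            reaction_ids=tuple(rec.get("REACTION", [])),
        )
        for rec in recs("enzymes.dat")
    ]
    genes = [
        Gene(
            id=_one(rec, "UNIQUE-ID"),
            symbol=_one(rec, "COMMON-NAME"),
            enzyme_ids=tuple(rec.get("ENZYME", [])),
        )
        for rec in recs("genes.dat")
    ]
    pathways = [
        Pathway(
            id=_one(rec, "UNIQUE-ID"),
            name=_one(rec, "COMMON-NAME"),
            compound_ids=tuple(rec.get("COMPOUND-LIST", [])),
            reaction_ids=tuple(rec.get("REACTION-LIST", [])),
        )
        for rec in recs("pathways.dat")
    ]
    return MetabolicDatabase(
        compounds, reactions, enzymes, genes, pathways, provenance=f"biocyc-subset:{path}"
    )


DIALECTS = {"native-tsv": _load_native, "biocyc-subset": _load_biocyc}


def load_database(path: str | Path, dialect: str = "native-tsv") -> MetabolicDatabase:
    """Load a database from *path* in the given *dialect*.

    Raises :class:`DatabaseLoadError` for a missing table (naming the
    file) or a malformed row (naming file and line).  Dangling references
    are *not* an error here; they are reported by
    :func:`validate_database`.
    """
    path = Path(path)
    if not path.exists():
        raise DatabaseLoadError(f"database path does not exist: {path}")
    try:
        loader = DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        ) from None
    return loader(path)


def validate_database(db: MetabolicDatabase) -> ValidationReport:
    """Collect every dangling cross-reference in *db*.

    Absent references (e.g. a gene with an empty enzyme list) are fine;
    only references to ids that do not exist are violations.
    """
    report = ValidationReport()

    def check(kind: str, eid: str, fieldname: str, refs: Iterable[str], pool: Mapping) -> None:
        for ref in refs:
            if ref not in pool:
                report.violations.append(Violation(kind, eid, fieldname, ref))

    for r in db.reactions.values():
        check("reaction", r.id, "substrate_ids", r.substrate_ids, db.compounds)
        check("reaction", r.id, "product_ids", r.product_ids, db.compounds)
        check("reaction", r.id, "enzyme_ids", r.enzyme_ids, db.enzymes)
        check("reaction", r.id, "pathway_ids", r.pathway_ids, db.pathways)
    for e in db.enzymes.values():
        check("enzyme", e.id, "gene_ids", e.gene_ids, db.genes)
        check("enzyme", e.id, "reaction_ids", e.reaction_ids, db.reactions)
    for g in db.genes.values():
        check("gene", g.id, "enzyme_ids", g.enzyme_ids, db.enzymes)
    for p in db.pathways.values():
        check("pathway", p.id, "compound_ids", p.compound_ids, db.compounds)
        check("pathway", p.id, "reaction_ids", p.reaction_ids, db.reactions)
    return report


_CLASS_ORDER = ("compound", "gene", "enzyme", "reaction", "pathway")
_KIND_ORDER = ("id", "name", "synonym", "xref")


def _class_candidates(db: MetabolicDatabase, cls: str, query: str) -> tuple[Match, ...] | None:
    """Best-rank matches of *query* within one entity class, or None."""
    q = query.casefold()
    pools: dict[str, Mapping[str, object]] = {
        "compound": db.compounds,
        "reaction": db.reactions,
        "enzyme": db.enzymes,
        "gene": db.genes,
        "pathway": db.pathways,
    }
    pool = pools[cls]

    by_kind: dict[str, list[str]] = {k: [] for k in _KIND_ORDER}
    for eid, ent in pool.items():
        if eid == query:
            by_kind["id"].append(eid)
        name = getattr(ent, "name", "") or getattr(ent, "symbol", "")
        if name and name.casefold() == q:
            by_kind["name"].append(eid)
        for syn in getattr(ent, "synonyms", ()):
            if syn.casefold() == q:
                by_kind["synonym"].append(eid)
                break
        for val in getattr(ent, "xrefs", {}).values():
            if val == query:
                by_kind["xref"].append(eid)
                break
    for kind in _KIND_ORDER:
        hits = sorted(set(by_kind[kind]))
        if hits:
            return tuple(Match(cls, eid, kind) for eid in hits)
    return None


def resolve_identifiers(
    db: MetabolicDatabase, queries: Iterable[str]
) -> ResolutionReport:
    """Resolve free-text *queries* against all entity classes.

    Matching priority within a class: exact id > exact name
    (case-insensitive) > synonym > xref value.  A query may match at most
    one entity per class; if several entities tie at the best rank the
    query is reported as ambiguous for that class instead of being
    silently assigned.  Deterministic and idempotent for a fixed database.
    """
    queries = list(queries)
    if not queries:
        raise ValueError("queries must be non-empty")
    report = ResolutionReport()
    for query in queries:
        if not query:
            report.unmatched.append(query)
            continue
        resolved: list[Match] = []
        ambiguous: list[Match] = []
        for cls in _CLASS_ORDER:
            hits = _class_candidates(db, cls, query)
            if hits is None:
                continue
            if len(hits) == 1:
                resolved.append(hits[0])
            else:
                ambiguous.extend(hits)
        if resolved:
            report.matches[query] = tuple(resolved)
        if ambiguous:
            report.ambiguous[query] = tuple(ambiguous)
        if not resolved and not ambiguous:
            report.unmatched.append(query)
    return report
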