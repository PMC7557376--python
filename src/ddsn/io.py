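"""Reading and writing interaction tables, annotations, and DDSN graphs.

The on-disk formats are deliberately plain: tab-separated interaction and
annotation tables (``#`` comment lines ignored) and three interoperable
graph formats (GEXF 1.2, GraphML, 3-column weighted edge list) so results
can round-trip through Gephi and other network tools.
"""

from __future__ import annotations

import csv
import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class Action(enum.Enum):
    """Binary drug-target action typing used by the similarity projection."""

    AGONIST = "agonist"
    ANTAGONIST = "antagonist"
    UNKNOWN = "unknown"


class Evidence(enum.Enum):
    """Provenance of a drug-property annotation."""

    DATABASE = "database"
    LITERATURE = "literature"
    NONE = "none"


#: Default normalization of free-text action vocabularies onto the binary
#: agonist/antagonist typing.  Real drug-target databases use a much richer
#: vocabulary ("inhibitor", "blocker", "inducer", ...); anything unmapped is
#: UNKNOWN and, by default, excluded from similarity counting.  Override via
#: the ``mapping`` argument of :func:`normalize_action`.
DEFAULT_ACTION_MAP: dict[str, Action] = {
    "agonist": Action.AGONIST,
    "activator": Action.AGONIST,
    "inducer": Action.AGONIST,
    "potentiator": Action.AGONIST,
    "partial agonist": Action.AGONIST,
    "stimulator": Action.AGONIST,
    "antagonist": Action.ANTAGONIST,
    "inhibitor": Action.ANTAGONIST,
    "blocker": Action.ANTAGONIST,
    "negative modulator": Action.ANTAGONIST,
    "suppressor": Action.ANTAGONIST,
}


def normalize_action(raw: str, mapping: Mapping[str, Action] | None = None) -> Action:
    """Map a raw action string to AGONIST/ANTAGONIST/UNKNOWN.

    Case-insensitive, whitespace-trimmed lookup; total (never raises) and
    idempotent on the names of its own outputs.
    """
    if mapping is None:
        mapping = DEFAULT_ACTION_MAP
    key = raw.strip().lower()
    if key in (a.value for a in Action):
        return Action(key)
    return mapping.get(key, Action.UNKNOWN)


@dataclass(frozen=True)
class InteractionRecord:
    """One typed drug-target interaction."""

    drug_id: str
    target_id: str
    action: Action
    drug_name: str = ""
    target_name: str = ""

    def __post_init__(self) -> None:
        if not self.drug_id or not self.target_id:
            raise ValueError("drug_id and target_id must be nonempty")


@dataclass
class InteractionTable:
    """A deduplicated set of typed drug-target interactions."""

    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def drugs(self) -> set[str]:
        return {r.drug_id for r in self.records}

    @property
    def targets(self) -> set[str]:
        return {r.target_id for r in self.records}

    @property
    def drug_names(self) -> dict[str, str]:
        return {r.drug_id: r.drug_name for r in self.records if r.drug_name}

    def typed_records(self) -> list[InteractionRecord]:
        """Records with a known (agonist/antagonist) action type."""
        return [r for r in self.records if r.action is not Action.UNKNOWN]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AnnotationTable:
    """drug_id -> property tags, with per-(drug, tag) evidence source.

    A drug absent from the table simply has no known properties.  Evidence
    ranks DATABASE > LITERATURE > NONE when rows disagree.
    """

    tags: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], Evidence] = field(default_factory=dict)

    _RANK = {Evidence.DATABASE: 2, Evidence.LITERATURE: 1, Evidence.NONE: 0}

    def add(self, drug_id: str, tag: str, source: Evidence = Evidence.NONE) -> None:
        tag = tag.strip().lower()
        if not tag:
            raise ValueError("property tags must be nonempty")
        self.tags.setdefault(drug_id, set()).add(tag)
        key = (drug_id, tag)
        old = self.evidence.get(key, Evidence.NONE)
        if self._RANK[source] > self._RANK[old]:
            self.evidence[key] = source
        else:
            self.evidence.setdefault(key, old)

    def tags_of(self, drug_id: str) -> set[str]:
        return self.tags.get(drug_id, set())

    def evidence_of(self, drug_id: str, tag: str) -> Evidence:
        return self.evidence.get((drug_id, tag.strip().lower()), Evidence.NONE)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _open_rows(path: str | Path, delimiter: str = "\t") -> Iterable[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            yield row


def read_interaction_table(
    path: str | Path,
    delimiter: str = "\t",
    mapping: Mapping[str, Action] | None = None,
) -> InteractionTable:
    """Read a typed interaction TSV (drug_id, target_id, action, names optional).

    Duplicate (drug, target) rows are deduplicated; duplicates that disagree
    on a non-UNKNOWN action are dropped entirely with a warning rather than
    arbitrated silently.
    """
    rows = iter(_open_rows(path, delimiter))
    try:
        header = [h.strip().lower() for h in next(rows)]
    except StopIteration:
        raise SchemaError(f"{path}: empty file, no header")
    for col in ("drug_id", "target_id", "action"):
        if col not in header:
            raise SchemaError(f"{path}: missing required column '{col}'")
    idx = {name: header.index(name) for name in header}

    def get(row: list[str], col: str) -> str:
        i = idx.get(col)
        return row[i].strip() if i is not None and i < len(row) else ""

    seen: dict[tuple[str, str], InteractionRecord] = {}
    conflicted: set[tuple[str, str]] = set()
    for row in rows:
        rec = InteractionRecord(
            drug_id=get(row, "drug_id"),
            target_id=get(row, "target_id"),
            action=normalize_action(get(row, "action"), mapping),
            drug_name=get(row, "drug_name"),
            target_name=get(row, "target_name"),
        )
        key = (rec.drug_id, rec.target_id)
        prev = seen.get(key)
        if prev is None:
            seen[key] = rec
        elif prev.action is rec.action:
            continue
        elif prev.action is Action.UNKNOWN:
            seen[key] = rec  # a typed row outranks an untyped duplicate
        elif rec.action is Action.UNKNOWN:
            continue
        else:
            conflicted.add(key)
    if conflicted:
        warnings.warn(
            f"{len(conflicted)} (drug, target) pairs had conflicting typed "
            f"actions and were dropped: {sorted(conflicted)[:5]}...",
            stacklevel=2,
        )
        for key in conflicted:
            seen.pop(key, None)
    return InteractionTable(records=list(seen.values()))


def read_annotations(path: str | Path, delimiter: str = "\t") -> AnnotationTable:
    """Read a drug-property annotation TSV: drug_id, properties (';'-joined), source.

    Unknown source strings map to NONE; repeated rows for one drug union
    their tags.
    """
    rows = iter(_open_rows(path, delimiter))
    try:
        header = [h.strip().lower() for h in next(rows)]
    except StopIteration:
        raise SchemaError(f"{path}: empty file, no header")
    if "drug_id" not in header:
        raise SchemaError(f"{path}: missing required column 'drug_id'")
    i_drug = header.index("drug_id")
    i_props = header.index("properties") if "properties" in header else 1
    i_src = header.index("source") if "source" in header else None

    table = AnnotationTable()
    for row in rows:
        drug = row[i_drug].strip()
        props = row[i_props].strip() if i_props < len(row) else ""
        raw_src = row[i_src].strip().lower() if i_src is not None and i_src < len(row) else ""
        try:
            source = Evidence(raw_src)
        except ValueError:
            source = Evidence.NONE
        for tag in filter(None, (t.strip() for t in props.split(";"))):
            table.add(drug, tag, source)
    return table


GRAPH_FORMATS = ("gexf", "graphml", "edgelist")


def write_graph(graph: nx.Graph, path: str | Path, format: str = "gexf") -> None:
    """Write a weighted DDSN graph as GEXF, GraphML, or a weighted edge list.

    Edge weights are preserved as integers; node attributes (community,
    centralities, layout coordinates) travel along in GEXF/GraphML.  The
    edge-list writer emits isolated nodes as single-token lines so that the
    weighted adjacency (and node set) round-trips losslessly in all formats.
    """
    path = Path(path)
    if format == "gexf":
        nx.write_gexf(graph, path)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# u\tv\tweight\n")
            for u, v, w in sorted(
                graph.edges(data="weight", default=1), key=lambda e: (str(e[0]), str(e[1]))
            ):
                fh.write(f"{u}\t{v}\t{int(w)}\n")
            for node in sorted((n for n in graph if graph.degree(n) == 0), key=str):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unsupported graph format {format!r}; use one of {GRAPH_FORMATS}")


def read_graph(path: str | Path, format: str = "gexf") -> nx.Graph:
    """Read a graph written by :func:`write_graph`; weights restored as int."""
    path = Path(path)
    if format == "gexf":
        g = nx.Graph(nx.read_gexf(path))
    elif format == "graphml":
        g = nx.Graph(nx.read_graphml(path))
    elif format == "edgelist":
        g = nx.Graph()
        for row in _open_rows(path, "\t"):
            if len(row) == 1:
                g.add_node(row[0])
            else:
                g.add_edge(row[0], row[1], weight=int(row[2]))
        return g
    else:
        raise ValueError(f"unsupported graph format {format!r}; use one of {GRAPH_FORMATS}")
    for u, v, data in g.edges(data=True):
        if "weight" in data:
            data["weight"] = int(data["weight"])
    return g
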