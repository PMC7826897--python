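"""Bipartite fish-welfare ontology: needs, parameters, correlation triples.

The ontology links *needs* — fundamental requirements a fish must have met
to experience good welfare (respiration, nutrition, safety, ...) — to
*parameters*, the quantifiable aspects by which those needs can be
assessed. Each link is a triple ``(need, parameter, relation)`` with a
relation of ``affects``, ``affected_by`` or ``both``. Links exist only
between needs and parameters (never need-need or parameter-parameter), so
the graph is bipartite by construction.

Parameters enter the scoring model only if they satisfy three selection
criteria: *relevant* (documented correlation with welfare), *practicable*
(measurable on-farm at reasonable cost) and *reliable* (methods give
consistent results). :func:`select_parameters` implements that filter.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Need",
    "OntologyParameter",
    "Triple",
    "OntologyGraph",
    "OntologyError",
    "load_ontology",
    "default_ontology",
    "degree",
    "select_parameters",
    "export_graph",
    "import_graph",
    "RELATIONS",
]

RELATIONS = ("affects", "affected_by", "both")


class OntologyError(ValueError):
    """The triple file violates referential or structural integrity."""


class Need(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    name: str
    description: str = ""


class OntologyParameter(BaseModel):
    """A candidate welfare parameter with its three selection criteria."""

    model_config = ConfigDict(extra="forbid")
    id: str
    name: str
    relevant: bool
    practicable: bool
    reliable: bool
    module_id: Optional[str] = None

    @model_validator(mode="after")
    def _selected_implies_criteria(self):
        if self.module_id is not None and not (
            self.relevant and self.practicable and self.reliable
        ):
            raise ValueError(
                f"parameter '{self.id}' is selected into module "
                f"'{self.module_id}' but fails a selection criterion"
            )
        return self


class Triple(BaseModel):
    model_config = ConfigDict(extra="forbid")
    need_id: str
    parameter_id: str
    relation: str

    @model_validator(mode="after")
    def _relation_known(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation '{self.relation}'")
        return self


class OntologyGraph(BaseModel):
    model_config = ConfigDict(extra="forbid")
    provenance: str = ""
    needs: list[Need]
    parameters: list[OntologyParameter]
    triples: list[Triple]

    @model_validator(mode="after")
    def _integrity(self):
        need_ids = {n.id for n in self.needs}
        if len(need_ids) != len(self.needs):
            raise ValueError("duplicate need ids")
        param_ids = {p.id for p in self.parameters}
        if len(param_ids) != len(self.parameters):
            raise ValueError("duplicate parameter ids")
        if need_ids & param_ids:
            raise ValueError(f"ids used as both need and parameter: {need_ids & param_ids}")
        seen = set()
        for t in self.triples:
            if t.need_id not in need_ids:
                raise ValueError(f"triple references undefined need '{t.need_id}'")
            if t.parameter_id not in param_ids:
                raise ValueError(
                    f"triple references undefined parameter '{t.parameter_id}'"
                )
            key = (t.need_id, t.parameter_id)
            if key in seen:
                raise ValueError(f"duplicate triple for {key}")
            seen.add(key)
        return self

    def need(self, need_id: str) -> Need:
        for n in self.needs:
            if n.id == need_id:
                return n
        raise KeyError(f"unknown need '{need_id}'")


def _looks_like_path(s: str) -> bool:
    if "\n" in s or len(s) > 1024:
        return False
    try:
        return Path(s).exists()
    except OSError:
        return False


def load_ontology(source: Union[str, Path]) -> OntologyGraph:
    """Load and validate a flat JSON triple file (needs[], parameters[], triples[])."""
    if isinstance(source, Path) or (
        isinstance(source, str) and _looks_like_path(source)
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise OntologyError(f"could not parse ontology JSON: {exc}") from exc
    try:
        return OntologyGraph.model_validate(data)
    except Exception as exc:
        raise OntologyError(str(exc)) from exc


def default_ontology() -> OntologyGraph:
    """The packaged ontology: 14 needs, the 80 model parameters plus the
    excluded VSI/hematocrit examples, and a reconstructed two-need excerpt
    of the correlation network."""
    ref = resources.files("fishwelfare.data").joinpath("ontology.json")
    return load_ontology(ref.read_text(encoding="utf-8"))


def degree(graph: OntologyGraph, node_id: str) -> int:
    """Number of triples touching a need or parameter node."""
    known = {n.id for n in graph.needs} | {p.id for p in graph.parameters}
    if node_id not in known:
        raise KeyError(f"unknown node '{node_id}'")
    return sum(1 for t in graph.triples if node_id in (t.need_id, t.parameter_id))


def select_parameters(
    graph: OntologyGraph,
    relevant: bool = False,
    practicable: bool = False,
    reliable: bool = False,
) -> list[OntologyParameter]:
    """Parameters satisfying every *required* criterion, ordered by id.

    A flag set to True requires that criterion; False imposes nothing, so
    ``select_parameters(g)`` returns all parameters.
    """
    out = [
        p
        for p in graph.parameters
        if (p.relevant or not relevant)
        and (p.practicable or not practicable)
        and (p.reliable or not reliable)
    ]
    return sorted(out, key=lambda p: p.id)


def to_networkx(graph: OntologyGraph) -> "nx.Graph":
    """Undirected bipartite view with typed nodes and relation-labelled edges."""
    g = nx.Graph()
    for n in graph.needs:
        g.add_node(n.id, type="need", name=n.name)
    for p in graph.parameters:
        g.add_node(
            p.id,
            type="parameter",
            name=p.name,
            module=p.module_id or "",
            relevant=p.relevant,
            practicable=p.practicable,
            reliable=p.reliable,
        )
    for t in graph.triples:
        g.add_edge(t.need_id, t.parameter_id, relation=t.relation)
    return g


def export_graph(graph: OntologyGraph, fmt: str = "graphml") -> str:
    """Serialize for graph viewers; ``graphml`` or ``json`` (the triple schema)."""
    if fmt == "json":
        return graph.model_dump_json(indent=1)
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(to_networkx(graph)))
    raise ValueError(f"unsupported export format '{fmt}'")


def import_graph(text: str, fmt: str = "graphml") -> OntologyGraph:
    """Inverse of :func:`export_graph`; reconstructs the validated triple model."""
    if fmt == "json":
        return load_ontology(text)
    if fmt != "graphml":
        raise ValueError(f"unsupported import format '{fmt}'")
    g = nx.parse_graphml(text)
    needs, params, triples = [], [], []
    for node, attrs in sorted(g.nodes(data=True)):
        if attrs.get("type") == "need":
            needs.append(Need(id=node, name=attrs.get("name", node)))
        else:
            params.append(
                OntologyParameter(
                    id=node,
                    name=attrs.get("name", node),
                    relevant=bool(attrs.get("relevant", False)),
                    practicable=bool(attrs.get("practicable", False)),
                    reliable=bool(attrs.get("reliable", False)),
                    module_id=attrs.get("module") or None,
                )
            )
    need_ids = {n.id for n in needs}
    for u, v, attrs in sorted(g.edges(data=True)):
        nid, pid = (u, v) if u in need_ids else (v, u)
        triples.append(Triple(need_id=nid, parameter_id=pid, relation=attrs["relation"]))
    return OntologyGraph(needs=needs, parameters=params, triples=triples)
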