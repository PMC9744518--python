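"""HPO ontology loading and phenotypic search-space expansion.

The Human Phenotype Ontology is a DAG of phenotype terms (``HP:NNNNNNN``)
related by ``is_a`` edges. Given one or more seed terms describing a patient,
the search space can be widened either towards descendants only (*children*
mode: more specific phenotypes subsumed by the seeds) or along the undirected
``is_a`` graph (*distance* mode: any neighboring term within a maximum
traversal distance). Only ``is_a`` edges participate in traversal; obsolete
terms are kept for bookkeeping but never traversed, and obsolete seed terms
are resolved once through ``replaced_by``.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import obonet

from .errors import RuntimeFailure, UsageError

HPO_ID_RE = re.compile(r"^HP:\d{7}$")

#: IRI prefix used for HP classes in OWL-RDF renderings of the ontology.
HP_IRI_PREFIX = "http://purl.obolibrary.org/obo/HP_"


def _iri_to_id(iri: str) -> str | None:
    if iri.startswith(HP_IRI_PREFIX):
        tail = iri[len(HP_IRI_PREFIX):]
        if tail.isdigit() and len(tail) == 7:
            return f"HP:{tail}"
    return None


@dataclass(frozen=True)
class HpoTerm:
    """A single ontology node.

    Parameters
    ----------
    id : str
        HPO identifier, ``HP:`` followed by seven digits.
    name : str
        Human-readable label.
    parents : frozenset of str
        Identifiers of direct ``is_a`` parents. Empty for roots and for
        obsolete terms (obsolete terms never participate in traversal).
    obsolete : bool
        Whether the term is deprecated.
    replaced_by : str or None
        Replacement term for an obsolete term, when the ontology names one.
    """

    id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False
    replaced_by: str | None = None


class Ontology:
    """An ``is_a`` DAG over :class:`HpoTerm` nodes with traversal indexes."""

    def __init__(self, terms: Iterable[HpoTerm]):
        self.terms: dict[str, HpoTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise RuntimeFailure(f"duplicate ontology term id {t.id}")
            self.terms[t.id] = t
        self._children: dict[str, set[str]] = {tid: set() for tid in self.terms}
        self._parents: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for t in self.terms.values():
            if t.obsolete:
                continue
            for p in t.parents:
                if p not in self.terms:
                    raise RuntimeFailure(
                        f"term {t.id} has is_a parent {p} not present in the ontology"
                    )
                self._parents[t.id].add(p)
                self._children[p].add(t.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self._parents.items():
            g.add_edges_from((child, p) for p in parents)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise RuntimeFailure(f"is_a relation is cyclic: {path}")

    @property
    def edges(self) -> set[tuple[str, str]]:
        """The ``is_a`` relation as (child, parent) pairs."""
        return {
            (child, p) for child, parents in self._parents.items() for p in parents
        }

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def children_of(self, term_id: str) -> set[str]:
        return set(self._children[term_id])

    def parents_of(self, term_id: str) -> set[str]:
        return set(self._parents[term_id])

    def neighbors_of(self, term_id: str) -> set[str]:
        return self._children[term_id] | self._parents[term_id]


def load_ontology(path, format: Literal["obo", "owl"] = "obo") -> Ontology:
    """Parse an HPO ontology file.

    Parameters
    ----------
    path : path-like
        OBO 1.4 flat file, or an OWL-RDF file (Turtle / RDF-XML) whose HP
        classes use ``http://purl.obolibrary.org/obo/HP_NNNNNNN`` IRIs.
    format : {"obo", "owl"}
        ``obo`` is the canonical format; ``owl`` is a best-effort convenience
        reading ``rdfs:subClassOf`` between named HP classes.

    Returns
    -------
    Ontology
        Every term with its ``is_a`` edges; obsolete terms retained with
        ``obsolete=True`` and excluded from traversal.
    """
    if format == "obo":
        return _load_obo(path)
    if format == "owl":
        return _load_owl(path)
    raise UsageError(f"unknown ontology format {format!r} (expected 'obo' or 'owl')")


def _load_obo(path) -> Ontology:
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except FileNotFoundError:
        raise RuntimeFailure(f"ontology file not found: {path}")
    except Exception as exc:  # obonet raises ValueError with stanza context
        raise RuntimeFailure(f"cannot parse OBO file {path}: {exc}")
    terms = []
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        replaced = data.get("replaced_by")
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms.append(
            HpoTerm(
                id=node,
                name=data.get("name", ""),
                parents=parents,
                obsolete=obsolete,
                replaced_by=replaced[0] if replaced else None,
            )
        )
    return Ontology(terms)


def _load_owl(path) -> Ontology:
    import rdflib
    from rdflib.namespace import OWL, RDFS

    g = rdflib.Graph()
    fmt = "xml" if str(path).endswith((".owl", ".xml", ".rdf")) else None
    try:
        g.parse(str(path), format=fmt)
    except FileNotFoundError:
        raise RuntimeFailure(f"ontology file not found: {path}")
    except Exception as exc:
        raise RuntimeFailure(f"cannot parse OWL file {path}: {exc}")

    replaced_by_pred = rdflib.URIRef("http://purl.obolibrary.org/obo/IAO_0100001")
    names: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    obsolete: set[str] = set()
    replaced: dict[str, str] = {}

    for s in set(g.subjects()):
        if not isinstance(s, rdflib.URIRef):
            continue
        tid = _iri_to_id(str(s))
        if tid is None:
            continue
        parents.setdefault(tid, set())
        for label in g.objects(s, RDFS.label):
            names[tid] = str(label)
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, rdflib.URIRef):
                pid = _iri_to_id(str(o))
                if pid is not None:
                    parents[tid].add(pid)
        for o in g.objects(s, OWL.deprecated):
            if str(o).lower() == "true":
                obsolete.add(tid)
        for o in g.objects(s, replaced_by_pred):
            rid = _iri_to_id(str(o)) or (str(o) if HPO_ID_RE.match(str(o)) else None)
            if rid:
                replaced[tid] = rid

    terms = [
        HpoTerm(
            id=tid,
            name=names.get(tid, ""),
            parents=frozenset() if tid in obsolete else frozenset(parents[tid]),
            obsolete=tid in obsolete,
            replaced_by=replaced.get(tid),
        )
        for tid in parents
    ]
    if not terms:
        raise RuntimeFailure(f"no HP classes found in OWL file {path}")
    return Ontology(terms)


def _resolve_seeds(ontology: Ontology, seeds: Iterable[str]) -> set[str]:
    unknown, dead = [], []
    resolved: set[str] = set()
    for s in sorted(set(seeds)):
        if s not in ontology:
            unknown.append(s)
            continue
        term = ontology.terms[s]
        if term.obsolete:
            # one-step replaced_by resolution only; chains are treated as dead
            rep = term.replaced_by
            if rep and rep in ontology and not ontology.terms[rep].obsolete:
                resolved.add(rep)
            else:
                dead.append(s)
        else:
            resolved.add(s)
    if unknown:
        raise UsageError(f"unknown HPO term(s): {', '.join(unknown)}")
    if dead:
        raise UsageError(
            "obsolete HPO term(s) without a usable replacement: " + ", ".join(dead)
        )
    return resolved


def expand_terms(
    ontology: Ontology,
    seeds: Iterable[str],
    mode: Literal["children", "distance"] = "children",
    max_distance: int = 0,
) -> set[str]:
    """Widen a set of seed HPO terms by ontology traversal.

    ``children`` mode adds every descendant reachable in at most
    ``max_distance`` child-direction steps; ``distance`` mode adds every term
    whose undirected shortest-path distance over ``is_a`` edges is at most
    ``max_distance``. In both modes the (resolved) seeds themselves are always
    part of the result, so the result is monotone in ``max_distance`` and
    ``max_distance=0`` returns exactly the seeds. Obsolete terms carry no
    traversal edges and therefore never appear.
    """
    if max_distance < 0:
        raise UsageError("max_distance must be >= 0")
    if mode not in ("children", "distance"):
        raise UsageError(f"unknown traversal mode {mode!r}")
    resolved = _resolve_seeds(ontology, seeds)

    step = ontology.children_of if mode == "children" else ontology.neighbors_of
    result = set(resolved)
    frontier = deque((s, 0) for s in sorted(resolved))
    while frontier:
        node, dist = frontier.popleft()
        if dist == max_distance:
            continue
        for nxt in step(node):
            if nxt not in result:
                result.add(nxt)
                frontier.append((nxt, dist + 1))
    return result
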