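"""Rooted DAG representation of an HPO-style ontology.

The ontology is a directed acyclic graph of terms connected by ``is_a``
edges only; a term may have several parents (e.g. *Cleft palate* sits under
both *Abnormal hard palate morphology* and *Oral cleft*).  Obsolete terms
are retained but excluded from the graph; inputs naming an obsolete term
are remapped through ``replaced_by``, and secondary (``alt_id``)
identifiers are remapped to their primary id with a warning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .errors import OntologyError

logger = logging.getLogger(__name__)

#: pattern every term identifier must match (prefix, colon, digits)
TERM_ID_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*:\d+$")


class TermId(str):
    """A validated term identifier such as ``"HP:0011297"``.

    Behaves as a plain string; ordering is lexicographic on the full id.
    Prefixes other than ``HP`` are accepted so synthetic ontologies can use
    their own namespace.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "TermId":
        if not TERM_ID_PATTERN.match(value):
            raise OntologyError(f"malformed term id: {value!r}")
        return super().__new__(cls, value)


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: primary id, label, ``is_a`` parents, alt ids."""

    id: str
    label: str = ""
    parents: frozenset = frozenset()
    alt_ids: frozenset = frozenset()
    obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        TermId(self.id)
        for p in self.parents:
            TermId(p)
        if self.obsolete and self.parents:
            raise OntologyError(
                f"obsolete term {self.id} must not have is_a parents"
            )


class Ontology:
    """A rooted DAG of terms answering ancestor-closure queries.

    Parameters
    ----------
    terms
        Iterable of :class:`OntologyTerm` (obsolete terms allowed).
    root
        Root term id; inferred as the unique parentless non-obsolete term
        when omitted.
    phenotypic_root
        Optional id of the phenotype subtree root (``HP:0000118`` in the
        real HPO).  When set, count reports are restricted to this subtree.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        root: str | None = None,
        phenotypic_root: str | None = None,
    ) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.id in self.terms:
                raise OntologyError(f"duplicate term id: {term.id}")
            self.terms[term.id] = term

        # alt ids must be disjoint across terms and from primary ids
        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.terms or alt in self._alt:
                    raise OntologyError(f"alt_id {alt} is not unique")
                self._alt[alt] = term.id

        self.graph = nx.DiGraph()  # edges point child -> parent
        for term in self.terms.values():
            if term.obsolete:
                continue
            self.graph.add_node(term.id)
            for parent in term.parents:
                target = self.terms.get(parent)
                if target is None:
                    raise OntologyError(
                        f"term {term.id} has dangling is_a target {parent}"
                    )
                if target.obsolete:
                    raise OntologyError(
                        f"term {term.id} has obsolete is_a target {parent}"
                    )
                self.graph.add_edge(term.id, parent)

        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise OntologyError(
                f"ontology contains a cycle through term {cycle[0][0]}"
            )

        parentless = sorted(
            n for n in self.graph.nodes if self.graph.out_degree(n) == 0
        )
        if root is not None:
            if root not in self.terms:
                raise OntologyError(f"declared root {root} not in ontology")
            extra = [n for n in parentless if n != root]
            if extra:
                raise OntologyError(
                    f"terms unreachable from declared root {root}: {extra}"
                )
            self.root = root
        else:
            if len(parentless) != 1:
                raise OntologyError(
                    "root is not unique; parentless terms: "
                    f"{parentless} (pass root= to disambiguate)"
                )
            self.root = parentless[0]

        if phenotypic_root is not None and phenotypic_root not in self.terms:
            raise OntologyError(
                f"phenotypic root {phenotypic_root} not in ontology"
            )
        self.phenotypic_root = phenotypic_root
        if phenotypic_root is not None:
            # descendants in the child->parent graph are graph-ancestors,
            # so subtree membership needs the reversed direction
            self._subtree = set(
                nx.ancestors(self.graph, phenotypic_root)
            ) | {phenotypic_root}
        else:
            self._subtree = None

        #: (given id, primary id) pairs recorded whenever an alt or
        #: obsolete id was silently remapped
        self.remap_log: list[tuple[str, str]] = []

    # -- id resolution ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return sum(1 for t in self.terms.values() if not t.obsolete)

    def label(self, term_id: str) -> str:
        return self.terms[self.primary_id(term_id)].label

    def primary_id(self, term_id: str) -> str:
        """Resolve *term_id* to a primary, non-obsolete id.

        Alt ids and obsolete ids with a ``replaced_by`` target are remapped
        with a warning (recorded in :attr:`remap_log`); anything else is an
        error naming the id.
        """
        seen: set[str] = set()
        current = term_id
        while True:
            if current in seen:
                raise OntologyError(f"replaced_by loop at term {current}")
            seen.add(current)
            if current in self._alt:
                current = self._alt[current]
                continue
            term = self.terms.get(current)
            if term is None:
                raise OntologyError(f"unknown term id: {current}")
            if term.obsolete:
                if term.replaced_by is None:
                    raise OntologyError(
                        f"term {current} is obsolete with no replacement"
                    )
                current = term.replaced_by
                continue
            if current != term_id:
                logger.warning("remapped %s -> %s", term_id, current)
                self.remap_log.append((term_id, current))
            return current

    # -- queries ---------------------------------------------------------

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(self.primary_id(term_id)))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(self.primary_id(term_id)))

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive ``is_a`` closure of *term_id*, capped at the root.

        Terms reachable along several paths (the DAG case) appear once.
        """
        primary = self.primary_id(term_id)
        closed = set(nx.descendants(self.graph, primary))
        if include_self:
            closed.add(primary)
        return closed

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        primary = self.primary_id(term_id)
        closed = set(nx.ancestors(self.graph, primary))
        if include_self:
            closed.add(primary)
        return closed

    def leaves(self) -> set[str]:
        """Terms without children (restricted to the phenotypic subtree
        when one is set)."""
        leaves = {
            n for n in self.graph.nodes if self.graph.in_degree(n) == 0
        }
        if self._subtree is not None:
            leaves &= self._subtree
        return leaves

    def in_reporting_subtree(self, term_id: str) -> bool:
        """Whether counts at this term belong in reports (the phenotypic
        subtree when a phenotypic root is set, everything otherwise)."""
        if self._subtree is None:
            return True
        return term_id in self._subtree

    def edges(self) -> Iterable[tuple[str, str]]:
        """All (child, parent) pairs of the non-obsolete graph."""
        return self.graph.edges()


def ancestors(ontology: Ontology, term_id: str, include_self: bool = False) -> set[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id, include_self=include_self)


def _scan_stanza_ids(text: str) -> list[str]:
    """Primary ids of every [Term] stanza, in file order."""
    ids = []
    in_term = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
        elif in_term and stripped.startswith("id:"):
            ids.append(stripped[3:].split("!")[0].strip())
            in_term = False  # only the first id tag per stanza
    return ids


def parse_obo(
    source: str | Path | IO[str],
    root: str | None = None,
    phenotypic_root: str | None = "HP:0000118",
) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Only ``is_a`` relations become edges; every other relationship tag is
    ignored.  Obsolete terms are retained with ``obsolete=True`` and kept
    out of closure queries.  ``phenotypic_root`` defaults to the HPO
    *Phenotypic abnormality* id and is silently dropped when the file does
    not contain it.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()

    stanza_ids = _scan_stanza_ids(text)
    seen: set[str] = set()
    for sid in stanza_ids:
        if sid in seen:
            raise OntologyError(f"duplicate term id: {sid}")
        seen.add(sid)

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms = []
    for node in stanza_ids:
        data: Mapping = graph.nodes[node]
        is_a = data.get("is_a", [])
        for parent in is_a:
            if parent not in seen:
                raise OntologyError(
                    f"term {node} has dangling is_a target {parent}"
                )
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        replaced = data.get("replaced_by", [None])
        terms.append(
            OntologyTerm(
                id=node,
                label=data.get("name", ""),
                parents=frozenset() if obsolete else frozenset(is_a),
                alt_ids=frozenset(data.get("alt_id", [])),
                obsolete=obsolete,
                replaced_by=replaced[0] if replaced else None,
            )
        )

    if phenotypic_root is not None and phenotypic_root not in seen:
        phenotypic_root = None
    return Ontology(terms, root=root, phenotypic_root=phenotypic_root)


def write_obo(ontology: Ontology, sink: str | Path | IO[str]) -> None:
    """Serialize an ontology back to OBO text (id/name/alt_id/is_a tags)."""
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: phenodiff/export\n")
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        out.write(f"\n[Term]\nid: {term.id}\n")
        if term.label:
            out.write(f"name: {term.label}\n")
        for alt in sorted(term.alt_ids):
            out.write(f"alt_id: {alt}\n")
        for parent in sorted(term.parents):
            out.write(f"is_a: {parent} ! {ontology.terms[parent].label}\n")
        if term.obsolete:
            out.write("is_obsolete: true\n")
            if term.replaced_by:
                out.write(f"replaced_by: {term.replaced_by}\n")
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(out.getvalue(), encoding="utf-8")
    else:
        sink.write(out.getvalue())
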