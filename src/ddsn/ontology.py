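"""Phenotype-ontology backbone: OBO parsing, ancestor closures, information
content and most-informative-common-ancestor (MICA) queries.

The ontology is held as a rooted directed acyclic graph over ``is_a`` links,
restricted to the subtree of a chosen root (in production the HPO
"Phenotypic abnormality" subtree, HP:0000118). Term specificity is measured
by a normalized Resnik-style information content

    IC(t) = log(N / n_t) / log(N)

where ``N`` is the number of annotated diseases and ``n_t`` the number of
diseases annotating ``t`` directly or through any descendant (propagated
counts). IC is 0 for a term annotating every disease and 1 for a term
annotating a single disease, and is monotone non-increasing from any term
towards the root.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx
import obonet

from .errors import (
    CycleError,
    ComputationError,
    ConfigurationError,
    OboParseError,
    UnknownTermError,
)

__all__ = [
    "Term",
    "OntologyDAG",
    "ICTable",
    "parse_obo",
    "compute_ic",
    "mica",
]


@dataclass(frozen=True)
class Term:
    """A single ontology term with its direct ``is_a`` parents."""

    id: str
    name: str = ""
    parents: FrozenSet[str] = frozenset()


class OntologyDAG:
    """Rooted DAG of ontology terms with cached ancestor closures.

    Parameters
    ----------
    terms:
        Mapping term id -> :class:`Term`. Parent references must stay inside
        the mapping; the root must have no parents.
    root:
        Identifier of the root term.
    """

    def __init__(self, terms: Mapping[str, Term], root: str):
        if root not in terms:
            raise UnknownTermError(f"root term {root!r} not among terms")
        for t in terms.values():
            for p in t.parents:
                if p not in terms:
                    raise UnknownTermError(
                        f"term {t.id!r} has parent {p!r} outside the ontology"
                    )
        if terms[root].parents:
            raise ConfigurationError(f"root {root!r} must not have parents")
        self.terms: Dict[str, Term] = dict(terms)
        self.root = root
        self._closures: Dict[str, FrozenSet[str]] = {}
        self._children: Optional[Dict[str, Set[str]]] = None
        self._check_structure()

    # -- basic queries ----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term_id: str) -> FrozenSet[str]:
        try:
            return self.terms[term_id].parents
        except KeyError:
            raise UnknownTermError(f"unknown term {term_id!r}") from None

    def children(self, term_id: str) -> Set[str]:
        if self._children is None:
            kids: Dict[str, Set[str]] = {t: set() for t in self.terms}
            for t in self.terms.values():
                for p in t.parents:
                    kids[p].add(t.id)
            self._children = kids
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id!r}")
        return self._children[term_id]

    def ancestors(self, term_id: str, include_self: bool = False) -> Set[str]:
        """Transitive closure over parent links (always contains the root)."""
        closure = self._closure(term_id)
        if include_self:
            return set(closure)
        return set(closure) - {term_id}

    def _closure(self, term_id: str) -> FrozenSet[str]:
        """Ancestor closure *including* the term itself, memoized."""
        cached = self._closures.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id!r}")
        out: Set[str] = {term_id}
        for p in self.terms[term_id].parents:
            out |= self._closure(p)
        frozen = frozenset(out)
        self._closures[term_id] = frozen
        return frozen

    def descendants(self, term_id: str, include_self: bool = False) -> Set[str]:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id!r}")
        out: Set[str] = set()
        frontier = [term_id]
        while frontier:
            nxt = frontier.pop()
            for c in self.children(nxt):
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        if include_self:
            out.add(term_id)
        return out

    def depth(self, term_id: str) -> int:
        """Length of the shortest parent path to the root."""
        if term_id == self.root:
            return 0
        return 1 + min(self.depth(p) for p in self.parents(term_id))

    # -- validation -------------------------------------------------------

    def _check_structure(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise CycleError(f"is_a cycle detected: {path}")
        for tid in self.terms:
            if tid != self.root and self.root not in self._closure(tid):
                raise ConfigurationError(
                    f"term {tid!r} does not reach the root {self.root!r}"
                )


@dataclass
class ICTable:
    """Normalized information content per term.

    ``ic`` maps term id -> IC in [0, 1]; terms never reached by any
    annotation (propagated count 0) carry no entry. ``n_diseases`` is the
    number of annotated diseases used for normalization.
    """

    ic: Dict[str, float]
    n_diseases: int

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: Optional[float] = None):
        return self.ic.get(term_id, default)

    def __len__(self) -> int:
        return len(self.ic)

    def to_tsv(self) -> str:
        lines = ["term_id\tic"]
        for t in sorted(self.ic):
            lines.append(f"{t}\t{self.ic[t]:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, n_diseases: int = 0) -> "ICTable":
        ic: Dict[str, float] = {}
        for row in text.splitlines()[1:]:
            if not row.strip():
                continue
            term, value = row.split("\t")
            ic[term] = float(value)
        return cls(ic=ic, n_diseases=n_diseases)


# ---------------------------------------------------------------------------
# OBO parsing

_LINE_RE = re.compile(r"^(\[[A-Za-z_-]+\]|[A-Za-z_][\w-]*\s*:.*|!.*)?\s*$")


def _prescan(obo_text: str) -> None:
    """Reject structurally malformed lines, naming the first offender.

    obonet is forgiving; this enforces the stricter contract that every
    non-blank line is a stanza header, a ``tag: value`` pair or a comment.
    """
    for lineno, line in enumerate(obo_text.splitlines(), start=1):
        if not _LINE_RE.match(line.strip()):
            raise OboParseError(f"malformed OBO line {lineno}: {line!r}")


def parse_obo(obo_text: str, root_id: str) -> OntologyDAG:
    """Parse an OBO document into the DAG induced by ``root_id``.

    Only ``is_a`` relations are honored; obsolete terms and terms outside
    the root's subtree are dropped; the root's own parents (which point
    outside the subtree) are severed.
    """
    _prescan(obo_text)
    try:
        graph = obonet.read_obo(io.StringIO(obo_text))
    except Exception as exc:  # pragma: no cover - obonet's own failures
        raise OboParseError(f"OBO parse failed: {exc}") from exc
    if root_id not in graph:
        raise UnknownTermError(f"root term {root_id!r} not found in the ontology")

    is_a = nx.DiGraph()
    is_a.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            is_a.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(is_a)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
        raise CycleError(f"is_a cycle detected: {path}")

    # nx.ancestors on the child->parent digraph yields ontological descendants
    subtree = {root_id} | nx.ancestors(is_a, root_id)
    terms: Dict[str, Term] = {}
    for tid in subtree:
        parents = (
            frozenset()
            if tid == root_id
            else frozenset(p for p in is_a.successors(tid) if p in subtree)
        )
        terms[tid] = Term(
            id=tid, name=graph.nodes[tid].get("name", ""), parents=parents
        )
    return OntologyDAG(terms, root_id)


# ---------------------------------------------------------------------------
# Information content and MICA


def compute_ic(
    dag: OntologyDAG, annotations: Mapping[str, Iterable[str]]
) -> ICTable:
    """Normalized IC from propagated annotation counts.

    A disease counts towards term ``t`` if ``t`` is in the ancestor closure
    (including self) of any of its annotation terms. Terms never reached
    get no IC entry.
    """
    n = len(annotations)
    if n < 2:
        raise ConfigurationError(
            f"IC normalization needs at least 2 annotated diseases, got {n}"
        )
    counts: Dict[str, int] = {}
    for disease, terms in annotations.items():
        reached: Set[str] = set()
        for t in terms:
            reached |= dag._closure(t)  # raises UnknownTermError if absent
        for t in reached:
            counts[t] = counts.get(t, 0) + 1
    log_n = math.log(n)
    ic = {t: math.log(n / c) / log_n for t, c in counts.items()}
    return ICTable(ic=ic, n_diseases=n)


def mica(
    dag: OntologyDAG, ic: ICTable, t1: str, t2: str
) -> Tuple[str, float]:
    """Most informative common ancestor of two terms and its IC.

    For identical terms the term itself is returned. Ties on IC are broken
    by the lexicographically smallest term identifier.
    """
    for t in (t1, t2):
        if t not in dag:
            raise UnknownTermError(f"unknown term {t!r}")
    if t1 == t2:
        if t1 not in ic:
            raise ComputationError(f"no IC for term {t1!r}")
        return t1, ic[t1]
    common = dag._closure(t1) & dag._closure(t2)
    best_term: Optional[str] = None
    best_ic = -1.0
    for t in common:
        value = ic.get(t)
        if value is None:
            raise ComputationError(f"no IC for candidate ancestor {t!r}")
        if value > best_ic or (value == best_ic and (best_term is None or t < best_term)):
            best_term, best_ic = t, value
    assert best_term is not None  # the root is always common
    return best_term, best_ic
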