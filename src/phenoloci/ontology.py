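"""HPO ontology parsing and annotation propagation.

Patients annotated with Human Phenotype Ontology (HPO) terms implicitly
carry every ancestral (more general) term as well: a patient with
"Low-set ears" also has "Abnormality of the ear".  This module parses the
ontology from OBO text, computes ancestor closures over ``is_a`` edges,
propagates patient term sets up the DAG, and partitions a reported term
set into most-specific terms versus their parental terms (the "+" vs "->"
marking used in per-patient reports).

Only ``is_a`` relations are interpreted; the HPO root ("All") is excluded
from propagated sets because it would connect every patient to every
phenotype and carries no information.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import obonet

logger = logging.getLogger(__name__)

#: Default root term(s) excluded from propagation (the HPO root "All").
DEFAULT_ROOTS = frozenset({"HP:0000001"})


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, dangling parent)."""


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG of phenotype terms.

    Parameters
    ----------
    terms
        Non-obsolete term identifiers.
    names
        Term id -> human-readable label.
    is_a
        Term id -> set of direct parents. Acyclic; every parent is a term.
    obsolete
        Deprecated term id -> replacement id (or None when none given).
    """

    terms: frozenset[str]
    names: Mapping[str, str]
    is_a: Mapping[str, frozenset[str]]
    obsolete: Mapping[str, str | None]
    _anc_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parents."""
        return frozenset(t for t in self.terms if not self.is_a.get(t))

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass(frozen=True)
class TermSet:
    """A patient's direct annotations and their ancestor closure.

    ``propagated`` is ``direct`` plus all ancestors, with the ontology
    root(s) removed.  ``direct <= propagated`` always holds.
    """

    direct: frozenset[str]
    propagated: frozenset[str]


def parse_obo(stream: TextIO | str) -> Ontology:
    """Parse OBO 1.2/1.4 text into an :class:`Ontology`.

    Only ``[Term]`` stanzas and the ``id``, ``name``, ``is_a``,
    ``is_obsolete`` and ``replaced_by`` fields are interpreted; trailing
    ``! name`` comments on is_a lines are stripped.  Obsolete terms are
    recorded (with their replacement when one is given) but excluded from
    the set of live terms.

    Raises
    ------
    OntologyError
        If the is_a graph contains a cycle or references an unknown term.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=False)

    terms: set[str] = set()
    names: dict[str, str] = {}
    is_a: dict[str, frozenset[str]] = {}
    obsolete: dict[str, str | None] = {}

    for node, data in graph.nodes(data=True):
        if not data:
            # referenced as a parent but never declared in a [Term] stanza
            continue
        if data.get("is_obsolete") in ("true", True):
            repl = data.get("replaced_by")
            obsolete[node] = repl[0] if repl else None
            continue
        terms.add(node)
        names[node] = data.get("name", node)
        parents = frozenset(data.get("is_a", []))
        is_a[node] = parents

    for child, parents in is_a.items():
        for p in parents:
            if p not in terms:
                raise OntologyError(
                    f"term {child} has is_a parent {p} not defined in the ontology"
                )

    onto = Ontology(
        terms=frozenset(terms), names=names, is_a=is_a, obsolete=obsolete
    )
    _check_acyclic(onto)
    return onto


def _check_acyclic(onto: Ontology) -> None:
    """Iterative three-color DFS; raises naming one edge of a cycle."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {t: WHITE for t in onto.terms}
    for start in onto.terms:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(onto.is_a.get(start, ())))]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if color[parent] == GRAY:
                    raise OntologyError(
                        f"is_a cycle detected through edge {node} -> {parent}"
                    )
                if color[parent] == WHITE:
                    color[parent] = GRAY
                    stack.append((parent, iter(onto.is_a.get(parent, ()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()


def ancestors(onto: Ontology, term: str) -> frozenset[str]:
    """Transitive is_a closure of ``term``, excluding the term itself.

    Memoized per ontology; deterministic by set semantics.
    """
    if term not in onto.terms:
        raise KeyError(f"unknown term: {term}")
    cache = onto._anc_cache
    if term in cache:
        return cache[term]
    # iterative post-order to fill the memo without recursion limits
    order: list[str] = []
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        order.append(t)
        for p in onto.is_a.get(t, ()):
            if p not in cache and p not in seen:
                stack.append(p)
    for t in reversed(order):
        if t in cache:
            continue
        acc: set[str] = set()
        for p in onto.is_a.get(t, ()):
            acc.add(p)
            acc |= cache.get(p) or ancestors(onto, p)
        cache[t] = frozenset(acc)
    return cache[term]


def propagate(
    onto: Ontology,
    direct: Iterable[str],
    roots: frozenset[str] | None = None,
) -> TermSet:
    """Propagate a patient's direct terms up the ontology.

    Obsolete terms are replaced via ``replaced_by`` when a replacement
    exists, otherwise dropped with a warning.  The ontology root(s) are
    removed from the result.  An empty direct set yields an empty TermSet.
    """
    if roots is None:
        roots = frozenset(DEFAULT_ROOTS) | onto.roots
    resolved: set[str] = set()
    for t in direct:
        if t in onto.terms:
            resolved.add(t)
        elif t in onto.obsolete:
            repl = onto.obsolete[t]
            if repl is not None and repl in onto.terms:
                logger.warning("obsolete term %s replaced by %s", t, repl)
                resolved.add(repl)
            else:
                logger.warning("obsolete term %s has no replacement; dropped", t)
        else:
            raise KeyError(f"unknown term: {t}")
    prop: set[str] = set(resolved)
    for t in resolved:
        prop |= ancestors(onto, t)
    prop -= roots
    return TermSet(direct=frozenset(resolved - roots), propagated=frozenset(prop))


def most_specific(
    onto: Ontology, terms: Iterable[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition ``terms`` into (specific, parental).

    A term is *parental* when some other member of the set descends from
    it; the remainder are the most specific terms.  Reports print "+" for
    specific rows and "->" for parental rows.
    """
    tset = frozenset(terms)
    parental: set[str] = set()
    for t in tset:
        parental |= ancestors(onto, t) & tset
    return tset - parental, frozenset(parental)
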