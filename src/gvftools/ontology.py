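"""Sequence Ontology term graph: loading, ancestry, branch membership.

GVF types its columns with terms from three branches of the Sequence
Ontology: *sequence_alteration* terms name the kind of change (the type
column), *sequence_feature* terms name the genomic features a variant
intersects, and *sequence_variant* terms name its consequence (both used
inside the ``Variant_effect`` attribute).  Only ``is_a`` edges are
traversed for typing — branch membership is an is_a taxonomy; part_of and
other relationships are ignored.

OBO stanza parsing is delegated to :mod:`obonet`; the resulting graph is
wrapped in :class:`Ontology`, which memoizes the reflexive-transitive
is_a closure.  A small hand-curated subgraph (synthetic, ~45 terms) is
bundled so the toolkit works without the full SO; pass any OBO file to
:func:`load_obo` to use a live release instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import IO

import networkx as nx
import obonet

from .errors import MalformedOntologyError, UnknownTermError

#: The three branch anchors used to type GVF columns.
BRANCH_ROOTS = ("sequence_alteration", "sequence_feature", "sequence_variant")

_BUNDLED_OBO = "so_subset_synthetic.obo"


@dataclass(frozen=True)
class Term:
    accession: str
    name: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False


class Ontology:
    """A directed acyclic ``is_a`` term graph with branch queries.

    Terms may be addressed by accession (``SO:0001483``, case-sensitive)
    or by primary name (``SNV``, case-insensitive).
    """

    def __init__(self, terms: dict[str, Term], parents: dict[str, tuple[str, ...]]):
        self.terms = terms
        self._parents = parents
        self._by_name: dict[str, str] = {}
        for acc, term in terms.items():
            if not term.obsolete:
                self._by_name.setdefault(term.name.lower(), acc)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._check_structure()

    # -- construction -------------------------------------------------

    def _check_structure(self) -> None:
        for acc, parents in self._parents.items():
            for p in parents:
                if p not in self.terms:
                    raise MalformedOntologyError(
                        f"term {acc} has is_a link to undeclared accession {p}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for acc, parents in self._parents.items():
            g.add_edges_from((acc, p) for p in parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise MalformedOntologyError(f"is_a cycle detected: {cycle}")

    # -- lookup -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        try:
            self.resolve(term)
        except UnknownTermError:
            return False
        return True

    def resolve(self, term: str) -> str:
        """Map an accession or primary name to the term's accession."""
        if term in self.terms:
            return term
        acc = self._by_name.get(term.lower())
        if acc is None:
            raise UnknownTermError(f"unknown ontology term: {term!r}")
        return acc

    def name_of(self, term: str) -> str:
        return self.terms[self.resolve(term)].name

    def parents(self, term: str) -> tuple[str, ...]:
        return self._parents.get(self.resolve(term), ())

    @property
    def roots(self) -> frozenset[str]:
        """Accessions of non-obsolete terms without is_a parents."""
        return frozenset(
            acc
            for acc, t in self.terms.items()
            if not t.obsolete and not self._parents.get(acc)
        )

    # -- ancestry -----------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive is_a closure (accessions), including *term*."""
        acc = self.resolve(term)
        cached = self._ancestor_cache.get(acc)
        if cached is None:
            out = {acc}
            for p in self._parents.get(acc, ()):
                out |= self.ancestors(p)
            cached = self._ancestor_cache[acc] = frozenset(out)
        return cached

    def is_a_closure(self, term: str, ancestor: str) -> bool:
        """True iff *ancestor* is reachable from *term* by >= 0 is_a edges."""
        return self.resolve(ancestor) in self.ancestors(term)

    def branches(self, term: str) -> frozenset[str]:
        """Names of the branch anchors reachable from *term* (possibly empty)."""
        reached = {self.terms[a].name for a in self.ancestors(term)}
        return frozenset(b for b in BRANCH_ROOTS if b in reached)

    def branch_of(self, term: str) -> str | None:
        """The unique branch anchor above *term*.

        Returns ``None`` when the term reaches no anchor.  If a term ever
        reaches more than one anchor the full set is returned so callers
        can check membership per branch.
        """
        b = self.branches(term)
        if not b:
            return None
        if len(b) == 1:
            return next(iter(b))
        return b  # type: ignore[return-value]

    def is_obsolete(self, term: str) -> bool:
        return self.terms[self.resolve(term)].obsolete


def load_obo(source: str | IO[str]) -> Ontology:
    """Load an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    *source* is a path or a text stream.  Obsolete terms are retained and
    flagged.  A cycle over is_a edges or an is_a link to an undeclared
    accession raises :class:`MalformedOntologyError`.
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)
    terms: dict[str, Term] = {}
    parents: dict[str, tuple[str, ...]] = {}
    for acc, data in graph.nodes(data=True):
        if "name" not in data:
            # networkx materializes edge targets as empty nodes
            raise MalformedOntologyError(
                f"is_a link targets undeclared accession {acc}"
            )
        synonyms = tuple(
            s.split('"')[1] for s in data.get("synonym", ()) if '"' in s
        )
        terms[acc] = Term(
            accession=acc,
            name=data["name"],
            synonyms=synonyms,
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parents.setdefault(child, ())
        parents[child] = parents[child] + (parent,)
    return Ontology(terms, parents)


def load_obo_text(text: str) -> Ontology:
    """Convenience wrapper: load an ontology from OBO text."""
    return load_obo(io.StringIO(text))


def load_bundled() -> Ontology:
    """Load the bundled synthetic SO subgraph shipped with the package."""
    ref = resources.files("gvftools").joinpath("data").joinpath(_BUNDLED_OBO)
    with ref.open("r", encoding="utf-8") as fh:
        return load_obo(fh)
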