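"""Tissue ontology DAG: term storage, ancestor closure and score propagation.

The ontology is a plain ``is_a`` DAG (no part_of / develops_from reasoning).
Evidence propagates upward with MAX semantics: a score at a term means
"expressed somewhere at or below this term", so a parent inherits the best
score among its descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

from .errors import ValidationError


@dataclass
class TissueOntology:
    """is_a DAG of tissue terms.

    Parameters
    ----------
    names
        Term id -> human readable name.
    parents
        Child term id -> set of direct is_a parents. Every parent must be a
        known term; the graph must be acyclic.
    major_tissues
        Configured subset of terms used for cross-dataset comparison and
        display (21 terms by default in the shipped configuration).
    """

    names: dict[str, str]
    parents: dict[str, set[str]] = field(default_factory=dict)
    major_tissues: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.names:
                raise ValidationError(f"parent map references unknown term {child!r}")
            for p in ps:
                if p not in self.names:
                    raise ValidationError(
                        f"term {child!r} has dangling is_a target {p!r}"
                    )
        cycle = self._find_cycle()
        if cycle is not None:
            raise ValidationError(
                "is_a graph contains a cycle: " + " -> ".join(cycle)
            )
        unknown_major = self.major_tissues - set(self.names)
        if unknown_major:
            raise ValidationError(
                f"major tissues not in ontology: {sorted(unknown_major)}"
            )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.names)

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def __len__(self) -> int:
        return len(self.names)

    def _find_cycle(self) -> list[str] | None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.names}
        stack_path: list[str] = []

        def dfs(node: str) -> list[str] | None:
            color[node] = GRAY
            stack_path.append(node)
            for p in sorted(self.parents.get(node, ())):
                if color[p] == GRAY:
                    i = stack_path.index(p)
                    return stack_path[i:] + [p]
                if color[p] == WHITE:
                    found = dfs(p)
                    if found is not None:
                        return found
            color[node] = BLACK
            stack_path.pop()
            return None

        for t in sorted(self.names):
            if color[t] == WHITE:
                found = dfs(t)
                if found is not None:
                    return found
        return None

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive is_a closure of *term*, excluding the term itself."""
        if term not in self.names:
            raise ValidationError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def with_major_tissues(self, major: set[str]) -> "TissueOntology":
        return replace(self, major_tissues=set(major))


def ancestors(onto: TissueOntology, term: str) -> frozenset[str]:
    """Functional alias for :meth:`TissueOntology.ancestors`."""
    return onto.ancestors(term)


def propagate_scores(assocs, onto: TissueOntology):
    """Propagate gene-tissue scores to all ancestor terms with MAX semantics.

    For every gene and every term, the propagated score is the maximum of the
    term's own score and the scores of all its descendants. Associations are
    created for ancestor terms that had none. Raw values are not propagated
    (they are platform-specific); the winning association's confidence and
    stars are copied to the ancestor.
    """
    from .scoring import Association, ScoredChannel

    for a in assocs.associations:
        if a.tissue not in onto:
            raise ValidationError(
                f"association ({a.gene}, {a.tissue}) references unknown term"
            )

    best: dict[tuple[str, str], Association] = {}

    def sort_key(a: Association):
        return (a.score_key(), a.tissue)

    for a in assocs.associations:
        targets = {a.tissue} | onto.ancestors(a.tissue)
        for t in targets:
            key = (a.gene, t)
            cur = best.get(key)
            if cur is None or sort_key(a) > sort_key(cur):
                best[key] = a

    out = []
    for (gene, term), src in sorted(best.items()):
        if term == src.tissue:
            out.append(src)
        else:
            out.append(
                Association(
                    gene=gene,
                    tissue=term,
                    raw=None,
                    confidence=src.confidence,
                    stars=src.stars,
                )
            )
    return ScoredChannel(
        channel=assocs.channel, organism=assocs.organism, associations=out
    )


def restrict_to_major(assocs, onto: TissueOntology):
    """Keep only associations whose tissue is in the configured major set."""
    from .scoring import ScoredChannel

    if not onto.major_tissues:
        raise ValidationError("ontology has an empty major-tissue set")
    kept = [a for a in assocs.associations if a.tissue in onto.major_tissues]
    return ScoredChannel(
        channel=assocs.channel, organism=assocs.organism, associations=kept
    )


def load_major_tissues(organism: str = "human") -> dict[str, str]:
    """Shipped default major-tissue configuration (term id -> name).

    21 terms for most organisms; rat lacks a gall bladder, so its list has 20.
    """
    text = (
        resources.files("tissuescore.data")
        .joinpath("major_tissues.tsv")
        .read_text(encoding="utf-8")
    )
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term, name = line.split("\t")
        if organism == "rat" and name == "gall bladder":
            continue
        out[term] = name
    return out
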