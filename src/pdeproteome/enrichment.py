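"""Overrepresentation analysis of candidate lists against a term database.

For a candidate sample of size ``n`` drawn from a reference universe of
size ``N``, a term with ``K`` annotated members has expected count
``K * n / N``; the fold enrichment is ``observed / expected`` and the
raw p-value is the one-tailed Fisher exact (hypergeometric upper tail)
probability ``P(X >= observed)``.  P-values are Bonferroni-corrected
over the number of terms actually tested.  Annotations follow the
true-path rule: a protein annotated to a term counts for all its
ancestors in the term DAG.  Among significant terms, the "most specific"
subset keeps only terms with no significant descendant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

__all__ = [
    "AnnotationDB",
    "EnrichmentResult",
    "overrepresentation_test",
    "bonferroni",
    "most_specific_terms",
]


@dataclass
class AnnotationDB:
    """Term membership plus parent links (a DAG), with true-path closure.

    ``terms`` maps a term id to ``(name, members)`` as annotated;
    ``parents`` maps a term id to its parent term ids.  On construction,
    memberships are propagated to all ancestors.  ``reference_size`` is
    the size of the reference universe (it may exceed the number of
    annotated proteins).
    """

    terms: dict[str, tuple[str, set[str]]]
    parents: dict[str, set[str]]
    reference_size: int

    graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.reference_size <= 0:
            raise ValueError("reference_size must be positive")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for parent in ps:
                g.add_edge(child, parent)  # edge points child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term parent links must form a DAG")
        self.graph = g
        # true-path rule: propagate members up to every ancestor
        closed: dict[str, tuple[str, set[str]]] = {
            t: (name, set(members)) for t, (name, members) in self.terms.items()
        }
        for term in nx.topological_sort(g):
            name, members = closed.get(term, (term, set()))
            for parent in g.successors(term):
                pname, pmembers = closed.get(parent, (parent, set()))
                closed[parent] = (pname, pmembers | members)
        self.terms = closed

    def members(self, term: str) -> set[str]:
        return self.terms[term][1]

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` in the DAG (more specific terms)."""
        return set(nx.ancestors(self.graph, term))

    # -- plain-text round trip --------------------------------------------
    def to_tables(self, annotations_path: str | Path, parents_path: str | Path) -> None:
        """Write GAF-like (accession, term, name) and (term, parent) TSVs."""
        with open(annotations_path, "w") as fh:
            fh.write("accession\tterm\tname\n")
            for term in sorted(self.terms):
                name, members = self.terms[term]
                for acc in sorted(members):
                    fh.write(f"{acc}\t{term}\t{name}\n")
        with open(parents_path, "w") as fh:
            fh.write("term\tparent\n")
            for term in sorted(self.parents):
                for parent in sorted(self.parents[term]):
                    fh.write(f"{term}\t{parent}\n")

    @classmethod
    def from_tables(
        cls,
        annotations_path: str | Path,
        parents_path: str | Path,
        reference_size: int,
    ) -> "AnnotationDB":
        terms: dict[str, tuple[str, set[str]]] = {}
        with open(annotations_path) as fh:
            next(fh)
            for line in fh:
                acc, term, name = line.rstrip("\n").split("\t")
                terms.setdefault(term, (name, set()))[1].add(acc)
        parents: dict[str, set[str]] = {}
        with open(parents_path) as fh:
            next(fh)
            for line in fh:
                term, parent = line.rstrip("\n").split("\t")
                parents.setdefault(term, set()).add(parent)
                terms.setdefault(term, (term, set()))
                terms.setdefault(parent, (parent, set()))
        return cls(terms=terms, parents=parents, reference_size=reference_size)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    K: int
    n: int
    observed: int
    expected: float
    fold: float
    p_raw: float
    p_corrected: float = float("nan")
    significant: bool = False
    is_most_specific: bool = False


def overrepresentation_test(
    sample: Iterable[str],
    db: AnnotationDB,
    min_observed: int = 1,
    *,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of every term in the sample.

    ``expected = K * n / N`` and ``fold = observed / expected`` use the
    full reference size ``N = db.reference_size``; ``p_raw`` is the
    upper-tail hypergeometric probability of observing at least the seen
    count.  Terms with fewer than ``min_observed`` sample members are not
    tested.  When ``universe`` is given, sample members outside it raise.
    """
    sample = set(sample)
    if universe is not None and not sample <= universe:
        bad = sorted(sample - universe)[:5]
        raise ValueError(f"sample members outside the reference universe: {bad}")
    n = len(sample)
    N = db.reference_size
    if n == 0:
        return []
    results = []
    for term in sorted(db.terms):
        name, members = db.terms[term]
        K = len(members)
        observed = len(sample & members)
        if observed < min_observed or K == 0:
            continue
        expected = K * n / N
        fold = observed / expected
        p_raw = float(stats.hypergeom.sf(observed - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term=term,
                name=name,
                K=K,
                n=n,
                observed=observed,
                expected=expected,
                fold=fold,
                p_raw=p_raw,
            )
        )
    return results


def bonferroni(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Bonferroni correction over the m terms actually tested."""
    m = len(results)
    out = []
    for r in results:
        p_c = min(1.0, m * r.p_raw)
        out.append(
            EnrichmentResult(
                term=r.term,
                name=r.name,
                K=r.K,
                n=r.n,
                observed=r.observed,
                expected=r.expected,
                fold=r.fold,
                p_raw=r.p_raw,
                p_corrected=p_c,
                significant=p_c < alpha,
            )
        )
    return out


def most_specific_terms(significant: set[str], db: AnnotationDB) -> set[str]:
    """Significant terms none of whose DAG descendants is significant."""
    unknown = significant - set(db.terms)
    if unknown:
        raise ValueError(f"terms not in the annotation DB: {sorted(unknown)[:5]}")
    return {
        t
        for t in significant
        if not (db.descendants(t) & (significant - {t}))
    }
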