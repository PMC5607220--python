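"""Sparsest-DAG edge reconstruction from a detected class pattern.

A class pattern pins down the relative hierarchy of every gene pair but
not the exact edge set: class 4/5 assignments lose track of how many
reporter-bound paths bypass the partner gene, so several DAGs share one
pattern.  Following the convention that genetic-interaction maps are
sparse, the policy emits only the edges *necessary* for the pattern:

* E1 — edge i->j if i is linearly upstream of j (class 1) and no gene l is
  linearly between them (class(i,l)=1 and class(j,l)=2);
* E2 — edge i->j if i is partially upstream of j (class 4) and no gene l
  is downstream of i (class(i,l) in {1,4}) while upstream of j
  (class(j,l) in {2,5});
* E3/E4 — mirrors of E1/E2 for edges j->i (classes 2 and 5);
* ER — edge i->R if no gene is linearly downstream of i and the class-4
  partner set M_i is empty or contains no two mutually independent genes
  (M_i' empty).

Ordered-pair class lookups use the symmetry expansion 1<->2, 4<->5.

The pairwise rules alone do not always realise the sparsest DAG of a
pattern: they cannot see *coalitions* of intermediates.  Dropping every
blocked optional edge can sever all of a gene's independent outlets (its
class-4 relations collapse to class 1 on re-derivation), and an edge can
be redundant because two partial intermediates jointly cover every path
even though neither blocks it alone.  :func:`reconstruct_edges` therefore
completes the rules with two exact, deterministic steps: a reporter edge
is granted to any gene whose partial-upstream independence the detected
edges fail to certify (necessary for the pattern, and always safe for a
gene without linearly-downstream partners), and detected edges that can
be removed without changing the re-derived pattern are greedily pruned in
canonical order.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from .dag_core import REPORTER, ClassPattern, Dag, Edge, pattern_from_dag, validate_dag


def candidate_sets(pattern: ClassPattern, i: str) -> Tuple[Set[str], Set[str]]:
    """The class-4 partner set M_i and its independent-pair subset M_i'."""
    m = {l for l in pattern.genes if l != i and pattern.get(i, l) == 4}
    mp = {
        l for l in m
        if any(pattern.get(l, lt) == 3 for lt in m if lt != l)
    }
    return m, mp


def _edge_condition(pattern: ClassPattern, i: str, j: str) -> bool:
    """E1 or E2 for the ordered pair (i, j): necessary edge i -> j."""
    k = pattern.get(i, j)
    if k == 1:
        return not any(
            pattern.get(i, l) == 1 and pattern.get(j, l) == 2
            for l in pattern.genes if l not in (i, j)
        )
    if k == 4:
        return not any(
            pattern.get(i, l) in (1, 4) and pattern.get(j, l) in (2, 5)
            for l in pattern.genes if l not in (i, j)
        )
    return False


def detect_edges(pattern: ClassPattern) -> FrozenSet[Edge]:
    """Gene-gene edges selected by the mutually exclusive rules E1-E4."""
    edges: List[Edge] = []
    for i, j in itertools.combinations(pattern.genes, 2):
        if _edge_condition(pattern, i, j):      # E1 / E2
            edges.append((i, j))
        if _edge_condition(pattern, j, i):      # E3 / E4 by mirror symmetry
            edges.append((j, i))
    return frozenset(edges)


def detect_reporter_edges(pattern: ClassPattern) -> FrozenSet[Edge]:
    """Reporter edges i -> R selected by rule ER."""
    edges: List[Edge] = []
    for i in pattern.genes:
        if any(pattern.get(i, l) == 1 for l in pattern.genes if l != i):
            continue
        m, mp = candidate_sets(pattern, i)
        if not m or not mp:
            edges.append((i, REPORTER))
    return frozenset(edges)


def _reaches_reporter_avoiding(succ: Dict[str, List[str]], start: str,
                               avoid: str | None) -> bool:
    seen, stack = {start}, [start]
    while stack:
        node = stack.pop()
        if node == REPORTER:
            return True
        for nxt in succ.get(node, []):
            if nxt != avoid and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def complete_reporter_edges(pattern: ClassPattern,
                            edges: Iterable[Edge]) -> FrozenSet[Edge]:
    """Add the reporter edges an edge set needs to carry the pattern.

    A gene with no linearly-downstream partner must keep, for every
    class-4 partner j, a route to the reporter avoiding j (and at least
    one route at all).  Where the given edges provide none, the sparsest
    single repair is the gene's reporter edge; one edge restores every
    such relation at once and cannot disturb any other pair.  Genes are
    examined in canonical order until no deficit remains.
    """
    edges = set(edges)
    genes = pattern.genes
    while True:
        succ: Dict[str, List[str]] = {}
        for a, b in edges:
            succ.setdefault(a, []).append(b)
        needy = None
        for i in genes:
            if (i, REPORTER) in edges:
                continue
            if any(pattern.get(i, l) == 1 for l in genes if l != i):
                continue
            m = [l for l in genes if l != i and pattern.get(i, l) == 4]
            if (not succ.get(i)
                    or not _reaches_reporter_avoiding(succ, i, None)
                    or any(not _reaches_reporter_avoiding(succ, i, j) for j in m)):
                needy = i
                break
        if needy is None:
            return frozenset(edges)
        edges.add((needy, REPORTER))


def _prune_redundant(pattern: ClassPattern,
                     edges: FrozenSet[Edge]) -> FrozenSet[Edge]:
    """Greedily drop edges whose removal leaves the pattern intact."""
    genes = pattern.genes
    order = {g: n for n, g in enumerate(genes)}
    order[REPORTER] = len(genes)
    kept = set(edges)

    def still_consistent(es: Set[Edge]) -> bool:
        dag = Dag(genes, es)
        if not validate_dag(dag).is_valid:
            return False
        return pattern_from_dag(dag).classes == pattern.classes

    for e in sorted(kept, key=lambda e: (order[e[0]], order[e[1]])):
        if still_consistent(kept - {e}):
            kept.discard(e)
    return frozenset(kept)


def reconstruct_edges(pattern: ClassPattern,
                      sparsify: bool = True) -> FrozenSet[Edge]:
    """Edge set of the sparsest DAG consistent with a class pattern.

    ``sparsify=False`` returns the raw rule output (E1-E4 plus ER) with
    no completion or pruning, for inspection.
    """
    base = detect_edges(pattern) | detect_reporter_edges(pattern)
    if not sparsify:
        return base
    completed = complete_reporter_edges(pattern, base)
    return _prune_redundant(pattern, completed)


def reconstruct_dag(pattern: ClassPattern, require_valid: bool = True) -> Dag:
    """Assemble the sparsest DAG consistent with a class pattern.

    For patterns satisfying the topology constraint set the result always
    passes validation; an invalid reconstruction signals an infeasible
    input pattern (possible when the unconstrained per-pair classifier
    feeds this policy).  With ``require_valid=False`` the graph is
    returned regardless, for inspection.
    """
    dag = Dag(pattern.genes, reconstruct_edges(pattern))
    if require_valid:
        report = validate_dag(dag)
        if not report.is_valid:
            raise ValueError(
                "reconstruction is not a valid DAG (infeasible pattern): "
                + "; ".join(report.violations)
            )
    return dag
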