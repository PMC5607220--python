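"""Rooted-DAG representation and the hierarchical-relationship class calculus.

A genetic-interaction map is a directed acyclic graph over a set of genes
plus one artificial *reporter* node ``R`` representing the measured cell
function (e.g. colony fitness).  Every gene influences the phenotype only
through directed paths that terminate at ``R``; the relative arrangement of
any two genes falls into exactly one of five hierarchical relationship
classes:

1. *i* linearly upstream of *j* — every path from *i* to ``R`` passes *j*;
2. *j* linearly upstream of *i*;
3. *i* and *j* independent — neither lies on any path of the other;
4. *i* partially upstream of *j* — *i* has a path avoiding *j* and a path
   whose node set contains a full path of *j*;
5. *j* partially upstream of *i*.

This module provides the ``Dag`` container, validation, exhaustive path
enumeration, the class predicates (evaluated literally from the path
quantifiers, plus a fast reachability shortcut), class-pattern extraction,
and an exhaustive enumerator of all valid DAGs for small gene sets which
serves as the oracle for the optimisation layers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Sequence, Tuple

import networkx as nx

#: Reserved identifier of the reporter node.
REPORTER = "R"

#: Class relabelling under swapping the two genes of a pair: 1<->2, 4<->5, 3 fixed.
SWAP = {1: 2, 2: 1, 3: 3, 4: 5, 5: 4}

Edge = Tuple[str, str]


class DagError(ValueError):
    """Raised for structurally invalid inputs (unknown genes, bad arguments)."""


# ---------------------------------------------------------------------------
# Dag container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dag:
    """A rooted genetic-interaction DAG.

    Parameters
    ----------
    genes:
        Ordered gene identifiers; the position in this tuple defines the
        canonical pair order ``(i, j)`` with ``index(i) < index(j)``.
    edges:
        Directed edges over ``genes + (REPORTER,)``.  The reporter has
        out-degree zero and is never listed in ``genes``.
    """

    genes: Tuple[str, ...]
    edges: FrozenSet[Edge]
    _succ: Dict[str, Tuple[str, ...]] = field(
        init=False, repr=False, compare=False, hash=False, default=None
    )

    def __init__(self, genes: Sequence[str], edges) -> None:
        object.__setattr__(self, "genes", tuple(genes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        if REPORTER in self.genes:
            raise DagError(f"reporter identifier {REPORTER!r} cannot be a gene")
        if len(set(self.genes)) != len(self.genes):
            raise DagError("duplicate gene identifiers")
        succ: Dict[str, List[str]] = {g: [] for g in self.genes}
        succ[REPORTER] = []
        order = {g: n for n, g in enumerate(self.genes)}
        order[REPORTER] = len(self.genes)
        for a, b in self.edges:
            if a not in succ or b not in succ:
                raise DagError(f"edge ({a!r}, {b!r}) references unknown node")
            succ[a].append(b)
        object.__setattr__(
            self,
            "_succ",
            {g: tuple(sorted(s, key=order.__getitem__)) for g, s in succ.items()},
        )

    # -- convenience -------------------------------------------------------

    @property
    def index(self) -> Dict[str, int]:
        return {g: n for n, g in enumerate(self.genes)}

    def successors(self, node: str) -> Tuple[str, ...]:
        return self._succ[node]

    def gene_gene_edges(self) -> FrozenSet[Edge]:
        return frozenset(e for e in self.edges if e[1] != REPORTER)

    def reporter_edges(self) -> FrozenSet[Edge]:
        return frozenset(e for e in self.edges if e[1] == REPORTER)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_node(REPORTER)
        g.add_edges_from(self.edges)
        return g

    def canonical_pair(self, i: str, j: str) -> Tuple[str, str]:
        """Return the pair ordered by gene index (the paper's ``j > i``)."""
        idx = self.index
        return (i, j) if idx[i] < idx[j] else (j, i)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidityReport:
    is_valid: bool
    violations: Tuple[str, ...]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.is_valid


def validate_dag(candidate: Dag) -> ValidityReport:
    """Check the rooted-DAG invariants.

    A valid map is acyclic, has no self-edges, no edges leaving the
    reporter, and every gene has out-degree >= 1 with every maximal path
    terminating at the reporter.  Invalid graphs are reported, not raised.
    """
    violations: List[str] = []
    for a, b in sorted(candidate.edges):
        if a == b:
            violations.append(f"self-edge at {a!r}")
        if a == REPORTER:
            violations.append(f"edge originates at reporter: ({a!r}, {b!r})")
    g = candidate.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        violations.append("cycle: " + " -> ".join(a for a, _ in cycle))
    else:
        # with acyclicity established, "every maximal path ends at R" is
        # equivalent to: every gene reaches R and every sink is R
        for gene in candidate.genes:
            if not candidate.successors(gene):
                violations.append(f"gene {gene!r} has out-degree 0")
            elif not nx.has_path(g, gene, REPORTER):
                violations.append(f"gene {gene!r} has no path to the reporter")
    return ValidityReport(not violations, tuple(violations))


# ---------------------------------------------------------------------------
# Path calculus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathSet:
    """All directed paths from one gene to the reporter."""

    origin: str
    paths: Tuple[Tuple[str, ...], ...]

    def node_sets(self) -> Tuple[FrozenSet[str], ...]:
        return tuple(frozenset(p) for p in self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def enumerate_paths(dag: Dag, gene: str) -> PathSet:
    """Exhaustively enumerate all directed paths ``gene -> ... -> R``."""
    if gene not in dag.genes:
        raise DagError(f"unknown gene {gene!r}")
    out: List[Tuple[str, ...]] = []

    def walk(node: str, trail: List[str]) -> None:
        if node == REPORTER:
            out.append(tuple(trail))
            return
        for nxt in dag.successors(node):
            walk(nxt, trail + [nxt])

    walk(gene, [gene])
    return PathSet(gene, tuple(out))


def classify_pair(dag: Dag, i: str, j: str) -> int:
    """Hierarchical relationship class of the ordered pair ``(i, j)``.

    Evaluated literally from the path quantifiers over the exhaustive path
    sets of ``i`` and ``j``.  Exactly one of the five conditions must hold
    for a valid DAG; anything else signals a bug or an invalid input.
    """
    if i == j:
        raise DagError("classify_pair requires two distinct genes")
    vi = enumerate_paths(dag, i).node_sets()
    vj = enumerate_paths(dag, j).node_sets()
    c1 = all(j in v for v in vi)
    c2 = all(i in v for v in vj)
    c3 = all(j not in v for v in vi) and all(i not in v for v in vj)
    c4 = any(j not in v for v in vi) and any(b < a for a in vi for b in vj)
    c5 = any(i not in v for v in vj) and any(a < b for a in vi for b in vj)
    hits = [k for k, c in enumerate((c1, c2, c3, c4, c5), start=1) if c]
    if len(hits) != 1:
        raise DagError(
            f"pair ({i!r}, {j!r}) matches classes {hits}; invalid DAG or bug"
        )
    return hits[0]


def _reachability(dag: Dag) -> Dict[str, FrozenSet[str]]:
    """Descendant sets (excluding the node itself) for every gene."""
    reach: Dict[str, FrozenSet[str]] = {REPORTER: frozenset()}
    order = list(nx.topological_sort(dag.to_networkx()))
    for node in reversed(order):
        acc: set = set()
        for s in dag.successors(node):
            acc.add(s)
            acc |= reach[s]
        reach[node] = frozenset(acc)
    return reach


def _reaches_r_avoiding(dag: Dag, start: str, avoid: str) -> bool:
    """True iff some path start -> R avoids ``avoid``."""
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        if node == REPORTER:
            return True
        for nxt in dag.successors(node):
            if nxt != avoid and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def classify_pair_fast(dag: Dag, i: str, j: str,
                       reach: Dict[str, FrozenSet[str]] | None = None) -> int:
    """Reachability-based classification, equivalent to :func:`classify_pair`.

    In a DAG, a path of ``i`` whose node set strictly contains a full path
    of ``j`` exists iff ``i`` reaches ``j`` (any i->j path is node-disjoint
    from any j->R path except at ``j``).  Hence:

    * class 1  iff ``i`` cannot reach R avoiding ``j``;
    * class 4  iff ``i`` reaches ``j`` and also reaches R avoiding ``j``;
    * classes 2/5 mirror; class 3 iff neither reaches the other.
    """
    if reach is None:
        reach = _reachability(dag)
    i_to_j = j in reach[i]
    j_to_i = i in reach[j]
    if i_to_j:
        return 4 if _reaches_r_avoiding(dag, i, j) else 1
    if j_to_i:
        return 5 if _reaches_r_avoiding(dag, j, i) else 2
    return 3


# ---------------------------------------------------------------------------
# Class patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassPattern:
    """Total assignment of one class k in {1..5} to every unordered pair.

    Keys are canonical pairs ``(i, j)`` with ``index(i) < index(j)``; the
    ordered lookup :meth:`get` applies the 1<->2 / 4<->5 swap symmetry.
    """

    genes: Tuple[str, ...]
    classes: Dict[Tuple[str, str], int]

    def __post_init__(self) -> None:
        idx = {g: n for n, g in enumerate(self.genes)}
        expected = {
            (a, b) for a, b in itertools.combinations(self.genes, 2)
        }
        if set(self.classes) != expected:
            raise DagError("pattern must assign exactly the canonical pairs")
        for pair, k in self.classes.items():
            if k not in SWAP:
                raise DagError(f"invalid class {k} for pair {pair}")
            if idx[pair[0]] >= idx[pair[1]]:
                raise DagError(f"pair {pair} is not in canonical order")

    def get(self, i: str, j: str) -> int:
        """Class of the ordered pair ``(i, j)`` (symmetry-expanded)."""
        if (i, j) in self.classes:
            return self.classes[(i, j)]
        return SWAP[self.classes[(j, i)]]

    def pairs(self) -> Iterator[Tuple[str, str]]:
        return iter(sorted(self.classes, key=lambda p: (
            self.genes.index(p[0]), self.genes.index(p[1]))))

    def as_tuple(self) -> Tuple[int, ...]:
        return tuple(self.classes[p] for p in self.pairs())


def pattern_from_dag(dag: Dag, fast: bool = True) -> ClassPattern:
    """Extract the full class pattern of a valid DAG.

    ``fast=True`` uses the reachability characterisation; ``fast=False``
    evaluates the literal path quantifiers (exponential in dense graphs).
    """
    classes: Dict[Tuple[str, str], int] = {}
    reach = _reachability(dag) if fast else None
    for i, j in itertools.combinations(dag.genes, 2):
        if fast:
            classes[(i, j)] = classify_pair_fast(dag, i, j, reach)
        else:
            classes[(i, j)] = classify_pair(dag, i, j)
    return ClassPattern(dag.genes, classes)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (oracle)
# ---------------------------------------------------------------------------

def default_gene_names(G: int) -> Tuple[str, ...]:
    return tuple(f"g{n}" for n in range(1, G + 1))


def _acyclic_gene_graphs(genes: Tuple[str, ...]) -> Iterator[FrozenSet[Edge]]:
    """All acyclic directed simple graphs over ``genes`` (no reporter yet).

    Recursion over the ordered edge universe with incremental transitive-
    closure pruning: an edge (a, b) is only added while b does not already
    reach a.
    """
    universe = [(a, b) for a in genes for b in genes if a != b]
    n = len(universe)
    reach = {g: {g} for g in genes}  # reflexive closure

    def rec(pos: int, chosen: List[Edge]) -> Iterator[FrozenSet[Edge]]:
        if pos == n:
            yield frozenset(chosen)
            return
        yield from rec(pos + 1, chosen)
        a, b = universe[pos]
        if a not in reach[b]:
            ancestors = [g for g in genes if a in reach[g]]
            added = {(g, d) for g in ancestors for d in reach[b] if d not in reach[g]}
            for g, d in added:
                reach[g].add(d)
            chosen.append((a, b))
            yield from rec(pos + 1, chosen)
            chosen.pop()
            for g, d in added:
                reach[g].remove(d)

    yield from rec(0, [])


def enumerate_valid_dags(G: int) -> Iterator[Dag]:
    """Yield every valid rooted DAG on ``G`` labelled genes exactly once.

    The graph universe grows as 2^(G(G-1)+G); the enumeration prunes cyclic
    gene-gene subgraphs incrementally and only attaches reporter edges that
    keep the map valid (sinks must wire to the reporter, non-sinks may).
    Capped at G=5 to stay desk-scale.
    """
    if not 1 <= G <= 5:
        raise DagError("enumerate_valid_dags supports 1 <= G <= 5")
    genes = default_gene_names(G)
    for gg in _acyclic_gene_graphs(genes):
        has_out = {a for a, _ in gg}
        sinks = [g for g in genes if g not in has_out]
        nonsinks = [g for g in genes if g in has_out]
        forced = [(g, REPORTER) for g in sinks]
        for r in range(len(nonsinks) + 1):
            for extra in itertools.combinations(nonsinks, r):
                yield Dag(genes, gg | set(forced) | {(g, REPORTER) for g in extra})


def count_valid_dags_bruteforce(G: int) -> int:
    """Independent oracle: filter *all* directed simple graphs through
    :func:`validate_dag`.  Exponential; intended for G <= 3 only."""
    genes = default_gene_names(G)
    universe = [(a, b) for a in genes for b in genes if a != b]
    universe += [(g, REPORTER) for g in genes]
    count = 0
    for mask in range(1 << len(universe)):
        edges = {universe[b] for b in range(len(universe)) if mask >> b & 1}
        if validate_dag(Dag(genes, edges)).is_valid:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_edge_list(dag: Dag, path) -> None:
    """Two-column TSV (source, target); reporter serialised as ``R``."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        idx = dag.index
        idx[REPORTER] = len(dag.genes)
        for a, b in sorted(dag.edges, key=lambda e: (idx[e[0]], idx[e[1]])):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> Dag:
    edges: List[Edge] = []
    nodes: List[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget":
            raise DagError(f"{path}: expected 'source\\ttarget' header, line 1")
        for n, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DagError(f"{path}: malformed edge at line {n}")
            edges.append((parts[0], parts[1]))
            for p in parts:
                if p != REPORTER and p not in nodes:
                    nodes.append(p)
    return Dag(sorted(nodes), edges)


def write_dot(dag: Dag, path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph gimap {\n")
        fh.write(f'  "{REPORTER}" [shape=doublecircle];\n')
        for a, b in sorted(dag.edges):
            fh.write(f'  "{a}" -> "{b}";\n')
        fh.write("}\n")


def write_graphml(dag: Dag, path) -> None:
    nx.write_graphml(dag.to_networkx(), path)
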