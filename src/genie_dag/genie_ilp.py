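"""The GENIE linear integer program.

Classifying every gene pair into one of the five hierarchical relationship
classes is a coupled multi-hypothesis test: the program minimises the total
quadratic mismatch

    min  sum_{i<j} sum_k s_k(i,j) alpha_k(i,j)

over binary class-selection variables ``alpha_k(i,j)`` (SOS-1 per pair),
subject to the topology constraint set ``L`` that restricts the selected
pattern to ones realisable by a valid rooted DAG.

``L`` is assembled from per-triple implication families: fixing the classes
of pairs (i,j) and (i,l) restricts the classes pair (j,l) can take.  The
allowed-class relation is derived once, exhaustively, from all rooted DAGs
on three genes (every class triple is realisable within a larger DAG iff it
is realisable on three genes, since the class of a pair depends only on
path membership of the other gene).  The family conditioned on class 1 of
(i,j) reproduces the five classical linear inequalities, e.g.

    alpha_1(j,l) + alpha_2(j,l) >= alpha_1(i,j) + alpha_1(i,l) - 1.

Solved exactly by branch-and-bound (HiGHS via scipy); determinism comes
from the fixed variable ordering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_array

from .dag_core import (SWAP, ClassPattern, DagError, default_gene_names,
                       enumerate_valid_dags, pattern_from_dag)
from .interaction_model import ModelRegistry, PhenotypeData, DEFAULT_REGISTRY, score

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]
CLASSES = (1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# Abstract model container + exact solver backend
# ---------------------------------------------------------------------------

class IlpError(RuntimeError):
    pass


class IlpInfeasibleError(IlpError):
    pass


@dataclass
class _Constraint:
    coeffs: Dict[str, float]
    lower: float
    upper: float
    tag: str


class IlpModel:
    """Binary-variable / linear-constraint / linear-objective container.

    The reported size follows the convention of one binary-domain
    constraint per declared variable plus one entry per linear constraint;
    this reproduces the printed "225 binary variables and 270 constraints"
    for the topology-free program at G=10.
    """

    def __init__(self, name: str = "model") -> None:
        self.name = name
        self._vars: Dict[str, int] = {}
        self._objective: Dict[str, float] = {}
        self._constraints: List[_Constraint] = []

    # -- building ----------------------------------------------------------

    def add_binary(self, name: str) -> None:
        if name in self._vars:
            raise IlpError(f"duplicate variable {name!r}")
        self._vars[name] = len(self._vars)

    def add_constraint(self, coeffs: Dict[str, float], lower: float,
                       upper: float, tag: str = "") -> None:
        for v in coeffs:
            if v not in self._vars:
                raise IlpError(f"constraint references undeclared variable {v!r}")
        self._constraints.append(_Constraint(dict(coeffs), lower, upper, tag))

    def set_objective(self, coeffs: Dict[str, float]) -> None:
        self._objective = dict(coeffs)

    # -- reporting ---------------------------------------------------------

    @property
    def n_binary(self) -> int:
        return len(self._vars)

    @property
    def n_constraints(self) -> int:
        """Total count: binary-domain constraints + linear constraints."""
        return len(self._vars) + len(self._constraints)

    def size_report(self) -> Dict[str, int]:
        by_tag: Dict[str, int] = {}
        for c in self._constraints:
            key = c.tag.split(":")[0] or "untagged"
            by_tag[key] = by_tag.get(key, 0) + 1
        rep = {"binary_variables": self.n_binary,
               "constraints": self.n_constraints,
               "domain_constraints": self.n_binary}
        rep.update({f"family_{k}": v for k, v in sorted(by_tag.items())})
        return rep

    def write_lp(self, path) -> None:
        """Debug export in (a subset of) CPLEX LP format."""
        with open(path, "w") as fh:
            fh.write("Minimize\n obj: ")
            fh.write(" + ".join(f"{c} {v}" for v, c in self._objective.items()) or "0")
            fh.write("\nSubject To\n")
            for n, c in enumerate(self._constraints):
                expr = " + ".join(f"{w} {v}" for v, w in c.coeffs.items())
                if c.lower == c.upper:
                    fh.write(f" c{n}: {expr} = {c.lower}\n")
                else:
                    if np.isfinite(c.lower):
                        fh.write(f" c{n}lo: {expr} >= {c.lower}\n")
                    if np.isfinite(c.upper):
                        fh.write(f" c{n}up: {expr} <= {c.upper}\n")
            fh.write("Binary\n")
            for v in self._vars:
                fh.write(f" {v}\n")
            fh.write("End\n")

    # -- solving -----------------------------------------------------------

    def solve(self, integrality_tol: float = 1e-6,
              time_limit: float | None = None) -> Dict[str, float]:
        """Solve to proven optimality; returns variable values by name."""
        nv = len(self._vars)
        c = np.zeros(nv)
        for v, w in self._objective.items():
            c[self._vars[v]] = w
        rows, cols, vals, lo, up = [], [], [], [], []
        for r, con in enumerate(self._constraints):
            for v, w in con.coeffs.items():
                rows.append(r)
                cols.append(self._vars[v])
                vals.append(w)
            lo.append(con.lower)
            up.append(con.upper)
        a = csr_array((vals, (rows, cols)), shape=(len(self._constraints), nv))
        options: Dict[str, float] = {"mip_rel_gap": 0.0}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = milp(
            c,
            constraints=LinearConstraint(a, lo, up) if self._constraints else None,
            integrality=np.ones(nv),
            bounds=Bounds(0, 1),
            options=options,
        )
        if res.status == 2:
            raise IlpInfeasibleError(f"{self.name}: program infeasible")
        if res.status == 1:
            raise IlpError(f"{self.name}: solver hit iteration/time limit, "
                           f"best bound {getattr(res, 'mip_dual_bound', None)}")
        if not res.success:
            raise IlpError(f"{self.name}: solver failed ({res.message})")
        x = np.rint(res.x)
        if np.max(np.abs(res.x - x)) > integrality_tol:
            raise IlpError(f"{self.name}: solution not integral")
        values = {v: float(x[idx]) for v, idx in self._vars.items()}
        values["__objective__"] = float(c @ x)
        return values


def alpha_name(k: int, i: str, j: str) -> str:
    return f"a{k}({i},{j})"


# ---------------------------------------------------------------------------
# Topology constraints (set L)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def allowed_triple_classes() -> Dict[Tuple[int, int], Tuple[int, ...]]:
    """Allowed classes of pair (j,l) given classes of (i,j) and (i,l).

    Derived exhaustively from every rooted DAG on three genes.  Keys are
    ``(k_ij, k_il)``; values are the sorted classes pair (j,l) can take in
    any valid DAG.  Combinations allowing all five classes carry no logical
    implication and are omitted from the emitted constraint set.
    """
    realizable = realizable_triples()
    table: Dict[Tuple[int, int], Tuple[int, ...]] = {}
    for x in CLASSES:
        for y in CLASSES:
            table[(x, y)] = tuple(sorted(
                z for z in CLASSES if (x, y, z) in realizable))
    return table


@lru_cache(maxsize=1)
def realizable_triples() -> frozenset:
    """All class triples (c(i,j), c(i,l), c(j,l)) realisable by a DAG."""
    out = set()
    for dag in enumerate_valid_dags(3):
        p = pattern_from_dag(dag)
        g = dag.genes
        out.add((p.get(g[0], g[1]), p.get(g[0], g[2]), p.get(g[1], g[2])))
    return frozenset(out)


@dataclass(frozen=True)
class TopologyConstraint:
    """One linear implication:  sum_{z in allowed} a_z(j,l) >= a_x(i,j) + a_y(i,l) - 1."""

    i: str
    j: str
    l: str
    k_ij: int
    k_il: int
    allowed_jl: Tuple[int, ...]


def build_topology_constraints(genes: Sequence[str]) -> List[TopologyConstraint]:
    """Assemble the full topology constraint set L for a gene set.

    Empty below three genes (no triples exist).  For every ordered triple
    ``i < j < l`` one constraint is emitted per non-vacuous combination of
    the classes of (i,j) and (i,l); 21 per triple, grouped into the five
    per-class families (5 for class 1 as printed, 4 for each other class).
    """
    genes = tuple(genes)
    table = allowed_triple_classes()
    out: List[TopologyConstraint] = []
    for i, j, l in itertools.combinations(genes, 3):
        for (x, y), allowed in table.items():
            if len(allowed) == len(CLASSES):
                continue
            out.append(TopologyConstraint(i, j, l, x, y, allowed))
    return out


def pattern_satisfies_topology(pattern: ClassPattern) -> bool:
    """Direct substitution check of a total pattern against L."""
    realizable = realizable_triples()
    for i, j, l in itertools.combinations(pattern.genes, 3):
        if (pattern.get(i, j), pattern.get(i, l), pattern.get(j, l)) not in realizable:
            return False
    return True


# ---------------------------------------------------------------------------
# Scores, priors, program assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorKnowledge:
    """Fixed-class assertions ``alpha_k(i,j) = 1`` from existing evidence."""

    assertions: Tuple[Tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        pairs = [(i, j) for i, j, _ in self.assertions]
        if len(set(pairs)) != len(pairs):
            raise DagError("at most one prior assertion per pair")


def build_class_scores(data: PhenotypeData,
                       registry: ModelRegistry = DEFAULT_REGISTRY
                       ) -> Dict[Tuple[str, str, int], float]:
    """Mismatch score s_k(i,j) for every pair and class: 5 G(G-1)/2 entries."""
    scores: Dict[Tuple[str, str, int], float] = {}
    for i, j in itertools.combinations(data.genes, 2):
        if (i, j) not in data.dk:
            raise DagError(f"DK table misses pair ({i}, {j})")
        for k in CLASSES:
            scores[(i, j, k)] = score(k, data.dk[(i, j)], data.sk[i],
                                      data.sk[j], registry)
    return scores


def _genes_of_scores(scores: Dict[Tuple[str, str, int], float]) -> Tuple[str, ...]:
    genes: List[str] = []
    for i, j, _ in scores:
        for g in (i, j):
            if g not in genes:
                genes.append(g)
    return tuple(genes)


def build_genie(scores: Dict[Tuple[str, str, int], float],
                priors: PriorKnowledge | None = None,
                include_topology: bool = True,
                genes: Sequence[str] | None = None) -> IlpModel:
    """Assemble the GENIE program.

    Binary ``alpha_k(i,j)`` per pair and class, one multiple-choice
    equality per pair, the topology set L (optional), and one fixing
    equality per prior assertion.
    """
    genes = tuple(genes) if genes is not None else _genes_of_scores(scores)
    model = IlpModel("GENIE" if include_topology else "GENIE-no-L")
    pairs = list(itertools.combinations(genes, 2))
    for i, j in pairs:
        for k in CLASSES:
            model.add_binary(alpha_name(k, i, j))
    model.set_objective({
        alpha_name(k, i, j): scores[(i, j, k)] for i, j in pairs for k in CLASSES
    })
    for i, j in pairs:
        model.add_constraint({alpha_name(k, i, j): 1.0 for k in CLASSES},
                             1.0, 1.0, tag="multiple_choice")
    if include_topology:
        for con in build_topology_constraints(genes):
            coeffs = {alpha_name(z, con.j, con.l): 1.0 for z in con.allowed_jl}
            coeffs[alpha_name(con.k_ij, con.i, con.j)] = \
                coeffs.get(alpha_name(con.k_ij, con.i, con.j), 0.0) - 1.0
            coeffs[alpha_name(con.k_il, con.i, con.l)] = \
                coeffs.get(alpha_name(con.k_il, con.i, con.l), 0.0) - 1.0
            model.add_constraint(coeffs, -1.0, np.inf, tag=f"L_{con.k_ij}")
    if priors is not None:
        for i, j, k in priors.assertions:
            model.add_constraint({alpha_name(k, i, j): 1.0}, 1.0, 1.0, tag="prior")
    logger.info("%s: %d binary variables, %d constraints", model.name,
                model.n_binary, model.n_constraints)
    return model


@dataclass(frozen=True)
class GenieResult:
    pattern: ClassPattern
    objective: float


def decode_pattern(genes: Sequence[str], values: Dict[str, float]) -> ClassPattern:
    genes = tuple(genes)
    classes: Dict[Pair, int] = {}
    for i, j in itertools.combinations(genes, 2):
        chosen = [k for k in CLASSES if values[alpha_name(k, i, j)] > 0.5]
        if len(chosen) != 1:
            raise IlpError(f"pair ({i},{j}) selected classes {chosen}")
        classes[(i, j)] = chosen[0]
    return ClassPattern(genes, classes)


def solve_genie(model: IlpModel, genes: Sequence[str],
                time_limit: float | None = None) -> GenieResult:
    """Solve to proven optimality and decode the class pattern."""
    values = model.solve(time_limit=time_limit)
    return GenieResult(decode_pattern(genes, values), values["__objective__"])
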