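"""GI-GENIE joint program: q threshold, coupling set L_c, optimality."""

import itertools

import numpy as np
import pytest

import genie_dag as gd
from genie_dag import (GiGenieWeights, GiProfile, build_class_scores,
                       build_coupling_constraints, build_gi_genie, compute_q,
                       solve_gi_genie)
from genie_dag.gi_genie_ilp import alpha_name, beta_name, z_name
from genie_dag.genie_ilp import realizable_triples
from genie_dag.interaction_model import draw_sk_values


def _profile(genes, values):
    return GiProfile(tuple(genes), dict(values))


# ---------------------------------------------------------------------------
# weights and q
# ---------------------------------------------------------------------------

def test_weight_validation():
    GiGenieWeights(0.05, 1.0, 0.8)
    with pytest.raises(ValueError):
        GiGenieWeights(lambda_c=0.5, lambda_p=0.8)   # c < p
    with pytest.raises(ValueError):
        GiGenieWeights(lambda_d=-1.0)
    with pytest.raises(ValueError):
        GiGenieWeights(lambda_c=1.5)


def test_q_threshold_economics():
    genes = ("a", "b", "c")
    w = GiGenieWeights(lambda_c=1.0, lambda_p=0.8)
    rho = _profile(genes, {("a", "b"): 1.0, ("a", "c"): 0.0, ("b", "c"): 0.79})
    q = compute_q(rho, w)
    # an edge is profitable exactly when lambda_c * rho >= lambda_p
    assert q[("a", "b")] == 1
    assert q[("a", "c")] == 0
    assert q[("b", "c")] == 0
    # monotone nondecreasing in rho
    grid = np.linspace(-1, 1, 21)
    qs = [compute_q(_profile(("x", "y", "z"),
                             {("x", "y"): r, ("x", "z"): 0, ("y", "z"): 0}),
                    w)[("x", "y")] for r in grid]
    assert qs == sorted(qs)
    # the literal printed quotient exceeds 1 and never fires
    q_lit = compute_q(rho, w, literal_threshold=True)
    assert all(v == 0 for v in q_lit.values())


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

def test_variable_decomposition_at_ten_genes():
    genes = gd.default_gene_names(10)
    zeros = {(i, j, k): 0.0
             for i, j in itertools.combinations(genes, 2) for k in range(1, 6)}
    flat = _profile(genes, {p: 0.0 for p in itertools.combinations(genes, 2)})
    model = build_gi_genie(zeros, flat, genes=genes)
    names = list(model._vars)
    n_alpha = sum(n.startswith("a") for n in names)
    n_beta = sum(n.startswith("b(") for n in names)
    n_z = sum(n.startswith("z") for n in names)
    assert (n_alpha, n_beta, n_z) == (225, 45, 360)
    assert model.n_binary == 630


def test_coupling_constraint_counts():
    genes = gd.default_gene_names(10)
    q = {p: 0 for p in itertools.combinations(genes, 2)}
    expanded = build_coupling_constraints(genes, q, expanded=True)
    compact = build_coupling_constraints(genes, q, expanded=False)
    assert len(expanded) == 45 * 8 * 18
    assert len(compact) == 45 * 8 * 12


def test_requires_three_genes():
    genes = ("a", "b")
    zeros = {("a", "b", k): 0.0 for k in range(1, 6)}
    with pytest.raises(ValueError):
        build_gi_genie(zeros, _profile(genes, {("a", "b"): 0.0}), genes=genes)


# ---------------------------------------------------------------------------
# coupling soundness oracle
# ---------------------------------------------------------------------------

def _blocked(pattern, i, j, l, q_ij):
    """Does gene l block the pair's edge under its class's (q-relaxed) rule?"""
    k = pattern.get(i, j)
    if k == 1:
        return pattern.get(i, l) == 1 and pattern.get(j, l) == 2
    if k == 2:
        return pattern.get(i, l) == 2 and pattern.get(j, l) == 1
    if k == 4:
        if q_ij:
            return pattern.get(i, l) == 1 and pattern.get(j, l) in (2, 5)
        return pattern.get(i, l) in (1, 4) and pattern.get(j, l) in (2, 5)
    if k == 5:
        if q_ij:
            return pattern.get(i, l) in (2, 5) and pattern.get(j, l) == 1
        return pattern.get(i, l) in (2, 5) and pattern.get(j, l) in (1, 4)
    return True  # class 3 carries no edge


def _policy_assignment(genes, pattern, q):
    """(alpha, beta, z) the coupling system admits for a fixed pattern:
    beta = 1 exactly for unblocked non-independent pairs, z_l = 1 unless
    l blocks."""
    vals = {}
    for (i, j), k in pattern.classes.items():
        for kk in range(1, 6):
            vals[alpha_name(kk, i, j)] = float(kk == k)
    for i, j in itertools.combinations(genes, 2):
        q_ij = q[(i, j)]
        others = [l for l in genes if l not in (i, j)]
        for l in others:
            vals[z_name(l, i, j)] = float(not _blocked(pattern, i, j, l, q_ij))
        unblocked = (pattern.get(i, j) != 3
                     and all(not _blocked(pattern, i, j, l, q_ij) for l in others))
        vals[beta_name(i, j)] = float(unblocked)
    return vals


@pytest.mark.parametrize("expanded", [True, False])
def test_coupling_soundness_on_enumerated_dags(expanded):
    """For every valid 3-gene DAG (and a G=4 sample), the true pattern
    together with its policy-implied edge selection and certificate
    variables satisfies every inequality of L_c and the aggregation
    constraint — the joint program never cuts a realisable pattern."""
    def check(dag):
        genes = dag.genes
        p = gd.pattern_from_dag(dag)
        und = {frozenset(e) for e in dag.gene_gene_edges()}
        q = {pair: int(frozenset(pair) in und)
             for pair in itertools.combinations(genes, 2)}
        vals = _policy_assignment(genes, p, q)
        for ineq in build_coupling_constraints(genes, q, expanded=expanded):
            total = sum(c * vals[v] for v, c in ineq.coeffs)
            assert total >= ineq.rhs - 1e-9, (sorted(dag.edges), ineq)
        for i, j in itertools.combinations(genes, 2):
            zsum = sum(vals[z_name(l, i, j)] for l in genes if l not in (i, j))
            assert len(genes) - 2 + vals[beta_name(i, j)] >= 1 + zsum - 1e-9

    for dag in gd.enumerate_valid_dags(3):
        check(dag)
    for n, dag in enumerate(gd.enumerate_valid_dags(4)):
        if n % 11 == 0:
            check(dag)


def test_printed_constraint_instance_forces_beta_zero():
    """alpha_1(i,j) = alpha_1(i,l) = alpha_2(j,l) = 1 forces beta(i,j) = 0."""
    genes = ("a", "b", "c")
    q = {p: 0 for p in itertools.combinations(genes, 2)}
    ineqs = build_coupling_constraints(genes, q)
    vals = {}
    for i, j in itertools.combinations(genes, 2):
        for kk in range(1, 6):
            vals[alpha_name(kk, i, j)] = 0.0
        for l in genes:
            if l not in (i, j):
                vals[z_name(l, i, j)] = 0.0
        vals[beta_name(i, j)] = 0.0
    vals[alpha_name(1, "a", "b")] = 1.0   # a linearly upstream of b
    vals[alpha_name(1, "a", "c")] = 1.0   # a linearly upstream of c
    vals[alpha_name(1, "b", "c")] = 1.0   # c between: alpha_2(b,c-swapped)
    vals[beta_name("a", "b")] = 1.0       # claimed edge must be rejected
    violated = any(
        sum(c * vals[v] for v, c in ineq.coeffs) < ineq.rhs - 1e-9
        for ineq in ineqs)
    assert violated
    vals[beta_name("a", "b")] = 0.0
    # note: with beta=0, some inequality may force z values instead; only
    # check that no beta-suppression inequality fires
    sup = [iq for iq in ineqs if iq.tag.startswith("Lc_E1")]
    assert all(sum(c * vals[v] for v, c in iq.coeffs) >= iq.rhs - 1e-9
               for iq in sup if (beta_name("a", "b"), -1.0) in iq.coeffs)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def test_bruteforce_optimality_g3(rng):
    """Solver optimum equals exhaustive enumeration of all feasible
    (pattern, beta, z) assignments on noisy 3-gene instances."""
    genes = gd.default_gene_names(3)
    pairs = list(itertools.combinations(genes, 2))
    w = GiGenieWeights()
    real = realizable_triples()
    for _ in range(4):
        dag = gd.random_dag(3, rng)
        sk = draw_sk_values(dag.genes, rng)
        data = gd.simulate_phenotypes(dag, sk, 0.5, seed=rng)
        rho = _profile(genes, {p: float(rng.uniform(-1, 1)) for p in pairs})
        scores = build_class_scores(data)
        q = compute_q(rho, w)
        ineqs = build_coupling_constraints(genes, q)
        best = np.inf
        for pat in itertools.product(range(1, 6), repeat=3):
            if pat not in real:
                continue
            for bvals in itertools.product((0, 1), repeat=3):
                if any(b and k == 3 for b, k in zip(bvals, pat)):
                    continue
                for zvals in itertools.product((0, 1), repeat=3):
                    vals = {}
                    for (i, j), k in zip(pairs, pat):
                        for kk in range(1, 6):
                            vals[alpha_name(kk, i, j)] = float(kk == k)
                    for (i, j), b in zip(pairs, bvals):
                        vals[beta_name(i, j)] = float(b)
                    for (i, j), z in zip(pairs, zvals):
                        l = next(g for g in genes if g not in (i, j))
                        vals[z_name(l, i, j)] = float(z)
                    if any(sum(c * vals[v] for v, c in iq.coeffs) < iq.rhs - 1e-9
                           for iq in ineqs):
                        continue
                    if any(1 + b < 1 + z for b, z in zip(bvals, zvals)):
                        continue  # |G|-2+beta >= 1+sum z at G=3
                    obj = sum(w.lambda_d * scores[(i, j, k)]
                              for (i, j), k in zip(pairs, pat))
                    obj += sum((-w.lambda_c * rho.get(i, j) + w.lambda_p) * b
                               for (i, j), b in zip(pairs, bvals))
                    best = min(best, obj)
        model = build_gi_genie(scores, rho, w, genes=genes)
        sol, _ = solve_gi_genie(model, genes)
        assert sol.objective == pytest.approx(best, abs=1e-9)


def test_zero_gi_weights_reduce_to_genie(rng):
    dag = gd.random_dag(4, rng)
    sk = draw_sk_values(dag.genes, rng)
    data = gd.simulate_phenotypes(dag, sk, 0.3, seed=8)
    rho = gd.gi_profile(data)
    scores = build_class_scores(data)
    w = GiGenieWeights(lambda_d=1.0, lambda_c=0.0, lambda_p=0.0)
    model = build_gi_genie(scores, rho, w, genes=dag.genes)
    sol, _ = solve_gi_genie(model, dag.genes)
    from genie_dag import build_genie, solve_genie
    base = solve_genie(build_genie(scores, genes=dag.genes), dag.genes)
    assert sol.pattern.classes == base.pattern.classes


def test_full_support_selects_every_permitted_edge(rng):
    """With rho = 1 everywhere, every pair the solved pattern permits
    carries an edge (brute-force dominance check at G=3)."""
    genes = gd.default_gene_names(3)
    pairs = list(itertools.combinations(genes, 2))
    dag = gd.random_dag(3, rng)
    sk = draw_sk_values(dag.genes, rng)
    data = gd.simulate_phenotypes(dag, sk, 0.0, seed=6)
    rho = _profile(genes, {p: 1.0 for p in pairs})
    scores = build_class_scores(data)
    model = build_gi_genie(scores, rho, genes=genes)
    sol, _ = solve_gi_genie(model, genes)
    for p in pairs:
        assert (sol.beta[p] == 0) == (sol.pattern.classes[p] == 3)


def test_class3_pairs_never_carry_edges(rng):
    for _ in range(3):
        dag = gd.random_dag(4, rng)
        sk = draw_sk_values(dag.genes, rng)
        data = gd.simulate_phenotypes(dag, sk, 1.0, seed=rng)
        rho = gd.gi_profile(data)
        scores = build_class_scores(data)
        model = build_gi_genie(scores, rho, genes=dag.genes)
        sol, edges = solve_gi_genie(model, dag.genes)
        for p, b in sol.beta.items():
            if sol.pattern.classes[p] == 3:
                assert b == 0


def test_noiseless_recovery_with_edge_indicator_profile(rng):
    """Noiseless phenotypes plus a profile derived from the true DAG
    (rho = 1 on edges, 0 elsewhere): the program recovers the true
    pattern and the exact gene-gene edge set."""
    for _ in range(5):
        dag = gd.random_dag(5, rng)
        sk = draw_sk_values(dag.genes, rng)
        data = gd.simulate_phenotypes(dag, sk, 0.0, seed=rng)
        und = {frozenset(e) for e in dag.gene_gene_edges()}
        rho = _profile(dag.genes, {
            p: 1.0 if frozenset(p) in und else 0.0
            for p in itertools.combinations(dag.genes, 2)})
        scores = build_class_scores(data)
        model = build_gi_genie(scores, rho, genes=dag.genes)
        sol, edges = solve_gi_genie(model, dag.genes)
        assert sol.pattern.classes == gd.pattern_from_dag(dag).classes
        gene_edges = frozenset(e for e in edges if e[1] != gd.REPORTER)
        assert gene_edges == dag.gene_gene_edges()


def test_raising_sparsity_penalty_never_adds_edges(rng):
    dag = gd.random_dag(4, rng)
    sk = draw_sk_values(dag.genes, rng)
    data = gd.simulate_phenotypes(dag, sk, 0.4, seed=13)
    rho = gd.gi_profile(data)
    scores = build_class_scores(data)
    counts = []
    for lp in (0.2, 0.5, 0.8, 1.0):
        w = GiGenieWeights(lambda_d=0.05, lambda_c=1.0, lambda_p=lp)
        model = build_gi_genie(scores, rho, w, genes=dag.genes)
        sol, _ = solve_gi_genie(model, dag.genes)
        counts.append(sum(sol.beta.values()))
    assert counts == sorted(counts, reverse=True)
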