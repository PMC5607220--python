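"""Sequential scalability (SEQSCA): subsampled estimation, aggregated.

The exact programs scale combinatorially with the number of genes, so for
large gene sets the estimator is run on many small random subsets and the
per-subset edge detections are aggregated into an empirical edge
*reliability matrix*: entry (i, j) is the fraction of iterations in which
genes i and j were co-sampled and an edge (either direction) was detected
between them.  The aggregate is a statistical statement about pairwise
interactions, not a valid DAG.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dag_core import REPORTER
from .genie_ilp import build_class_scores, build_genie, solve_genie
from .gi_genie_ilp import GiGenieWeights, build_gi_genie, solve_gi_genie
from .edge_policy import reconstruct_edges
from .interaction_model import (DEFAULT_REGISTRY, GiProfile, ModelRegistry,
                                PhenotypeData, gi_profile)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityMatrix:
    """Empirical edge probabilities with per-pair co-sampling counts.

    ``values[i, j]`` is defined only where ``counts[i, j] > 0``; uncovered
    pairs are reported as missing (NaN), never as 0.  Both matrices are
    symmetric with unused diagonals.
    """

    genes: Tuple[str, ...]
    values: np.ndarray
    counts: np.ndarray

    def value_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def count_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.genes)

    def coverage(self) -> float:
        n = len(self.genes)
        off = n * (n - 1) / 2
        covered = sum(
            self.counts[a, b] > 0
            for a, b in itertools.combinations(range(n), 2)
        )
        return covered / off if off else 1.0


def sample_subset(genes: Sequence[str], n_s: int,
                  rng: np.random.Generator) -> Tuple[str, ...]:
    """Uniform random subset of size ``n_s``, drawn without replacement.

    The subset preserves the master gene order, so within-subset pair
    indexing is consistent with the full set (kappa_i < kappa_j for i < j).
    """
    genes = tuple(genes)
    if not 2 <= n_s <= len(genes):
        raise ValueError(f"subset size {n_s} out of range 2..{len(genes)}")
    picked = rng.choice(len(genes), size=n_s, replace=False)
    return tuple(genes[k] for k in sorted(picked))


def _restrict(data: PhenotypeData, subset: Tuple[str, ...]) -> PhenotypeData:
    sk = {g: data.sk[g] for g in subset}
    dk = {(i, j): data.dk_value(i, j) for i, j in itertools.combinations(subset, 2)}
    return PhenotypeData(subset, sk, dk)


def _restrict_rho(rho: GiProfile, subset: Tuple[str, ...]) -> GiProfile:
    return GiProfile(subset, {
        (i, j): rho.get(i, j) for i, j in itertools.combinations(subset, 2)
    })


def estimate_subset_edges(data: PhenotypeData,
                          rho: Optional[GiProfile],
                          estimator: str,
                          weights: GiGenieWeights,
                          registry: ModelRegistry) -> frozenset:
    """Gene-gene edges of one subset estimate (reporter edges excluded)."""
    scores = build_class_scores(data, registry)
    if estimator == "genie":
        model = build_genie(scores, genes=data.genes)
        result = solve_genie(model, data.genes)
        edges = reconstruct_edges(result.pattern)
    elif estimator == "gi-genie":
        if rho is None:
            raise ValueError("gi-genie estimator requires a GI profile")
        model = build_gi_genie(scores, rho, weights, genes=data.genes)
        _, edges = solve_gi_genie(model, data.genes)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return frozenset(e for e in edges if e[1] != REPORTER)


def run_seqsca(data: PhenotypeData,
               rho: Optional[GiProfile] = None,
               s: int = 100,
               n_s: int = 6,
               estimator: str = "genie",
               weights: GiGenieWeights = GiGenieWeights(),
               registry: ModelRegistry = DEFAULT_REGISTRY,
               seed: int | np.random.Generator = 0,
               count_failed: bool = False) -> ReliabilityMatrix:
    """Run the subsampling loop and aggregate the reliability matrix.

    Per iteration: draw a subset, increment the co-sampling counts of all
    its pairs, estimate the subset DAG, and accumulate the symmetric 0/1
    gene-gene adjacency.  Finally each accumulated entry is divided by its
    count.  If the estimator fails on a subset the iteration is skipped
    and (by default) its count increments are rolled back.

    ``rho`` defaults to the profile computed from ``data`` when the
    gi-genie estimator is selected.
    """
    if s < 1:
        raise ValueError("number of iterations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genes = data.genes
    if estimator == "gi-genie" and rho is None:
        rho = gi_profile(data)
    n = len(genes)
    idx = {g: k for k, g in enumerate(genes)}
    acc = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    skipped = 0
    for _ in range(s):
        subset = sample_subset(genes, n_s, rng)
        sub_pairs = list(itertools.combinations(subset, 2))
        for i, j in sub_pairs:
            counts[idx[i], idx[j]] += 1
            counts[idx[j], idx[i]] += 1
        try:
            edges = estimate_subset_edges(
                _restrict(data, subset),
                _restrict_rho(rho, subset) if rho is not None else None,
                estimator, weights, registry)
        except Exception:  # solver failure: roll back this iteration
            logger.exception("SEQSCA iteration skipped (estimator failure)")
            skipped += 1
            if not count_failed:
                for i, j in sub_pairs:
                    counts[idx[i], idx[j]] -= 1
                    counts[idx[j], idx[i]] -= 1
            continue
        undirected = {frozenset(e) for e in edges}
        for i, j in sub_pairs:
            if frozenset((i, j)) in undirected:
                acc[idx[i], idx[j]] += 1
                acc[idx[j], idx[i]] += 1
    if skipped:
        logger.warning("SEQSCA: %d of %d iterations skipped", skipped, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    rel = ReliabilityMatrix(genes, values, counts)
    if rel.coverage() < 1.0:
        logger.warning("SEQSCA coverage incomplete: %.1f%% of pairs co-sampled",
                       100 * rel.coverage())
    return rel
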