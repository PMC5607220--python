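"""Phenotype models, mismatch score, synthetic data generator, GI profiles.

Phenotypes are colony-size-like fitness readouts on the log scale (log2
ratio to the unperturbed strain, wild type = 0; knockouts negative).
``R(i)`` is the single-knockout (SK) phenotype of gene ``i``; ``R(i,j)``
the double-knockout (DK) phenotype of the pair.  Each hierarchical
relationship class ``k`` predicts the DK phenotype through a model
``mu_k(R(i), R(j))``:

* class 1 (*i* linearly upstream of *j*): the double mutant phenocopies
  the downstream knockout, ``mu_1 = R(j)``;
* class 2: mirror, ``mu_2 = R(i)``;
* class 3 (independent): multiplicative fitness neutrality, which is
  additive on the log scale, ``mu_3 = R(i) + R(j)``;
* class 4 (*i* partially upstream of *j*): part of *i*'s effect is masked
  by *j*, part acts independently — the midpoint ``(mu_1 + mu_3)/2``;
* class 5: mirror of class 4.

The registry of models is injectable so that every downstream optimisation
is independent of this particular transcription.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Tuple

import numpy as np
from scipy import stats

from .dag_core import Dag, DagError, pattern_from_dag

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]
Model = Callable[[float, float], float]


# ---------------------------------------------------------------------------
# Model registry and mismatch score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelRegistry:
    """Five pure functions ``mu_k(R_i, R_j) -> float``, k = 1..5."""

    models: Tuple[Model, Model, Model, Model, Model]

    def mu(self, k: int, r_i: float, r_j: float) -> float:
        if not 1 <= k <= 5:
            raise ValueError(f"class must be in 1..5, got {k}")
        return self.models[k - 1](r_i, r_j)


DEFAULT_REGISTRY = ModelRegistry((
    lambda ri, rj: rj,                      # 1: i linearly upstream of j
    lambda ri, rj: ri,                      # 2: j linearly upstream of i
    lambda ri, rj: ri + rj,                 # 3: independent (log-additive)
    lambda ri, rj: rj + 0.5 * ri,           # 4: i partially upstream of j
    lambda ri, rj: ri + 0.5 * rj,           # 5: j partially upstream of i
))


def score(k: int, r_ij: float, r_i: float, r_j: float,
          registry: ModelRegistry = DEFAULT_REGISTRY) -> float:
    """Quadratic mismatch ``(R(i,j) - mu_k(R(i), R(j)))**2``."""
    return float((r_ij - registry.mu(k, r_i, r_j)) ** 2)


# ---------------------------------------------------------------------------
# Phenotype container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeData:
    """SK and DK phenotype tables over an ordered gene set.

    ``dk`` is keyed by canonical pairs (gene order of ``genes``) and must be
    complete: one value for every unordered pair.
    """

    genes: Tuple[str, ...]
    sk: Dict[str, float]
    dk: Dict[Pair, float]

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.sk]
        if missing:
            raise DagError(f"SK table misses genes {missing}")
        expected = set(itertools.combinations(self.genes, 2))
        if set(self.dk) != expected:
            bad = expected.symmetric_difference(self.dk)
            raise DagError(f"DK table pair mismatch, e.g. {sorted(bad)[:3]}")

    def dk_value(self, i: str, j: str) -> float:
        return self.dk[(i, j)] if (i, j) in self.dk else self.dk[(j, i)]


@dataclass(frozen=True)
class GiProfile:
    """Pearson GI-profile correlations, keyed by canonical pairs."""

    genes: Tuple[str, ...]
    rho: Dict[Pair, float]

    def get(self, i: str, j: str) -> float:
        return self.rho[(i, j)] if (i, j) in self.rho else self.rho[(j, i)]


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

def ideal_phenotypes(dag: Dag, sk_values: Dict[str, float],
                     registry: ModelRegistry = DEFAULT_REGISTRY) -> PhenotypeData:
    """Noise-free phenotypes implied by a ground-truth DAG."""
    pattern = pattern_from_dag(dag)
    dk = {
        (i, j): registry.mu(pattern.get(i, j), sk_values[i], sk_values[j])
        for i, j in itertools.combinations(dag.genes, 2)
    }
    return PhenotypeData(dag.genes, dict(sk_values), dk)


def simulate_phenotypes(dag: Dag, sk_values: Dict[str, float], sigma: float,
                        registry: ModelRegistry = DEFAULT_REGISTRY,
                        seed: int | np.random.Generator = 0) -> PhenotypeData:
    """Simulate noisy SK/DK phenotypes from a ground-truth DAG.

    The ideal DK value of pair ``(i, j)`` is ``mu_k*`` for the pair's true
    class ``k*``; independent zero-mean Gaussian noise of variance
    ``sigma**2`` corrupts every SK and DK entry.  Reproducible for a fixed
    integer seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ideal = ideal_phenotypes(dag, sk_values, registry)
    sk = {g: ideal.sk[g] + rng.normal(0.0, sigma) for g in dag.genes}
    dk = {p: v + rng.normal(0.0, sigma) for p, v in ideal.dk.items()}
    return PhenotypeData(dag.genes, sk, dk)


def draw_sk_values(genes: Iterable[str],
                   rng: np.random.Generator,
                   low: float = -4.5, high: float = -0.5) -> Dict[str, float]:
    """Draw generic SK phenotypes, uniform on [low, high].

    Values are log2 fitness defects: each knockout costs between half a
    doubling and 4.5 doublings of colony growth.  On this scale the five
    class models are separated by at least ``|R|/2 >= 0.25`` for every
    pair, the wrong-class mismatch scores range up to ``max(R)^2 ~ 20`` so
    that the benchmark weight ``lambda_d = 0.05`` scales them into [0, 1],
    and the continuous draw keeps the models pairwise distinct almost
    surely.
    """
    return {g: float(rng.uniform(low, high)) for g in genes}


def snr_to_sigma(snr: float, ideal: PhenotypeData) -> float:
    """Noise level for a target signal-to-noise ratio.

    SNR is defined as the variance ratio ``Var(ideal DK) / sigma**2`` over
    all pairs, which makes benchmark curves independent of the phenotype
    scale.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    var = float(np.var(list(ideal.dk.values())))
    return float(np.sqrt(var / snr))


# ---------------------------------------------------------------------------
# GI profiles
# ---------------------------------------------------------------------------

def gi_profile(data: PhenotypeData, exclude_pair_entries: bool = True,
               profile: str = "epsilon",
               registry: ModelRegistry = DEFAULT_REGISTRY) -> GiProfile:
    """Pearson correlation of the GI profiles of every gene pair.

    The default profile entry for gene ``i`` against partner ``l`` is the
    interaction score ``eps(i, l) = R(i, l) - mu_3(R(i), R(l))``, the
    deviation of the double knockout from the multiplicative independence
    expectation — the standard GI-profile construction in quantitative
    interaction screens.  Correlating raw DK values (``profile="raw"``) is
    available but degenerate: for non-interacting genes the raw profiles
    are both proportional to the partner SK values, so their correlation
    tends to 1 regardless of any interaction.

    By default the two genes of the pair are excluded from the partner
    set: self-knockouts ``R(i, i)`` are unmeasured and the pair's own
    entries would correlate the pair with itself.  Zero-variance profiles
    yield rho = 0 with a logged warning.
    """
    if profile not in ("epsilon", "raw"):
        raise ValueError(f"unknown profile dialect {profile!r}")

    def entry(a: str, l: str) -> float:
        v = data.dk_value(a, l)
        if profile == "epsilon":
            v -= registry.mu(3, data.sk[a], data.sk[l])
        return v

    genes = data.genes
    rho: Dict[Pair, float] = {}
    flat_pairs: list = []
    for i, j in itertools.combinations(genes, 2):
        if exclude_pair_entries:
            partners = [l for l in genes if l not in (i, j)]
            vi = np.array([entry(i, l) for l in partners])
            vj = np.array([entry(j, l) for l in partners])
        else:
            # literal dialect: keep the pair's own DK entry, align R(i,j)
            # of profile i with R(j,i) (= R(i,j)) of profile j; self
            # entries R(i,i) are unmeasured and always dropped
            partners = [l for l in genes if l not in (i, j)] + [j]
            vi = np.array([entry(i, l) for l in partners])
            vj = np.array([entry(j, l if l != j else i) for l in partners])
        if len(partners) < 2 or np.ptp(vi) == 0 or np.ptp(vj) == 0:
            flat_pairs.append((i, j))
            rho[(i, j)] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = stats.pearsonr(vi, vj).statistic
        rho[(i, j)] = float(r) if np.isfinite(r) else 0.0
    if flat_pairs:
        logger.warning("zero-variance GI profile for %d pair(s) (e.g. %s); rho set to 0",
                       len(flat_pairs), flat_pairs[0])
    return GiProfile(genes, rho)
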