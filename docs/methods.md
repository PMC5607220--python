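# Methods

## Problem and model

A genetic-interaction map over genes `G = {g1, …, gG}` is a rooted
directed acyclic graph: every gene influences the measured cell function
only through directed paths terminating at an artificial reporter node
`R`, and no gene repeats on a path. The map cannot be observed directly;
what is measured are single-knockout (SK) phenotypes `R(i)` and
double-knockout (DK) phenotypes `R(i,j)`.

Every ordered gene pair falls into exactly one of five hierarchical
relationship classes, defined by path quantifiers over the sets `P_i` of
all paths from `i` to `R`:

| k | relation | condition |
|---|----------|-----------|
| 1 | `i` linearly upstream of `j` | every path of `i` passes `j` |
| 2 | `j` linearly upstream of `i` | mirror of 1 |
| 3 | independent | neither gene lies on any path of the other |
| 4 | `i` partially upstream of `j` | some path of `i` avoids `j`, and some path of `i` contains a full path of `j` |
| 5 | `j` partially upstream of `i` | mirror of 4 |

In a DAG these conditions are equivalent to a reachability
characterisation used internally for speed (`i` reaches `j` plus whether
`i` reaches `R` avoiding `j`); the equivalence is proved in the
`classify_pair_fast` docstring and tested against the literal quantifier
evaluation on every 4-gene DAG.

## Phenotype models

Class `k` predicts the DK phenotype through `mu_k(R(i), R(j))`. Defaults
operate on log2 fitness (colony-size ratio to the unperturbed strain;
wild type 0, knockouts negative):

    mu_1 = R(j)            downstream knockout masks the upstream one
    mu_2 = R(i)
    mu_3 = R(i) + R(j)     multiplicative fitness neutrality (log-additive)
    mu_4 = R(j) + R(i)/2   half of i's effect masked by j
    mu_5 = R(i) + R(j)/2

The linear-pathway models and the multiplicative null are the standard
epistasis conventions; the partial-upstream models interpolate midway
between full masking and independence, the simplest one-parameter-free
choice that keeps all five models pairwise distinct for generic SK
values. The registry is injectable everywhere, so the optimisation layer
never depends on this particular choice.

The mismatch score of class `k` for a pair is the squared residual
`s_k(i,j) = (R(i,j) − mu_k(R(i),R(j)))²`.

## The exact programs

**Pattern detection** minimises the total mismatch over binary
class-selection variables `alpha_k(i,j)` (exactly one per pair), subject
to a topology constraint set `L` that admits precisely the class
patterns realisable by a valid DAG. `L` consists of per-triple
implications: conditioning on the classes of `(i,j)` and `(i,l)`
restricts the class of `(j,l)` to an allowed set, as one linear
inequality per non-vacuous combination,

    sum_{z in allowed(x,y)} alpha_z(j,l) >= alpha_x(i,j) + alpha_y(i,l) − 1.

The allowed-set table is *derived*, not transcribed: a class triple is
realisable inside any DAG iff it is realisable on three genes (classes
depend only on path membership of the third gene), so the table is
computed once by exhaustive enumeration of all 79 rooted 3-gene DAGs and
cached. The derivation reproduces the five classical class-1
implications exactly and yields 21 non-vacuous combinations per triple
(family decomposition 5+4+4+4+4). Soundness (no realisable pattern cut)
and completeness (no spurious pattern admitted: at four genes the
1207 triple-feasible patterns coincide with the 1207 realisable ones)
are asserted against independent exhaustive enumeration in the test
suite. Prior knowledge enters as fixing equalities `alpha_k0(i0,j0)=1`.

**Joint detection** adds one undirected edge-selection binary
`beta(i,j)` per pair and auxiliary binaries `z_l(i,j)` (one per pair and
third gene) and minimises

    lambda_d * (mismatch term) − lambda_c * sum rho(i,j) beta(i,j)
                               + lambda_p * sum beta(i,j),

where `rho` is the GI-profile correlation. An edge is profitable exactly
when `lambda_c * rho > lambda_p`, i.e. above the threshold
`lambda_p / lambda_c`; the profile-only detections `q(i,j)` use the same
threshold. `z_l(i,j) = 1` certifies that gene `l` does not block the
edge between `i` and `j` under the sparse-edge rules below; coupling
inequalities force the certificates, the aggregation constraint
`|G| − 2 + beta >= 1 + sum_l z_l` converts "no gene blocks" into
`beta = 1`, a blocking gene forces `beta = 0`, and independent pairs
never carry an edge. For pairs with `q = 1` the class-4/5 blocking rules
relax to their linear cores, so optional edges strongly supported by the
profile are admitted. Two logically equivalent emissions exist: the
default expands the class-4/5 blocker disjunctions into one inequality
per blocker combination (18 inequalities per pair and third gene), the
compact form keeps the summed disjunctions (12); equivalence under the
one-class-per-pair structure is tested by brute force.

Both programs are solved to proven optimality by branch-and-bound
(HiGHS through `scipy.optimize.milp`, zero relative MIP gap).
Determinism comes from the fixed variable ordering; among multiple
optima the solver's incumbent is returned. Integrality is accepted at
1e−6 and re-checked after rounding.

**Model-size convention.** Reported constraint counts are one
binary-domain constraint per declared variable plus one per linear
constraint. For ten genes this gives 225 binaries / 270 constraints for
the topology-free classifier, 225 / 2790 for the full pattern program
(270 + 120 triples × 21), and 630 / 9765 for the joint program
(630 domain + 45 multiple-choice + 2520 topology + 45 independence
exclusions + 45 aggregations + 360 × 18 coupling). The profile-threshold
baseline is reported as 270 binaries (225 class-selection + 45 edge
indicators) and 270 constraints; its edge indicators are data-determined
rather than free decisions, so they contribute no domain constraints.

## Sparse edge reconstruction

A class pattern is a non-unique fingerprint: class-4/5 assignments lose
the number of reporter-bound bypass paths, so several DAGs share one
pattern. Following the sparsity convention for interaction maps, the
reconstruction emits only necessary edges:

* E1: `i -> j` when class(i,j)=1 and no gene sits linearly between them;
* E2: `i -> j` when class(i,j)=4 and no gene is downstream of `i`
  (class 1 or 4) while upstream of `j` (class 2 or 5);
* E3/E4: mirrors; ER: `i -> R` when nothing is linearly downstream of
  `i` and the class-4 partner set `M_i` is empty or contains no two
  mutually independent genes (`M_i'` empty).

These pairwise rules are necessary but not sufficient for an exact
round trip: they cannot see *coalitions* of intermediates. Two failure
modes exist (both witnessed exhaustively at four genes): every
independent outlet of a gene may be routed through a single
intermediate, so dropping each individually-optional edge jointly
destroys a class-4 relation; and an edge may be jointly covered by two
partial intermediates although neither blocks it alone. The
reconstruction therefore completes the rules with two exact,
deterministic steps: a reporter edge is granted to any gene whose
partial-upstream independence the detected edges fail to carry (one
edge restores all such relations and cannot disturb any other pair for
a gene without linearly-downstream partners), and edges whose removal
provably leaves the re-derived pattern unchanged are greedily pruned in
canonical order. With the completion, reconstruction over every valid
3- and 4-gene DAG and 100 random 5-gene DAGs returns a valid DAG with
the identical pattern and never more edges than the source DAG. Both
steps cost a handful of reachability checks per gene and edge, so the
policy remains linear-algebra-free and fast at subsampling sizes.

For unconstrained (per-pair argmin) patterns the reconstruction may be
cyclic or disconnected; it is still computed and the validity report is
returned with the graph when requested.

## Synthetic data

The generator draws a ground-truth DAG, SK phenotypes, and produces
ideal DK values from the pair's true class model, then corrupts every SK
and DK entry with independent zero-mean Gaussian noise of variance
`sigma²`.

* SK values: uniform on [−4.5, −0.5] log2 units — each knockout costs
  between half and 4.5 doublings of growth. On this scale the class
  models are separated by at least `|R(i)|/2 >= 0.25` for every pair and
  the wrong-class mismatch scores range up to ≈20, so the benchmark
  weight `lambda_d = 0.05` scales the score term into [0, 1], the
  documented role of that constant (the knockout term and the
  correlation term then compete on a common scale).
* DAG sampler: uniform over the exhaustive enumeration up to five genes
  (weighted two-stage draw); for larger sets, a random topological order
  with Bernoulli(0.3) edges, sinks wired to the reporter.
* SNR is the variance ratio `Var(ideal DK) / sigma²`, which makes noise
  levels comparable across phenotype scales; the benchmark grid spans
  1–100 (0–20 dB).
* GI profiles correlate *interaction scores*
  `eps(i,l) = R(i,l) − mu_3(R(i),R(l))` over all partners excluding the
  pair itself, the standard construction in quantitative interaction
  screens. Correlating raw DK vectors is available as a switch but is
  degenerate by construction: under any separable independence model the
  raw profiles of two non-interacting genes are both monotone images of
  the partner SK values, so their correlation approaches 1 as noise
  vanishes, for interacting and non-interacting pairs alike.
* One master seed drives DAG, SK, noise and subsampling draws.

What passing synthetic tests do *not* show: real screens have replicate
structure, batch effects, plate normalisation artefacts and missing
pairs, none of which the generator emulates; with few genes the profile
vectors are short (G−2 entries), so profile correlations are noisy and
the profile-guided program is at its least informative — benchmark
orderings, not absolute error levels, are the meaningful readout.

## Subsampled ensemble estimation

For large gene sets the exact programs are run on `S` random subsets of
size `N_S` (uniform, without replacement). Each subset estimate is
translated into a symmetric 0/1 gene-gene adjacency (reporter edges
excluded — reliability is defined over gene pairs), co-sampling counts
`n_ij` are incremented per iteration, and the final reliability value is
the accumulated adjacency divided by `n_ij` — algebraically the per-pair
mean over co-sampled iterations, which the tests assert against an
independent replay. Pairs never co-sampled are reported as missing, not
zero, and incomplete coverage triggers a warning. A failed subset solve
is skipped with its count increments rolled back (switchable). The
aggregate is a statistical statement about pairwise interaction, not a
valid DAG.

## Evaluation

Directed-edge recovery is scored by the false-detection rate
`|detected \ true| / |true|` and the miss rate `|true \ detected| / |true|`,
both normalised by the true edge count; reporter edges are compared like
any other edge, and the profile-threshold baseline receives reporter
edges from the reporter rule applied to its inferred pattern so all
methods emit comparable edge sets. The acceptance ratio of a reliability
matrix is the fraction of pairs at reliability ≥ 1−eps present in a
reference interaction set (undefined, reported as missing, when nothing
reaches significance). Baselines: the per-pair least-mismatch classifier
(topology constraints dropped; ties to the smallest class) and profile
thresholding at `t_corr` with orientation from the least-mismatch class.

The benchmark harness sweeps the SNR grid at 20 replicates and six genes
with the published weights (`lambda_d = 0.05`, `lambda_c = 1`,
`lambda_p = 0.8`, `t_corr = 0.6`). These sizes keep the full sweep in
minutes while leaving the method ordering stable; figure-level claims
are asserted as orderings, never as absolute curve values.

## Numerical and degenerate-input choices

* Zero-variance profile vectors (e.g. a gene with no interactions at
  zero noise) get `rho = 0` with a logged warning.
* Score ties in the unconstrained classifier break to the smallest
  class index.
* Contradictory priors build fine and surface as solver infeasibility
  naming the model.
* `p_ed`/`p_mis` raise on an empty true edge set (a valid DAG always has
  at least the reporter edges, so this only guards misuse).
* The aggregation constraint of the joint program requires at least
  three genes; two-gene instances are rejected at build time.
* The benchmark harness caps each exact solve at 60 s of wall clock; a
  timed-out fit is recorded as missing for that method and noise level,
  never silently dropped or substituted. Occasional joint-program
  instances sit on near-flat objective plateaus where branch-and-bound
  proof takes tens of seconds; the cap bounds the sweep without
  affecting solved cells, which remain proven optima.

## Known limitations

* The exhaustive DAG enumeration (the oracle behind the constraint
  tables and the uniform sampler) caps at five genes; beyond that the
  Bernoulli sampler is not uniform over DAGs.
* The joint program's profile reward can re-classify pairs whose
  mismatch margin is below `lambda_p/lambda_d` score units; with short
  profiles this inflates its false-detection rate relative to the
  pattern-only program at high SNR.
* The reconstruction returns one sparsest representative; enumerating
  all DAGs consistent with a pattern is out of scope.
* Real-data workflows (replicates, normalisation, database lookups) are
  out of scope; inputs are assumed to be one clean value per knockout.
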