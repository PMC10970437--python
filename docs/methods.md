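# Methods

This note documents the models implemented in `drgnet`, the conventions and
defaults chosen where the underlying methodology leaves room, what the
synthetic-data generator does and does not emulate, and known limitations.

## Varying-coefficient network estimation

For each target gene *l* and each cell line *α* (sensitivity value
*m_α*), the coefficient vector β_l(m_α) over all other genes minimises

```
(1/2) Σ_i K(m_i − m_α | b) (y_il − β'x_i)²
    + λ Σ_j [ (1/2)(1−δ) β_j² + δ w_j |β_j| ],      K(d|b) = exp(−d²/b).
```

Conventions and defaults:

- **Kernel weights are used as written** — they are not normalised to sum
  to one. The weight of cell line *i* is its raw kernel value.
- **Bandwidth** `b` (units: squared sensitivity). Default `"auto"`: solved
  by log-space bisection so the mean effective sample size
  Σ_i K(m_i − m_α | b), averaged over α, equals one third of the panel
  (`ess_fraction = 1/3`). One third balances locality in *m* against the
  variance of a sparse regression fit; because the kernel depends on
  distance only through d²/b, the selected bandwidth scales with the square
  of the spread of the sensitivity values. Demanding the full panel
  (fraction 1) is only attainable in the infinite-bandwidth limit and
  returns a capped value with a warning.
- **Penalty mix** δ = 0.5 (equal ridge/lasso weighting), fixed across
  targets.
- **Recursive (adaptive) weights**: pass 1 uses w_j = 1; pass k+1 uses
  w_j = 1/(|β̂_j^(k)| + 1e−6). Default two passes; the second pass
  de-biases surviving edges and prunes noise edges.
- **λ selection** per (target, cell line): kernel-weighted BIC
  `n_eff · log(RSS_w / n_eff) + log(n_eff) · df` with n_eff = Σ_i K_i,
  RSS_w the kernel-weighted residual sum of squares and df the number of
  nonzero coefficients, minimised over a geometric grid of 20 values from
  the KKT threshold λ_max = max_j |Σ_i K_i x_ij y_il| / (δ w_j) down to
  λ_max·10⁻³ (ties resolved toward the sparser, larger-λ fit). A
  kernel-weighted K-fold cross-validation rule is available
  (`selection_rule="weighted-cv"`).
- **Solver**: cyclic coordinate descent on the Gram form of the objective
  with warm starts along the λ path and glmnet-style active-set iteration;
  convergence when the largest coefficient change in a sweep falls below
  1e−8 (cap 10⁴ sweeps). Coordinates with nonpositive curvature
  (zero weighted variance) are pinned at zero. Tests certify solutions via
  the subgradient (KKT) conditions rather than the iteration count.
- **Standardisation**: genes are z-scored before fitting by default
  (coefficients then refer to standardised expression); raw-scale fitting
  is available with `standardize=False`. No intercept is fitted —
  standardisation removes gene means.
- **Self-regulation** is structurally excluded (β_ll ≡ 0); every gene acts
  as both potential regulator and target, matching an analysis carried out
  on a single variance-filtered gene set.
- Two cell lines with equal sensitivity values receive identical networks:
  the estimate depends on the cell line only through its *m*.

## Screening

- **Variance filter**: keep the k genes of largest sample variance
  (ddof = 1); ties broken lexicographically by gene id; surviving genes
  keep their original column order.
- **Extreme groups**: the k largest sensitivity values form the sensitive
  group, the k smallest the resistant group; boundary ties are broken by
  cell-line id (ascending ids sort with ascending values), which keeps the
  groups disjoint whenever 2k ≤ n.
- **Top edges**: every directed edge is ranked by the **median across
  networks of its absolute coefficient**, consistent with reporting edge
  weights as medians over a network collection; edges with zero median are
  treated as non-edges and excluded from the percentage base. The top
  ⌈fraction·E⌉ edges are kept (default fraction 1%). The alternative
  reading — union of each network's own top fraction — is available with
  `per_network=True`. All ties break by (regulator, target) id order.
- **Subnetworks**: connected components of the undirected view of the edge
  set, each carrying its induced directed edges; ordered by decreasing gene
  count, then smallest member gene id; labelled S1, S2, …
- **Medians** of an even number of values are midpoints of the two central
  values. Median edge summaries report sign separately from magnitude
  (positive/negative edge-colour convention).

## Differential regulation statistic (DCS)

For each randomly matched sensitive/resistant pair, restricted to a
subnetwork's genes:

1. edge weights w_ij = (|β_ij| + |β_ji|)/2 (symmetric, nonnegative, zero
   diagonal);
2. adjacency difference d_ij = (½ |sign(w^S)(w^S)² − sign(w^R)(w^R)²|)^γ.
   The γ exponent applies to the **whole** half-absolute-difference term;
   at the default γ = 1 this choice is immaterial. The sign factor is
   vacuous for nonnegative edge weights but makes the same code serve the
   signed-correlation (DiffCoEx) variant;
3. topological-overlap dissimilarity
   t_ij = 1 − (Σ_k d_ik d_jk + d_ij) / (min(Σ_k d_ik, Σ_k d_jk) + 1 − d_ij),
   with t_ii := 1 and d_ii := 0. Because the diagonal of D is zero, the
   k = i and k = j numerator terms and the self terms of the row sums
   vanish identically, so the "sum over all k" and "sum excluding i, j"
   readings coincide; only one implementation is needed;
4. Ave[T(α)] = the mean of all p² entries of T(α) (diagonal included, as
   the normalisation by p² implies; an off-diagonal-only mode is
   available);
5. DCS = mean of Ave[T(α)] over pairs.

**Normalisation.** Regression-coefficient edge weights are unbounded
(unlike correlations), which can push the dissimilarity ratio outside
[0, 1]. By default each pair's two weight matrices are divided by the
maximum entry over the pair, bounding d by (½)^γ; raw mode is available
(`normalize=False`).

**Identity**: if every sensitive network equals its paired resistant
network, D = 0, T ≡ 1 and DCS = 1 exactly.

**Permutation test.** Each permutation reshuffles the pooled 2k cell lines
into two groups and draws a fresh matching; DCS is recomputed from the
already-estimated networks. Two tail conventions are shipped:

- `small-is-extreme` (default): p = Σ I(DCS_pm ≤ DCS)/T. Small
  dissimilarity entries flag concerted rewiring, so small DCS is the
  interesting tail;
- `literal`: p = Σ I(DCS ≤ DCS_pm)/T, the printed form of the original
  formulation. The two conventions are complementary (they overlap exactly
  at ties), and the literal form makes strongly rewired subnetworks yield
  *large* p, which contradicts the accompanying decision rule p < τ; the
  default inverts the indicator to the logically consistent direction while
  the literal form is retained for fidelity.

No add-one correction is applied by default (p = b/T); the finite-sample
(b+1)/(T+1) version is available with `plus_one=True`. Each subnetwork
draws from an RNG stream seeded by the global seed and a CRC-32 hash of its
sorted member genes, so results do not depend on the order subnetworks are
supplied. Defaults follow the analysis settings γ = 1, τ = 0.05, T = 500.
Raw p-values are compared against τ without multiple-testing correction by
default; Benjamini–Hochberg is available in the pipeline configuration.

## Synthetic data

The generator emulates the assumed data-generating process: a planted
directed acyclic network whose coefficients vary smoothly with the
sensitivity value. Sensitivity values are uniform over a configurable range
(default [−2, 2]; a bimodal option mimics screens restricted to extreme
responders). Expression is forward-simulated in topological order: root
genes are i.i.d. standard normal; every other gene is the coefficient-
weighted sum of its regulators plus Gaussian noise (default sd 0.3). Edge
coefficients follow per-edge profiles — constant, logistic (default:
midpoint at the median sensitivity, steepness 8/range), or step — between a
resistant-end and a sensitive-end value. Optional gene modules plant
disjoint connected subnetworks (spanning path along the topological order
plus random extra edges), with designated modules receiving differential
profiles; this is the ground truth used by the recovery studies. The null
generator flattens every profile to the midpoint of its end values, so the
coefficient tensor is identical across cell lines.

Not emulated: count-based sequencing noise, batch effects, missing values,
feedback loops (the truth is a DAG by construction so that forward
simulation is well defined — the estimator itself imposes no acyclicity),
and the distributional quirks of real CCLE expression. Passing recovery
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not performance on real panels.

## Simulation studies and problem sizes

The replicated studies in `drgnet.evaluation` (also run by
`scripts/acceptance.py`) use desk-scale conditions: null calibration at
p = 15 genes, n = 120 cell lines, 20 planted edges, 30 extreme cell lines
per end, T = 99 permutations, 200 replicates; planted-module recovery at
n = 200, three 5-gene modules, 50 extremes per end, T = 500, 50
replicates; estimator recovery at p = 20, n = 300. Extreme groups cover one
quarter of the panel at each end at these scales. The full-panel analysis
(1000 genes, hundreds of networks) is the same code path at larger scale
parameters.

## Known limitations

**The permutation reference is anti-conservative for kernel-smoothed
networks.** The estimated network at m_α is a deterministic, smooth
function of m_α given the data: networks at nearby sensitivity values share
kernel weight and are therefore similar *even when the true coefficients do
not vary at all*. The observed design always pairs cell lines from opposite
extremes of the sensitivity axis, whereas permuted designs mix, frequently
pairing cell lines with nearby sensitivity values whose networks are
similar by construction. Under the no-differential-structure null the
observed DCS is therefore systematically smaller than the permuted DCS, and
the `small-is-extreme` p-values concentrate near zero (measured rejection
rate ≈ 1.0 at nominal τ = 0.05 in the null calibration study; the
`literal` tail concentrates near one and essentially never rejects). A
control experiment in the test suite confirms that the permutation
machinery is exactly calibrated when the input networks are genuinely
exchangeable — the miscalibration is a structural property of combining
kernel-smoothed per-cell-line networks with a label-permutation null, not
an implementation artefact. Practical consequences:

- permutation p-values should be read as *relative* evidence for ranking
  subnetworks, not as calibrated type-I-error statements;
- the observed DCS (smaller = more rewired) is the more interpretable
  quantity; in the planted-module study the differential module has the
  lowest DCS in ≈ 96% of replicates while every module's p-value saturates
  at zero;
- a calibrated test would require a null reference that preserves the
  smooth dependence of networks on the sensitivity value (e.g. rotation or
  circular-shift nulls on the sensitivity axis, or re-estimating networks
  under permuted sensitivity assignments), which changes the method and is
  out of scope here.

Other limitations: exact reproduction of any specific published full-panel
analysis requires that analysis's data release and tuning constants
(bandwidth, λ, δ), which are not recoverable from the method description;
the estimator assumes linear regulatory effects and Gaussian-ish noise on
(log-scale) expression; and the screening step conditions the tested
subnetworks on the resistant networks, so the subsequent tests are not
independent of the screen.
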