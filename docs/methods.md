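# Methods

## Problem setting

An undirected, unweighted simple graph `G = (V, E)` with `n = |V|` nodes is
observed through its symmetric 0/1 adjacency matrix `A` (zero diagonal). A
fraction of the edges is hidden: `E` is split uniformly at random into a
training set (kept in `A`) and a probe set (hidden). A link predictor
assigns a score to every unobserved non-self pair; good predictors rank
probe edges above pairs that are absent from the full graph.

## The joint factorization model

Plain NMF approximates `A ≈ W·H` with non-negative factors, and scores
pairs by the reconstruction. The joint model adds a second, auxiliary
similarity matrix `S` (node-by-node, symmetric, non-negative) and forces
both reconstructions through a **shared basis** `W`:

    Q(W, H1, H2) = ||A − W·H1||²_F + α·||S − W·H2||²_F
                   + β·(||H1||²_F + ||H2||²_F),    W, H1, H2 ≥ 0.

The shared `W` maps topology and auxiliary information into one latent
feature space, so attribute communities can fill in structure that edge
sparsity removed. `Q` is non-convex; a local minimum is reached by
multiplicative updates (one Gauss–Seidel sweep updates `W`, then `H1`, then
`H2`, each using the freshest factors):

    W  ← W  ∘ (A·H1ᵀ + α·S·H2ᵀ) ⊘ (W·H1·H1ᵀ + α·W·H2·H2ᵀ)
    H1 ← H1 ∘ (Wᵀ·A)            ⊘ (Wᵀ·W·H1 + β·H1)
    H2 ← H2 ∘ (α·Wᵀ·S)          ⊘ (α·Wᵀ·W·H2 + β·H2)

These rules preserve non-negativity and, empirically across the test
suite's randomized instances, never increase `Q` by more than 1e−8
relative per sweep. Iteration stops when the relative objective change
drops below `rel_tol` (default 1e−6) or after `max_iter` sweeps (default
500); the first sweep always runs. Link scores are `(W·H1 + (W·H1)ᵀ)/2` —
the reconstruction is not exactly symmetric even though `A` is, and ranking
needs one score per unordered pair. Scores are ranked only over the
candidate mask (unobserved, non-self pairs of the training graph).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | `min(20, n/5)` | latent dimension; must stay well below `n/2` (warning otherwise). Automatic rank selection is out of scope; the default is conservative and overridable. |
| `alpha` | 4 | weight of the auxiliary residual; 0 ignores `S` entirely. |
| `beta` | 32 | ridge penalty on `H1`, `H2` against overfitting. |
| `rel_tol` | 1e−6 | relative objective-change stopping threshold. |
| `max_iter` | 500 | sweep cap. |
| `eps` | 1e−10 | elementwise floor on update denominators. |
| `random_state` | 0 | seed for the uniform (0, 1] factor initialization. |

The α = 4, β = 32 defaults sit in the stable region of the sensitivity
sweeps the `sensitivity_sweep` harness reproduces at small scale; predictive
quality is fairly flat around them.

### Numerical choices

- **Denominator guard.** Denominators are floored at `eps = 1e−10`
  (`max(den, eps)`) rather than shifted by adding `eps`. Flooring leaves
  exact fixed points untouched: when `A = W·H1`, `S = W·H2` and β = 0, a
  sweep moves no entry by more than 1e−12, whereas an additive guard would
  perturb every entry by ~`eps/den`. Zero denominators (which pair with
  zero numerators under these rules) are equally protected.
- **Initialization.** All factor entries i.i.d. uniform on (0, 1] — strictly
  positive, so no entry is spuriously frozen at zero by the multiplicative
  rule. A zero entry stays zero forever by construction; that is used by the
  reduction identity below, not fought.
- **Reduction.** With α = β = 0 and a shared initialization, the A-side
  factors evolve exactly as plain NMF (Lee–Seung updates); the test suite
  checks score agreement to 1e−10. `H2` collapses to zero after one sweep
  and is inert.
- **Convergence measure.** The relative criterion is evaluated on the
  model's own objective (joint `Q` or the plain Frobenius residual).

## Auxiliary similarity inputs

**External (attributes).** Attributes are non-negative numeric columns
(binary indicators or coded values). Each column is divided by its sum, so
heterogeneously scaled attributes contribute comparably; then pairwise node
similarity is computed — cosine by default (the variant used throughout the
experiments), with Euclidean `1/(1 + d)` and Pearson (negatives clipped to
0) as alternatives. All-zero attribute vectors get similarity 0 everywhere,
keeping `S` finite and non-negative. The `1/(1+d)` transform for Euclidean
and clipping (rather than shift-rescaling) for Pearson are this package's
choices — bounded, monotone, and non-negative as the factorization
requires.

**Internal (structure).** Any of CN, Salton, Jaccard, RA, AA, Katz, ACT
computed **on the training graph only**. AA uses the natural logarithm (the
dominant convention). Katz is computed by a direct linear solve of
`(I − θA)X = I` with divergence detection at `θ·λ_max ≥ 1`; the convergent
power series is kept as a test oracle only. ACT uses the Moore–Penrose
pseudo-inverse of the Laplacian, mapping non-finite or zero-denominator
scores to 0. Index matrices entering the factorization are rescaled by
their global maximum into [0, 1] so their range is comparable to the 0/1
adjacency (a flag disables the rescaling); diagonals are zeroed since
self-links are never candidates.

Combination modes: `A+S` (adjacency + attribute similarity), `A+Sim`
(adjacency + structural index — usable without attributes), and `Sim+S`
(the structural index replaces adjacency as the first factor target).

## Evaluation protocol

- **Splits.** Training size is `round(f·|E|)` (half-up, for cross-platform
  determinism), sampled without replacement; the training graph keeps all
  nodes. Splits are not constrained to keep the graph connected.
- **AUC.** `(n′ + 0.5·n″)/n` over comparisons of a probe-edge score against
  a nonexistent-pair score. Nonexistent pairs are drawn from the complement
  of the **full** graph's edge set, so probe links are never counted as
  nonexistent. Exhaustive enumeration is used while
  `|probe| × |nonexistent| ≤ 1e6`, otherwise 1e5 sampled comparisons with
  replacement. For i.i.d. random scores the expected AUC is 0.5, the null
  calibration the acceptance script recomputes.
- **Precision@L.** Candidates ranked by descending score, ties broken by a
  seeded random shuffle (deterministic, no index bias); precision is the
  fraction of the top L (default 100) that are probe edges.
- **Harness.** `run_experiment` derives one split seed per
  (fraction, repetition) from the master seed and scores every method on
  the same split — paired comparisons across methods. Defaults: fractions
  0.9 … 0.2, 100 repetitions.

## Synthetic data

`generate_attributed_network` plants a partition: `c` communities of
near-equal size (remainder to the first ones), edge probability `p_in`
within and `p_out` between; each community owns a disjoint block of
`⌈m/c⌉` binary attributes, and each node copies its community template with
independent bit-flip probability `attr_noise`. Defaults: n = 200, c = 4,
p_in = 0.25, p_out = 0.02, m = 40, noise = 0.1 — communities strong enough
that attribute similarity is genuinely informative of links (checked with a
3σ margin in the tests) while the whole suite stays fast. Binary attributes
mirror the word-vector style of web-page benchmarks and make homophily
strength a single parameter.

What the generator does **not** emulate: heavy-tailed degree distributions,
overlapping or nested communities, attribute columns of wildly different
cardinality, and disassortative regimes. Passing tests therefore show the
machinery is correct and that the model exploits homophily when present —
not that it wins on any particular real network.

`generate_low_rank_graph` keeps the top `round(density·n_pairs)` entries of
a random non-negative rank-k Gram matrix as edges, giving near-low-rank
adjacency structure (exactly nested neighbourhoods at k = 1) for
reconstruction tests.

## Problem sizes used in checks

The test suite and acceptance script run entirely on generated data:
oracle-equivalence checks on graphs of ≤ 15 nodes, monotonicity over 100
random instances with n ≤ 60 and k ≤ 8, and the signal-recovery and
calibration studies on the 200-node default scenario with 20–100
repetitions. These sizes give stable statistics (standard errors on mean
AUC around 0.005) while keeping a full run under a minute of CPU for the
unit suite.

## Known limitations

- Directed, weighted and multigraph networks are unsupported.
- The latent dimension `k` is user-set; no automatic rank selection.
- The objective is non-convex: different seeds reach different local
  minima, which is why evaluation averages over repeated seeded runs.
- Dense `n × n` linear algebra throughout: fine to a few thousand nodes,
  not intended for very large networks.
- Katz with the conventional θ = 0.1 diverges on graphs whose spectral
  radius exceeds 10; the implementation refuses with an explicit error
  rather than returning a meaningless matrix.
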