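# Methods

## Model

An undirected simple graph on `n` nodes is encoded by its symmetric 0/1
adjacency matrix `A` (zero diagonal).  Node attributes, when present, form a
non-negative `m × n` matrix `B` with attributes in rows and nodes in
columns; each node's attribute vector (a column) is L1-normalized, so all
entries lie in [0, 1] and nodes with many attributes do not dominate the
reconstruction term merely by mass.  Storing `B` nodes-in-columns is what
lets the two coefficient matrices `V` and `V_B` — and the consensus matrix
`V*` — share the `k × n` node-embedding orientation.

The factorization model and objective are

    J(U, V, U_B, V_B, V*) =
        ‖A − U V‖²_F + ‖B − U_B V_B‖²_F
        + λ ‖Q V − V*‖²_F + μ ‖Q_B V_B − V*‖²_F,     all factors ≥ 0,

with `Q = diag(column sums of U)` and `Q_B = diag(column sums of U_B)`.
`Q` and `Q_B` are functions of the base matrices, not free variables: they
re-express each coefficient matrix against column-normalized bases
(`U V = (U Q⁻¹)(Q V)`), which removes the arbitrary relative scaling
between the topology and attribute factorizations before the consensus
penalty compares them.  The code recomputes them from the current column
sums wherever J or its gradients are evaluated.

Assumptions worth stating: the graph is unweighted and undirected; the
latent structure relevant for missing links is low-rank and non-negative
(parts-based, community-like); attributes are non-negative and carry signal
about the same latent structure — the consensus penalty is only useful when
topology and attributes agree.

## Optimization

J is minimized by block coordinate descent with multiplicative updates.
Writing `q_m` for the m-th column sum of `U`, `s_m = Σ_j V²_mj`,
`r_m = Σ_j V*_mj V_mj` (and starred/`B` analogues), one cycle is:

1. `U_lm ← U_lm · [(A Vᵀ)_lm + λ r_m] / [(U V Vᵀ)_lm + λ s_m q_m + δ]`,
   then recompute `Q`;
2. the same update with `(B, U_B, V_B, μ, Q_B)` for `U_B`, then recompute
   `Q_B`;
3. `V ← V ⊙ (Uᵀ A + λ Q V*) / (Uᵀ U V + λ Q² V + δ)` (Q acting as a row
   scaling);
4. the analogous update for `V_B` with `(B, U_B, μ, Q_B)`;
5. `V* ← (λ Q V + μ Q_B V_B) / (λ + μ)` — the exact minimizer of J in
   `V*`; at `λ = μ` this is the plain average of the two rescaled
   embeddings, and when both weights are zero (J then ignores `V*`) the
   plain average is kept as the convention.

Each of steps 1–4 rescales a factor by the ratio of the negative to the
positive part of the gradient of J's relevant terms.  Because every such
block is a quadratic with entrywise non-negative Hessian and non-negative
linear part, the standard diagonal-majorization argument applies and no
step can increase J.  A design point deserves emphasis: the consensus
penalty enters the `V` and `V_B` updates with the *same* `Q`-weighting
that J carries.  An asymmetric variant (penalizing plain `‖V − V*‖` in the
coefficient updates while J carries `‖Q V − V*‖`) has no common Lyapunov
function, and numerically its objective history oscillates rather than
decreases; the consistent weighting used here makes the recorded J history
provably non-increasing for any `λ, μ ≥ 0` and makes the converged factors
satisfy the first-order (KKT) conditions of J itself, which the test suite
verifies against central-difference gradients.  With `λ = μ = 0` every
update reduces exactly to the classical Lee–Seung multiplicative rule for
the Frobenius objective.

In no-attribute mode the `B` and `μ` terms vanish, the cycle is steps 1, 3
and `V* = Q V`, and scoring proceeds from `V*` unchanged.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `k` | halving schedule, `i = 1` | latent dimension; `n/2ⁱ` without attributes, `(n+m)/2^(i+1)` with, clamped to `[1, n−1]`.  These are the largest ranks satisfying the compression conditions `2nk < n²` and `(n+m)k < nm`. |
| `λ, μ` | 1.0 | consensus weights (dimensionless); equal weighting treats topology and attribute embeddings symmetrically. |
| `eps` | `10⁻⁴ · ‖A‖²_F` | absolute stop on the reconstruction error; made relative to the data scale because an absolute threshold is meaningless across graph sizes, and `A` is generally not exactly low-rank so very small absolute targets may be unreachable. |
| `rel_tol` | `10⁻⁶` | secondary stop on the relative per-cycle decrease of J; guarantees termination with the iteration cap. |
| `max_iter` | 500 | cycle cap; hitting it flags `converged = False` on the returned model rather than raising. |
| `δ` | `10⁻¹²` | guard added to every update denominator; denominators can reach zero when a factor row/column dies.  Converged J changes by < 10⁻⁶ relative when δ is doubled (tested). |
| `n_restarts` | 1 | random initializations; the lowest-final-J model is kept.  Multiplicative updates only find local optima, and on small latent dimensions a poor draw can merge planted communities; 3 restarts is what the benchmark protocol uses. |
| `seed` | 0 | all factor draws are uniform on (0, 1] from one generator seeded here; restart `r` uses `seed + r`. |

Scoring uses cosine similarity of `V*` columns by default (bounded and
invariant to positive rescaling, so it compares embedding *directions*;
the evaluation only consumes the induced ordering).  Dot product and
negative Euclidean distance are provided for comparison.  The cosine of
two zero columns is defined as 0.

## Evaluation protocol

Observed edges are randomly partitioned into k near-equal folds (edges,
not nodes, because train/probe must partition the edge set); each fold in
turn is the probe set while the predictor sees only the training graph —
baseline neighbourhoods and the factorization alike are computed on
training edges only, and the harness re-derives the training adjacency
internally so probe information cannot leak.  AUC compares probe edges
against *nonexistent* pairs (absent from the full edge set), counting
exact floating-point score ties as one half; `auc_exact` enumerates all
comparisons via sorting, `auc_sampling` draws `n_samples = 10 000` pairs
by default.  Ranked outputs break score ties by lexicographic node-index
order so runs are bitwise reproducible.  Precision@L counts probe edges
among the top-L non-observed pairs.

## Synthetic data

The stochastic block model generator is the benchmark bed: `n = 100`
nodes in 2 equal blocks, within/between edge probabilities
`p_in = 0.3` / `p_out = 0.05`, and `m = 20` binary attributes of which
each block owns half, present on its members with probability
`attr_signal = 0.9` and elsewhere at a background rate of 0.05.  These
defaults give a sparse assortative graph (mean degree ≈ 17) whose
communities are recoverable but not trivial, with attributes that carry
strong but noisy block information — the regime the joint model is meant
for.  A useful calibration: a scorer that knows only the block structure
attains exact AUC ≈ 0.72 on these graphs, so cross-validated AUCs just
above 0.7 mean the embedding has essentially saturated the planted
block-level signal.

The low-rank generator plants `P = W Wᵀ` with `W` uniform `n × k`, i.e.
the coefficient factor is the base factor's transpose.  This makes the
planted product symmetric *and* exactly rank `k`; symmetrizing a product
of two independent factors would double the rank and put a floor (~3×10⁻³
relative at `n = 60`, `k = 4`) under the best achievable rank-`k`
reconstruction.  The thresholded adjacency keeps the top pairs of `P` at
expected density `0.25 · density_scale`.

What the generators do not emulate: heavy-tailed degree distributions,
local clustering beyond what blocks induce, degree–attribute correlations,
and the scale of real curated networks (10³–10⁴ nodes).  Passing the
benchmark shows the pipeline extracts planted community/attribute signal
at calibration-point fidelity; it does not certify performance on real
heterogeneous networks.

## Validation problem sizes

The test and acceptance runs use: calibration and sampling-agreement
checks on the `n = 100` SBM (20 × 10 000 sampled comparisons; 100 runs for
the 3σ agreement band against exhaustive AUC); objective monotonicity on
20 attributed instances with `n = 30`, `m = 15`, `k = 5`, `λ = μ = 1` at
10⁻⁹ relative slack; first-order conditions on `n = 8`, `k = 3` instances
run to stationarity (20 000 cycles) with central-difference gradients
required below 10⁻⁴ at entries above 10⁻⁶; planted recovery at `n = 60`,
`k = 4`, `λ = 0` to < 10⁻³ relative error within 500 iterations; and the
10-fold benchmark on five generator seeds with `k = 2` (the planted block
count) and 3 restarts.

## Known limitations

- Dense `n × n` arithmetic throughout: O(n²k) time per cycle and O(n²)
  memory; practical to a few thousand nodes, not beyond.
- The objective is non-convex; different seeds reach different local
  optima.  Restarts mitigate but do not remove this.
- Multiplicative updates converge sublinearly near stationary points;
  entries heading to zero approach it geometrically but never exactly
  reach it (complementary slackness holds in the limit).  A known caveat
  of this update family: an entry that has collapsed numerically to zero
  cannot be reawakened, so a limit point occasionally keeps a descent
  direction locked behind such a dead entry — interior stationarity and
  the complementarity product `x·|∂J/∂x| ≈ 0` hold, but the boundary sign
  condition can be violated there.  Restarts are the practical remedy.
- `λ, μ` are not tuned automatically; the equal-weight default is a
  convention, and rank selection is limited to the two halving schedules.
- Weighted or directed graphs, probability-calibrated scores, and global
  similarity indices (Katz, random walks) are out of scope.
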