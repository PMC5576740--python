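# nmflp — link prediction by joint non-negative matrix factorization

Real interaction networks — protein–protein interaction maps, co-authorship
graphs, infrastructure networks — are observed incompletely: many true links
are simply not (yet) recorded.  Link prediction ranks the non-observed node
pairs by how likely they are to be genuine edges, so that experiments or
curation can be pointed at the most promising candidates.

`nmflp` implements a latent-space predictor for undirected simple graphs,
optionally augmented with node attributes (e.g. annotation keywords), plus
the classical neighbourhood indices and the standard AUC / precision
evaluation protocol for comparing them.

## The model

Let `A` be the `n × n` adjacency matrix and `B` the `m × n` non-negative
node-attribute matrix (per-node columns, L1-normalized).  The method seeks
non-negative factors

    A ≈ U V,        U: n × k,   V: k × n
    B ≈ U_B V_B,    U_B: m × k, V_B: k × n

whose coefficient matrices are tied together through a consensus embedding
`V*` by minimizing

    J = ‖A − U V‖²_F + ‖B − U_B V_B‖²_F
        + λ ‖Q V − V*‖²_F + μ ‖Q_B V_B − V*‖²_F,

subject to non-negativity of all factors, where `Q = diag(Σ_i U_i1, …,
Σ_i U_ik)` (and `Q_B` likewise) rescales the coefficients as if the bases
had unit column sums, putting the two embeddings on a common scale.  J is
minimized by block-coordinate multiplicative updates — each factor entry is
rescaled by the ratio of the negative to the positive part of its block
gradient — which preserve non-negativity and never increase J; with
`λ = μ = 0` they reduce to the classical Lee–Seung rules.  Without
attributes, the `B` and `μ` terms drop and `V* = Q V`.

Column `i` of `V*` is node `i`'s latent coordinate vector; candidate links
are ranked by cosine similarity of these columns.  Prediction quality is
measured by AUC — the probability that a held-out (probe) edge outscores a
random nonexistent pair, ties counting one half — and by precision@L, under
k-fold cross-validation over edges.

## Worked example

Generate a 2-community benchmark graph with community-correlated attributes,
fit the factorization, and rank candidate links:

```
$ nmflp synth --n 40 --blocks 2 --m 8 --seed 7
n=40 edges=146 blocks=2 sizes=[20, 20] attributes=8

$ nmflp fit synthetic_edges.txt --attributes synthetic_attrs.txt --k 2 --seed 1 --top-L 5
INFO nmflp: loaded 40 nodes, 146 edges, 8 attributes
INFO nmflp: stopped after 266 iteration(s) by rule 'rel_change'; J=241.025, ||A-UV||^2=224.57
INFO nmflp: wrote 5 candidate pair(s) to ranking.tsv
```

`ranking.tsv` lists the five highest-scoring non-observed pairs (here all
within-community pairs whose cosine similarity rounds to 1 — in a 2-D
non-negative latent space same-block embeddings are nearly parallel, and the
ranking, not the absolute score, is what the evaluation uses).

Cross-validated comparison against common-neighbour and preferential-
attachment baselines (5 folds; mean exact AUC per method):

```
$ nmflp benchmark synthetic_edges.txt --attributes synthetic_attrs.txt \
      --methods NMF-LP,CN,PA --folds 5 --k 2 --seed 1
method  fold    auc
NMF-LP  mean    0.757594
CN      mean    0.635608
PA      mean    0.41286
```

The factorization exploits both the planted block structure and the
attribute signal, so it clearly outperforms chance (0.5) and the purely
degree-based PA index on this graph.

The same pipeline is available as a library:

```python
import nmflp
graph, attrs, blocks = nmflp.generate_sbm(nmflp.PlantedSpec(seed=7))
model = nmflp.fit(graph, nmflp.normalize_attributes(attrs),
                  nmflp.FitConfig(k=2, seed=1))
scores = nmflp.score_from_embeddings(model)
top = nmflp.rank_candidates(scores, graph.edges, top_L=10)
```

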