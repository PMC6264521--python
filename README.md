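# linknmf

Link prediction on attributed networks via jointly regularized non-negative
matrix factorization.

Given an undirected network with adjacency matrix `A` and, optionally, node
attributes, the task is to rank the unobserved node pairs by how likely they
are to be true (missing or future) edges. Purely topological predictors
struggle on sparse networks; `linknmf` couples the observed structure with
**auxiliary similarity information** — either attribute-derived ("external",
`S`) or computed from the topology itself with a classical index
("internal", `Sim`) — in a single factorization with a shared basis:

```
min  ||A − W·H1||²_F + α·||S − W·H2||²_F + β·(||H1||²_F + ||H2||²_F)
 s.t.  W, H1, H2 ≥ 0
```

`W (n×k)` is a latent feature basis shared by both information sources,
`α` balances structure against auxiliary similarity, and `β` is a ridge
penalty on the coefficient factors. The objective is minimized with
multiplicative update rules that preserve non-negativity; the link score of
a pair is the symmetrized reconstruction `(W·H1 + (W·H1)ᵀ)/2`.

The package is aimed at researchers studying networks with homophily — the
tendency of similar nodes to connect, common in social and biological
systems — who want to test whether attribute or latent-structure similarity
improves missing-link recovery over classical indices.

Also included:

- the seven classical similarity indices (CN, Salton, Jaccard, RA, AA,
  Katz, ACT) as standalone predictors and as internal auxiliary input;
- attribute preprocessing (column normalization; cosine, Euclidean and
  Pearson pairwise similarities);
- evaluation by AUC (probe vs nonexistent links, ties half credit) and
  precision@L, with a repeated-random-split experiment harness;
- a synthetic generator of planted-partition networks with homophilous
  binary attributes, so everything is testable without external data.

## Worked example

```python
from linknmf import (SynthConfig, generate_attributed_network, split_edges,
                     score_method, auc, precision_at_L, summary_stats)

cfg = SynthConfig(seed=1)          # 200 nodes, 4 communities, 40 attributes
graph, attrs, _ = generate_attributed_network(cfg)
s = summary_stats(graph)
print(f"N={s.n_nodes} E={s.n_edges} <K>={s.avg_degree:.2f} "
      f"<d>={s.mean_shortest_distance:.3f} C={s.clustering_coefficient:.3f}")

split = split_edges(graph, train_fraction=0.9, seed=7)
print(f"train edges: {split.train_graph.n_edges}, probe edges: {len(split.probe_edges)}")

for method in ["CN", "AA", "RA", "NMF", "JointNMF:A+S"]:
    scores, _ = score_method(method, split, attrs=attrs, seed=7)
    a = auc(scores, split.probe_edges, graph, n_samples="exhaustive")
    p = precision_at_L(scores, split.probe_edges, L=100, seed=7)
    print(f"{method:14s} AUC={a.auc:.3f}  precision@100={p.precision:.2f}")
```

prints

```
N=200 E=1540 <K>=15.40 <d>=2.368 C=0.173
train edges: 1386, probe edges: 154
CN             AUC=0.720  precision@100=0.00
AA             AUC=0.714  precision@100=0.00
RA             AUC=0.714  precision@100=0.00
NMF            AUC=0.741  precision@100=0.04
JointNMF:A+S   AUC=0.800  precision@100=0.02
```

The AUC is the probability that a held-out true edge outranks a random
nonexistent pair; 0.5 is chance. On this homophilous network the joint
factorization with attribute similarity (`JointNMF:A+S`, α=4, β=32) beats
both the local indices and plain NMF: the attributes carry community
information that the sparsified topology alone does not.

Method labels accepted by `score_method` / `run_experiment`: the seven
index names, `NMF`, `Random`, and `JointNMF:<mode>[:<index>]` where mode is
`A+S` (adjacency + attribute similarity), `A+Sim` (adjacency + structural
index, e.g. `JointNMF:A+Sim:AA`), or `Sim+S` (structural index replacing
adjacency + attribute similarity).

## Command line

```sh
linknmf simulate --out-dir net/ --n-nodes 200 --seed 1
linknmf stats net/edges.tsv
linknmf predict net/edges.tsv --method JointNMF:A+S --attributes net/attributes.tsv --top 20
linknmf evaluate net/edges.tsv --methods CN,AA,NMF --fractions 0.9,0.8 --repetitions 20
linknmf sweep net/edges.tsv --alphas 1,4,16 --betas 8,32,100 --attributes net/attributes.tsv
```

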