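# netconsensus

Consensus scoring of nodes in interaction networks.

Many biological and social networks encode a *collective opinion* about each
node: a primate subordination-signalling network encodes group consensus about
who wins fights (social power), a scientific collaboration network encodes a
community's view of a researcher's reputation, and a functional gene-linkage
network encodes how important a gene is to the cell. `netconsensus` implements
a family of algorithms that read this consensus off a non-negative interaction
matrix `A`, where `A[i, j]` counts interactions sent from node `i` to node
`j`, together with the protocols needed to evaluate and stress-test them.

**Breadth algorithms** score a node by how *uniformly many* partners direct
interactions at it:

- Simple Consensus `D_j` — number of distinct senders to `j`;
- Weighted Simple Consensus `Δ_j = D_j · R_j`, where `R_j = Σ_i A[i, j]` is
  the weighted in-degree;
- Shannon Consensus `Π_j = H_j · R_j`, where
  `H_j = −Σ_i N[i, j] log N[i, j]` is the Shannon entropy of `j`'s receiving
  distribution `N[i, j] = A[i, j] / R_j`.

**Depth algorithms** treat interactions as a diffusion and weight partners by
their own incoming flow:

- Eigenvector Centrality `C` with redistribution: the unique solution of
  `C = εv + (1−ε) C M` with `M` the (dangling-patched) row-stochastic sending
  matrix, `ε ∈ (0, 1]` the redistribution weight and `v` the redistribution
  vector;
- David's Score `DS = w + w₂ − l − l₂` over dyadic receive proportions, plus
  a depth-`k` generalization;
- Graph Laplacian consensus `GL = (K − Aᵀ) H` with `K = diag(R)`.

**Count algorithm**: the Borda count `β`, aggregating each node's tie-averaged
ordinal ranking of the others as votes.

The package also provides the *source-bias shuffle* (concentrate all of a
node's in-weight on one partner while conserving every weighted in-degree) and
a degree-preserving randomization control for quantifying each algorithm's
robustness; quartile-based prediction-heterogeneity profiles against per-node
functional covariates; redistribution-weight selection (by predictive value,
or by skewness minimization when no covariates exist); and synthetic
generators emulating heavy-tailed transitive signalling networks, skewed
collaboration graphs with tunable degree assortativity, and entropy/in-degree
decorrelated controls.

## Worked example

```python
import numpy as np
from netconsensus import (InteractionNetwork, shannon_consensus,
                          eigenvector_centrality, sensitivity_experiment)

# a -> b twice, a -> c once, b -> c three times
net = InteractionNetwork(
    ("a", "b", "c"),
    np.array([[0, 2, 1],
              [0, 0, 3],
              [0, 0, 0]], dtype=float))

pi = shannon_consensus(net)
print(pi.to_frame().to_string(index=False))
# node    score  rank
#    a 0.000000   2.5
#    b 0.000000   2.5
#    c 2.249341   1.0

ec = eigenvector_centrality(net)   # eps = 0.15, uniform v
print(ec.to_frame().to_string(index=False))
# node    score  rank
#    a 0.050000   3.0
#    b 0.078333   2.0
#    c 0.871667   1.0

exp = sensitivity_experiment(net, ["pi", "R"], sample_size="all", seed=7)
print(exp.summary[["algorithm", "mean_rank_drop"]].to_string(index=False))
# algorithm  mean_rank_drop
#        pi        0.666667
#         R        0.000000
```

Node `c` receives interactions from both other nodes, one quarter from `a`
and three quarters from `b`, so its receiving entropy is
`−(¼ ln ¼ + ¾ ln ¾) ≈ 0.562` nats and its Shannon Consensus is
`0.562 × 4 ≈ 2.249`; nodes with a single sender (or none) score exactly zero.
Eigenvector Centrality accumulates on `c` (the only non-sender) but the
ε-redistribution keeps every node at or above `ε/n = 0.05`. The shuffle
experiment shows that in-degree `R` is untouched by source bias (it is
conserved by construction) while Shannon Consensus reacts.

The same pipeline is available from a shell:

```bash
netconsensus simulate --kind signaling --n 50 --seed 7 -o net.tsv
netconsensus score --input net.tsv -a pi -a ec -o scores/
netconsensus shuffle-test --input net.tsv --algorithms pi,gl,ec,D,R \
    --sample all --seed 7 -o sensitivity.tsv
netconsensus sweep-epsilon --input net.tsv --grid 0.05:0.95:0.05
```

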