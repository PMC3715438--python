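# Methods

## The consensus model

All algorithms operate on a node-labelled non-negative interaction matrix
`A`, `A[i, j]` = count or weight of interactions from node `i` to node `j`,
with a zero diagonal (self-interaction is rejected at load: the systems this
models — signalling dyads, collaborations, gene linkages — have none). The
orientation convention is fixed throughout: consensus about a node
accumulates in its *column*, so every "in" quantity is a column sum. For
undirected networks `A` is symmetric; for unweighted networks it is binary.
Duplicate rows in an edge list are summed (with a warning) so that
event-level interaction logs can be loaded directly.

The interpretation is that each sender's out-edges express its opinion of
the receivers, and a node's score quantifies how much the population agrees
about its state. What the consensus is *about* depends on what the edges
are; the algorithms only quantify the agreement structure.

### Breadth scores

- `D_j` (Simple Consensus): number of distinct senders — column-wise count
  of positive entries of the binary matrix.
- `R_j` (weighted in-degree): total in-weight, the baseline every other
  score modulates.
- `H_j`: Shannon entropy of the receiving distribution
  `N[i, j] = A[i, j] / R_j`. `H = 0` with a single sender (consensus is
  vacuous), `H = log k` with `k` equal senders (its maximum), and `H = 0`
  by convention when `R_j = 0`.
- `Δ_j = D_j · R_j` and `Π_j = H_j · R_j`. Multiplying by `R` lets the
  scores distinguish a node receiving ten signals from each of ten partners
  from one receiving one signal from each. The products, rather than some
  other combination of uniformity and volume, are this package's reading:
  they reproduce the intended qualitative behaviour (zero for single-sender
  nodes, the unweighted reductions `Δ = R²` and `Π = R log R`, linear
  scaling of `Π` under uniform reweighting). An alternative
  `Π = H · log R` is available behind `shannon_consensus(..., weighting="logR")`
  for users who want the score on the entropy scale.

### Depth scores

- Eigenvector Centrality solves `C = εv + (1−ε) C M` with `M` the
  row-stochastic sending matrix. Rows of non-senders are patched before the
  fixed point exists; the default patch is a self-loop (`M[i, i] = 1`),
  which preserves the absorbing-state reading that motivates
  redistribution, with a uniform row (`1/n`) as an alternative. Any
  solution automatically sums to 1 because `M` is row-stochastic. The
  default is a dense linear solve; power iteration is available and the two
  agree to 1e-10 on random networks up to n = 500 (tested). Default
  `ε = 0.15`, uniform `v`; because the right `ε` is data-dependent, it is
  always recorded in the output provenance and the `evaluation` module
  implements both selection procedures (below).
- David's Score uses dyadic receive proportions
  `ρ[i, j] = A[j, i] / (A[i, j] + A[j, i])`, *absent* (not 1/2) for
  non-interacting dyads so sparse networks are not inflated. With
  `w = Σ_j ρ[i, j]`, `l` its emit-side mirror, and `w₂ = ρ·w`, `l₂` the
  chained versions, `DS = w + w₂ − l − l₂`. Receive orientation is the
  default because the score is meant to favour nodes that receive much and
  emit little; `win_oriented=True` flips the convention for classical
  dominance matrices where `A` records wins. The depth-`k` extension
  iterates `w^(t) = ρ · w^(t−1)` and sums `Σ_{t≤k} (w^(t) − l^(t))`; `k = 2`
  recovers `DS` exactly, and the rank order stabilizes as `k` grows (the
  iterates align with the dominant eigendirection of `ρ`). This iterated-sum
  form is the package's declared interpretation of "depth k".
- Graph Laplacian consensus `GL = (K − Aᵀ) H`, `K = diag(R)`:
  `GL_i = R_i H_i − Σ_j A[j, i] H_j`, the net entropy-weighted flow into
  `i`. It is linear in `H` for fixed topology and identically zero on
  entropy-constant networks.

### Count score

The Borda count treats each node as a voter ranking the other `n−1` nodes
by how much it sends them: top candidate gets `n−1` votes down to 1, ties
tie-averaged. Candidates a voter never interacts with form its bottom tie
class, and out-edge-less voters still vote (everyone tied at `n/2`). This
keeps vote conservation exact: each voter distributes `n(n−1)/2` votes, so
scores always total `n²(n−1)/2`.

### Ranks

All rank outputs are descending tie-averaged ranks (rank 1 = highest score;
ties share the average of the positions they span), so rank vectors always
sum to `n(n+1)/2`.

## Source-bias robustness

A *source bias* is a distortion concentrating a node's in-weight on few
senders, whether by systematic observation error or by deliberate
manipulation. The shuffle implements the extreme case: target `t` receives
*all* of `R_t` from one in-neighbour `p`. In directed mode only the
`t`-column changes (`A'[p, t] = R_t`, other in-edges of `t` removed);
the partner's out-edges to third parties are held constant. This is the only
reading under which the full weighted in-degree vector is conserved, which
is the point of the protocol — `R` is unmoved by construction, so any rank
change isolates sensitivity to sourcing. (The alternative of rescaling the
partner's other out-edges would break the conservation and is not
implemented.) In undirected mode the target's incident edges are replaced by
one symmetric edge of weight `R_t`, preserving symmetry.

The sensitivity experiment either exhausts all (target, in-neighbour) pairs
(`sample_size="all"`, the treatment for small networks) or samples targets
without replacement with one random in-neighbour each. Both the target's
tie-aware rank drop and the Spearman correlation of the full before/after
score vectors are recorded per algorithm — the field reports both
statistics, and neither is privileged here. Isolated targets (`R = 0`) are
skipped and counted. Identical seeds give identical experiments.

The degree-preserving randomization control treats each unit of weight as
an event token and re-matches sender tokens to a random permutation of
receiver tokens, repairing self-loop conflicts by random swaps. Every
node's weighted in- and out-degree is conserved exactly while transitivity
and other higher-order structure are destroyed; it requires integer
weights. A pathological degree sequence that cannot be repaired raises an
error suggesting the unidirectionality constraint be relaxed.

## Predictive evaluation

Scores are evaluated against per-node outcome tables by OLS within seven
nested rank subsets (top quartile, top half, top three quartiles, all
nodes, bottom three, bottom half, bottom quartile). Heavy-tailed score
distributions predict well in the tail and poorly in the bulk; the subset
profile makes this prediction heterogeneity visible instead of averaging it
away. Cut points are positional at `ceil(n·k/4)` with a deterministic
(score descending, node id ascending) tie-break. Subsets need at least 4
overlapping nodes and 3 complete pairs per regression; zero-variance
regressions define `r² = 0` with a warning rather than erroring.

"Multivariate r²" is defined here as the squared multiple correlation from
regressing the *score* on all outcome columns jointly — symmetric in
spirit, a single number, and reducing to the univariate `r²` with one
outcome. Outcomes are assumed already corrected for any underlying
propensity (a plain `observed_minus_expected` helper is provided for users
who supply expected columns; no propensity model is fitted here).

The redistribution sweep evaluates EC over an `ε` grid. With outcomes the
criterion is the full-sample multivariate `r²` (argmax); without outcomes
it is |sample skewness| (argmin) — the heuristic being that an `ε` that
neither crushes the score distribution toward uniform nor lets it collapse
onto absorbers tends to coincide with the predictive optimum. Ties go to
the first grid value and the full table is always returned so flatness is
inspectable.

## Synthetic generators

The generators exist so every procedure is testable without any empirical
download; their defaults are the package's standing study conditions.

- **Signalling** (`n = 50`, `interaction_prob = 0.3`,
  `direction_noise = 0.05`, `weight_rate = 5`): latent node strengths are
  log-normal(0, 1) — producing the heavy-tailed score distributions typical
  of power-structured groups — each dyad activates independently, signals
  run weak→strong (direction flipped with probability 0.05), and event
  counts are `1 + Poisson` scaled by the receiver's relative strength so
  active dyads are never empty. Unidirectionality is enforced exactly,
  mirroring the defining property of subordination signals. With zero
  noise the binary relation embeds in a total order, hence is fully
  transitive; at default noise the networks are highly transitive and show
  the strong positive entropy/in-degree coupling seen in real signalling
  data (Spearman ≈ 0.95+).
- **Collaboration**: Chung–Lu graph on log-normal(0, 0.5) expected degrees
  scaled to mean degree `interaction_prob·(n−1)`; binary, symmetric,
  right-skewed. The assortativity knob rewires by degree-preserving
  double-edge swaps: since Newman's coefficient is affine in
  `S = Σ_edges deg(u)·deg(v)` once the degree sequence is fixed, moves are
  scored in O(1), with a cooling schedule (initial temperature = mean
  degree squared) so the walk escapes jamming points where no single swap
  improves. Unreachable targets raise with the achieved value: dense
  graphs with near-saturated hubs have genuinely bounded assortativity.
- **Decorrelated**: half the nodes receive `~4·weight_rate` events from a
  single sender (high `R`, `H = 0`), half receive one event from each of
  up to five senders (low `R`, `H = log k`), forcing Spearman(H, R) ≤ 0 —
  the control demonstrating that in-weight and entropy are logically
  independent even though they correlate in natural data.
- **Outcomes**: each column is `slope·score + N(0, noise_sd)`; the metadata
  records the implied population `R² = var(slope·s) / (var(slope·s) + sd²)`
  and `noise_sd_for_r2` inverts it.

What the generators do *not* emulate: observation effort heterogeneity,
temporal structure, reciprocity beyond the direction-noise rate, community
structure, and the size of real collaboration/linkage networks (10⁴–10⁵
nodes). Passing tests therefore demonstrate the algorithms' contracts and
relative orderings under these structural assumptions, not performance on
any particular empirical system.

## Numerical choices

- EC: dense solve of `(I − (1−ε)Mᵀ)C = εv`; power iteration tolerance
  1e-12 (L1 residual), max 10000 iterations, error on non-convergence.
  `ΣC = 1` is exact to 1e-12 and `C_i ≥ ε v_i` always (the redistribution
  floor implied by the fixed-point form).
- Entropies use natural log by default (recorded in output params);
  base-2 available. `0 log 0 ≡ 0` throughout.
- Tie handling is tie-averaging everywhere (ranks, Borda votes, quartile
  order uses node-id tie-break instead so subsets are deterministic sets).
- Degenerate inputs: all-zero networks are valid everywhere (scores 0);
  constant score vectors skip normality tests and leave Spearman
  correlations NaN (skipped in summaries) rather than fabricating a value.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at deliberately desk-sized
scales chosen to make the stochastic orderings unambiguous while staying
quick: sensitivity orderings use 20 (tests) or 10 (script) signalling
networks of n = 50 with all (target, partner) pairs exhausted (~350–400
trials per network); solver-agreement checks go up to n = 500; `r²`
recovery uses n = 200; the `ε`-recovery sweep uses n = 60 with a 0.05 grid.

## Known limitations

- The exact functional forms combining uniformity and volume (`Δ`, `Π`)
  and the depth-`k` recursion are this package's own committed
  interpretations of verbally specified quantities; both are documented
  above and flagged in the API docs where alternatives are offered.
- Randomization requires integer weights (token semantics).
- The assortativity knob targets the *measured* coefficient within ±0.05,
  not an exact value, and can legitimately fail on dense or extremely
  skewed degree sequences.
- No bias-corrected entropy estimators: entropies are plug-in sample
  entropies, adequate for the weight ranges the generators produce but
  biased low for very sparse columns.
- No multigraph, temporal or bipartite representations.
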