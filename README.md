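# multiweb

Tools for analysing **multiplex ecological networks** — communities in
which one set of species is linked by several interaction types at once:
a trophic layer (who eats whom), a positive non-trophic layer (refuge
provisioning, recruitment facilitation) and a negative non-trophic layer
(competition for space, predator interference). The motivating system is
a marine rocky-intertidal web of ~100 co-occurring species with thousands
of directed links of all three kinds.

The package answers four questions about such a web:

1. **Structure.** Which species play the same three-dimensional role? A
   multiplex stochastic block model clusters species by their joint
   connectivity in all layers simultaneously.
2. **Pair specificity.** Do species pairs engage in fewer (or more)
   simultaneous interaction types than expected? Observed pair-type
   counts are compared with degree-preserving random multiplexes.
3. **Dynamics.** Do the non-trophic links matter where they actually
   are? A bioenergetic consumer–resource model with six non-trophic
   rate modifiers is simulated on the cluster-level web and compared
   with randomized-placement nulls.
4. **Function.** Do clusters collapse into trait-predictable,
   taxonomically coherent functional groups? Ward aggregation of block
   parameters, classification trees on traits, and permutation tests on
   patristic distances.

## The model

For species `i, j` the directed pair outcome is the 3-bit vector
`Y_ij = (Y_ij1, Y_ij2, Y_ij3)` — presence of a trophic, positive and
negative link. With latent memberships `Z_i ~ Multinomial(1, a)` over `Q`
clusters, the emission is a joint **3D-Bernoulli** (categorical over the
8 outcomes):

```
Y_ij | Z_iq = Z_jl = 1  ~  f(. ; θ_ql),    θ_ql ∈ Δ^8
```

so within-pair coupling of interaction types is part of the model, not an
afterthought. Estimation is variational EM (mean-field responsibilities
τ); starts come from k-means on the Rogers–Tanimoto distance matrix
between species interaction vectors `V_i = (Y_i., Y_.i)` plus random
membership perturbations; `Q` is chosen by an integrated classification
likelihood (ICL) criterion with penalty
`(Q−1)/2·log n + 7Q²/2·log n(n−1)`.

Cluster-level dynamics follow the bioenergetic consumer–resource form

```
dB_i/dt = r_i g_i (1 − B_i/K_i) B_i + e_i B_i Σ_j F_ij TR(i,j)
          − Σ_k F_ki B_k TR(k,i) − x_i B_i
```

with a multi-prey Holling functional response `F_ij` and six saturating
non-trophic modifiers: competition (growth multiplier `g_i`), predator
interference (in the denominator of `F`), mortality increase
(`x_i → x_max_i`), recruitment facilitation (`r_i → r_i + r_max_i`),
refuge provisioning (`b_ij → b_min_ij`) and survival facilitation
(`x_i → x_min_i`).

## Worked example

```python
import numpy as np
from multiweb import MultiplexSBM, adjusted_rand, pairwise_overlap_test
from multiweb.synth import planted_multiplex, separable_theta

theta = separable_theta(3, p_in=0.8, p_out=0.05, p_pos_in=0.15, p_neg_out=0.1)
net, truth = planted_multiplex(n=60, Q=3, a=[1/3]*3, theta=theta, seed=7)

model = MultiplexSBM(net)
best = model.select_Q(range(1, 7), n_restarts=5, seed=0)
print(best.summary())
print("aRI vs planted labels:", adjusted_rand(truth, best.membership))
print(pairwise_overlap_test(net, n_reps=200, seed=1))
```

prints

```
Multiplex stochastic block model (3D-Bernoulli emission)
  species: 60    layers: TPN
  clusters (Q): 3
  ELBO: -2390.3555    ICL: -2651.8642
  iterations: 2  converged: True
  cluster sizes: 1:21, 2:22, 3:17
aRI vs planted labels: 1.0
Pairwise interaction-type overlap test (200 random multiplexes)
  n0: observed 871  null range 651-714  p < 0.005 (high)
  n1: observed 731  null range 833-932  p < 0.005 (low)
  ...
```

The ICL scan picks the planted number of clusters (Q = 3) and the modal
partition matches the planted labels exactly (adjusted Rand index 1).
The overlap test counts unordered species pairs linked by exactly 0–3
interaction types and locates each count in the null distribution from
degree-preserving random multiplexes; here the planted blocks concentrate
links on fewer pairs than the null expects, so the unlinked-pair count
sits above the null range (one-sided empirical p below 1/200).

The same surfaces exist on the command line (`multiweb fit / select /
pairtest / randomize / simulate / compare / groups / taxtest / synth`);
every stochastic subcommand takes a mandatory `--seed` and writes a run
manifest next to its outputs.

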