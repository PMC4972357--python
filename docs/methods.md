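# Methods

## The block model and its estimation

The clustering model treats each directed species pair as one
observation: the 3-bit outcome (trophic, positive, negative link
presence) of pair (i, j). Conditional on the latent cluster memberships,
outcomes are independent draws from an 8-cell categorical distribution
`θ_ql` specific to the ordered block pair — a joint ("3D-Bernoulli")
emission rather than three independent Bernoullis, so the tendency of
link types to co-occur (or to exclude each other) on the same pair is
itself a model parameter. Self-pairs are excluded from the likelihood;
self-loops remain representable in the data objects for downstream use.

Estimation is variational EM. The E-step applies the standard mean-field
fixed point for responsibilities τ (up to 5 inner sweeps, stopping when
the largest τ change falls below 1e-4); the M-step has closed forms for
the mixture weights and emission cells. Because simultaneous mean-field
updates are not formally guaranteed to increase the bound, an update
that decreases the ELBO is damped once by averaging τ with its previous
value before being accepted; in practice the logged traces are monotone
(the test suite checks every trace to a 1e-8 slack). Iteration stops when
the ELBO improves by less than `tol` (default 1e-6, max 200 iterations).
Emission cells and mixture weights are floored at 1e-10 so logarithms
stay finite; an empty cluster in the M-step renormalizes against that
floor and emits a warning rather than aborting.

Starting points: k-means on the rows of the Rogers–Tanimoto distance
matrix between species interaction vectors (the distance-matrix row is
the species' coordinate vector — the "k-means on the distance matrix"
reading), followed by perturbed copies that switch a uniform 5–15
distinct species to uniformly drawn other labels. `fit_best` keeps the
highest-ELBO run; the number of restarts is a runtime knob (the field
analysis used 1,000; the desk-scale tests use 3–5, which suffices at the
separations they plant). A k-medoids initializer is available behind
`init_method="medoids"` but is not the default.

Model selection maximizes an integrated classification likelihood:
completed log-likelihood at the modal partition minus
`(Q−1)/2·log n` for the mixture and `(K−1)Q²/2·log n(n−1)` for the
emission, with `K = 2^(number of layers)` (7 free parameters per ordered
block pair in the three-layer case). These penalty constants follow the
standard directed-SBM ICL; the criterion under-merges rather than
over-splits — on pure-noise networks the scan returns Q = 1 (tested).

Ties in the modal assignment go to the lowest cluster index. Layer-subset
fits reuse the identical machinery with a `2^|layers|`-cell emission,
which supports asking whether any single layer recovers the
three-dimensional clusters.

## Null models and the pair-type test

The random multiplexes preserve each layer's expected in- and out-degree
sequences: edge (i, j) appears with probability
`min(1, d_i^out d_j^in / m)` independently, and draws are rejected until
the realized edge count is within ±2.5% of the original. The cap at 1
slightly biases hub degrees downward; the calibration test bounds the
residual bias. Self-edges are never generated, and layers with no edges
are copied verbatim (nothing to randomize).

Pairs are counted unordered and distinct: a type is present for a pair
if at least one directed link of that type exists in either direction,
so `n0+n1+n2+n3 = n(n−1)/2` always. Empirical p-values are plain
proportions of replicates at least as extreme in the direction of
deviation, reported as `< 1/n_reps` when no replicate reaches the
observed value; a (r+1)/(n+1)-corrected variant sits behind
`plus_one=True`.

## Dynamics

Nodes are clusters; link weights are between-cluster interaction
frequencies in [0, 1] (either block-model marginals or direct
aggregation of a species partition). Parameters and defaults:

| parameter | meaning | default |
|---|---|---|
| `r` (1/time) | producer growth | 1 for producers, else 0 |
| `K` (biomass) | carrying capacity | 1 |
| `e` | conversion efficiency | 0.85 |
| `x` (1/time) | metabolic rate | `x0 = 0.2227` for consumers, 0 for producers |
| `h` (time) | handling time | `1/(y·x0)`, `y = 10` (max ingestion = y × metabolism) |
| `b` | attack rate | 0.5 |
| `b_min` | refuge floor on `b` | 0.2·b |
| `r_max`, `x_min`, `x_max` | facilitation bounds | `r`, `x/2`, `2x` (producers: `x_max = x0`) |
| `c`, `d` | competition / interference intensity | 1 |
| `q` | Hill coefficient | 0 (type-II response) |
| `intpos`, `intneg` | global multipliers on positive / negative NTI strengths | 1, 0.2 |

All six modifiers are saturating in facilitator/competitor biomass and
respect their limits exactly (`r → r+r_max`, `x ∈ [x_min, x_max]`,
`b' ∈ [b_min, b]`, `g ≤ 1`); the limits are covered by closed-form tests.
Two deliberate choices where the printed equations are ambiguous or
problematic:

* **Refuge form.** The additive saturating form for the attack rate has
  large-facilitator limit `b + b_min`, yet `b_min` is described as the
  *minimum* consumption reached in the presence of facilitators. The
  default implementation interpolates downward,
  `b' = b − (b − b_min)·S/(1+S)`, so the stated limit holds; the additive
  printed form is available behind `strict_refuge=True`.
* **Competition floor.** The growth multiplier `g = 1 − Σ c·B` can go
  negative at high competitor biomass; a negative multiplier on the
  logistic term would flip its sign, so `g` is floored at 0 by default
  (`g_floor=False` disables it).

Integration is LSODA in unit-time chunks; after each chunk any node at
or below 1e-6 biomass is clamped to zero for the remainder of the run
(the threshold is part of the protocol; the chunk-and-clamp mechanism is
this package's choice — it keeps the stiff integrator away from the
extinction discontinuity). Extinct nodes have their derivatives masked,
so zero is exactly absorbing. With all NTI matrices empty every modifier
reduces to the identity in exact floating point, and the trajectories
are bit-identical to an independently coded plain bioenergetic
right-hand side (tested).

**Mechanism mapping.** The data carry one positive and one negative
layer but the model distinguishes three mechanisms per sign. The default
rule: negative links between two sessile nodes → space competition
(COMP); negative links between consumers sharing at least one prey →
interference (INT); remaining negative links → mortality (MORT);
positive links onto producers → recruitment (REC); positive links onto
prey → refuge (REF); remaining positive links → survival facilitation
(FAC). The rule, the sessile/producer flags and the link threshold are
all configurable (`NTIMapping`), since no canonical assignment exists.

**Randomized-NTI comparison.** The trophic layer stays fixed; each
replicate redraws the positive and negative layers at species level from
the expected-degree null and re-aggregates with the same membership and
mapping before simulating (randomizing at species level, not the
cluster matrices directly, is this package's choice for that open
design point). The biomass p-value is the fraction of replicates whose
final total biomass reaches the observed value, ties counted half — a
null identical to the data yields p = 0.5 rather than 0.

## Functional groups

Cluster profiles are the concatenated emission rows and columns
`(θ_q., θ_.q)` (length 2·Q·K); Ward's method agglomerates the Euclidean
distances between them. The cut level is a user choice: the merge tree is
always exposed (and exportable as Newick) so the level can be picked by
inspection, as was done for the field web.

The trait predictor is a CART **classification** tree (the response is a
categorical group), with fit quality reported as a deviance-based
pseudo-R² = 1 − deviance(tree)/deviance(root) — the natural analogue of
the regression R² for this response type, and an interpretation flag
worth knowing when comparing against regression-tree figures. Ordinal
shore scores are used as numbers (low = 1, mid = 2, high = 3,
low-mid = 1.5); mobility and trophic category are integer-coded.

Taxonomic coherence: the statistic is the mean patristic distance
between species of the same functional group (overall and per group);
the null permutes group labels across species; p is the proportion of
permutations with a statistic at most the observed one. The choice of
statistic is this package's (the alternative schemes are pluggable); a
star tree makes the statistic permutation-invariant and returns p = 1,
and singleton groups are skipped with a note.

## Synthetic data

`planted_multiplex` inverts the generative model exactly: memberships
from the mixture, pair outcomes from the 8-cell block distributions,
empty diagonal. `separable_theta` builds strongly separated emissions
(within-block trophic probability 0.8 vs 0.05 elsewhere in the default
recovery tests). `planted_traits` and `planted_cladogram` emit
group-consistent trait tables and group-clustered trees with adjustable
noise, calibrated so zero noise gives pseudo-R² = 1 / minimal p and full
shuffling destroys the signal.

The `chile_like` preset matches the field web's **scale** — 106 species,
14 planted blocks, expected per-layer edge counts calibrated to
1,362/172/3,089 — with producer-like blocks (no outgoing trophic links,
dense mutual negative links) and facilitator blocks. Because its three
layers are conditionally independent given the blocks, it does **not**
emulate the field web's pair-level interaction-type exclusivity: its
two-type pair count sits near (or above) the null range rather than far
below it. Passing tests on these fixtures therefore demonstrate correct
inference and calibrated nulls, not that the generator reproduces every
empirical pattern of real data.

The `facilitation_scenario` fixture is the constructed direction-of-
effect experiment: positive links pair high-biomass facilitators with
the producer that fuels the food chain, while decoy links pair a
starving source with an inert target; degree-preserving randomization
mixes the pairings and dilutes the recruitment boost, so the observed
web out-produces the null median (the experiment behind the
direction-of-effect test).

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code
path with comfortable margins: planted recovery at n = 60–80 with 3–5
restarts and ICL scans over Q ∈ 1..6/1..7 across 5 seeds; null
calibration with 1,000 accepted draws on a 50-node layer; dynamics
comparisons with 20 null replicates over 300 time units on 5-node
cluster webs (the acceptance script uses the same sizes with 3–5 seeds).
Field-scale settings (1,000 restarts, 10⁴ null replicates, 500 dynamic
nulls over 2,000 time units, 10⁵ permutations) remain the documented
defaults on the corresponding functions.

## Known limitations

* Interaction strengths are not estimated; cluster-web weights are
  interaction frequencies, and the dynamic conclusions inherit that
  assumption.
* The NTI mechanism mapping is heuristic and configurable, not inferred.
* No degree-corrected or weighted block-model variants; no Bayesian
  estimation; at most the three built-in layers are exposed.
* Local-stability (Jacobian) analysis and spatial/stochastic dynamics
  are out of scope.
* The ICL penalty constants are a documented convention; other
  penalties shift the selected Q at weak separation.
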