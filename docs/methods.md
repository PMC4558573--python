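# Methods

## Scoring model

A candidate link's score is the negative conditional self-information of the
connection event given observed structural features. Writing I(·) = −log₂ p(·)
(all information in bits), a feature set Ω with variables assumed mutually
independent gives

    I(L¹ₓᵧ | Ω) = I(L¹ₓᵧ) − Σ_{ω∈Ω} gain(ω),    gain(ω) = I(L¹ₓᵧ) − I(L¹ₓᵧ | ω),

and k features combine linearly with nonnegative weights:
s = −Σᵢ λᵢ · I(L¹ₓᵧ | Ωᵢ). Because all information terms share one log base,
changing the base multiplies every score by the same positive constant:
rankings, AUC, and Precision are base-invariant (asserted by test). Bits are
used as the conventional unit.

### Prior

The prior connection probability is degree-based:

    p(L¹ₓᵧ) = 1 − C(M − kₓ, kᵧ) / C(M, kᵧ),

the probability that at least one of kᵧ link endpoints drawn uniformly
without replacement from the M training links falls on one of kₓ marked
slots. It is symmetric and monotone in each degree, and is validated against
an independent Monte-Carlo placement oracle (10⁵ literal without-replacement
draws per grid point) at 3 standard errors.

Degree-0 nodes — which arise when probe removal isolates a node — would give
p = 0 and infinite information, so priors are clamped into
[p_floor, 1 − p_floor] with p_floor = 1/(2(M+1)). The floor is below 1/C(M,1),
the smallest nonzero prior, so clamping preserves the ordering
"smaller degree ⇒ larger prior information" while keeping every score finite.

### Conditional estimators

*Common-neighbor feature.* For a node z with degree k_z ≥ 2, the probability
that a pair sharing z as a common neighbor is connected is estimated by z's
clustering statistic: N_Δz connected and N_Λz disconnected pairs among z's
C(k_z, 2) neighbor pairs, Laplace-smoothed to

    c_z = (N_Δz + 1) / (N_Δz + N_Λz + 2).

Smoothing keeps 0 < c < 1 so the conditional information −log₂ c_z is always
finite; the unsmoothed ratio equals the standard local clustering coefficient
(verified against networkx's independent triangle counter). Degree-0/1 nodes
cannot be common neighbors and receive no estimate. The information gain of
z averages the prior self-information over z's neighbor pairs and subtracts
−log₂ c_z; it is negative for low-clustering neighbors, i.e. sharing such a
neighbor is evidence against a link.

*Cross-link feature.* Each training edge {u, v} is characterized by the node
pairs it bridges, {(m, n) : m ∈ Γ(u)\{v}, n ∈ Γ(v)\{u}, m ≠ n}, with the same
smoothed connected-fraction estimator and the same gain construction (mean
bridged-pair prior information minus conditional information). An edge that
bridges nothing (e.g. a triangle edge between degree-2 endpoints) contributes
gain 0. The cross-link set of a candidate pair (x, y) excludes edges incident
to x or y themselves: the feature measures connectivity *between* the two
neighborhoods, not the pair's own stars; an edge joining two common neighbors
lies across both sets and counts once.

### Indices

MI is the single-feature (common-neighbor) case at λ = 1. NSI adds the
cross-link feature at weight λ = λ₂/λ₁:

    s_NSI = −(1 + λ)·I(L¹ₓᵧ) + Σ_{z∈CN} gain(z) + λ·Σ_{l∈cross} gain(l).

The prior term carries the factor (1 + λ) rather than being normalized to
weight 1; the two conventions differ by a positive scale factor at fixed λ
and therefore rank identically. Default λ = 0.1; a pair with no common
neighbors and no cross links falls back to −(1+λ)·prior information, so
distant pairs are still ordered by degree rather than collapsing to a single
tied score. Baselines: CN = |Γ(x)∩Γ(y)|; AA = Σ 1/ln k_z (natural log, the
established convention); RA = Σ 1/k_z; PA = kₓ·kᵧ; LP = (A²)ₓᵧ + ε(A³)ₓᵧ with
ε = 0.001 and literal walk-count (adjacency-power) semantics — for the
non-adjacent pairs actually scored, walk counts and simple-path counts
coincide.

## Evaluation protocol

Observed links are split uniformly at random into a training set (fraction
0.9 by default, |E^T| = round(0.9·|E|)) and a probe set; all structural
queries see only the training graph, and probe-isolated nodes are retained
with degree 0. Sampled AUC draws n (default 10⁵, standard error ≤ 0.0016)
independent probe-vs-non-existent comparisons with replacement and scores
(n′ + 0.5·n″)/n; exact AUC is the Mann–Whitney mid-rank statistic over all
probe × non-existent pairs, to which the sampled value converges.
Non-existent pairs are those in U − E — never probe links. Precision@L
(default L = 100) breaks ties by a seeded shuffle before a stable sort, so
label order cannot bias the top-L cut. The benchmark runner derives each
repetition's split seed as base_seed + r and metric seeds from (base_seed, r),
making whole benchmarks bit-reproducible; reported sd is the population
standard deviation (0 for a single repetition).

## Synthetic data

The generators (Erdős–Rényi, Barabási–Albert, Watts–Strogatz) delegate to
networkx's seeded implementations and stand in for real benchmark networks in
all tests; one pinned edge-list fixture guards against generator drift. They
emulate sparse undirected topologies with tunable clustering (WS) and degree
heterogeneity (BA) but not the degree–clustering correlations, community
structure, or measurement biases of real protein-interaction or citation
networks — passing tests demonstrate *correctness of the computation*, not
predictive accuracy on any particular real network (real networks are
supplied by the user as edge lists).

The tie-breaking fixture (`lp_tie_fixture`) is a 24-node graph built so that
its two designated candidate pairs have identical common-neighbor counts,
length-3 path counts, and — by equalizing every relevant degree between the
two halves — identical priors and mean bridged-pair informations. The only
difference is the clustering of the common neighbors (1/6 each vs 0 each),
so LP ties on the two pairs for every ε while NSI separates them by exactly
2·log₂ 2 = 2 bits for every λ ≥ 0. Each structural premise is asserted by
its own test before the separation claim is tested.

## Numerical choices and degenerate inputs

- Laplace smoothing (x+1)/(n+2) for every conditional probability; prior
  clamping as above. Both choices exist solely to keep information finite.
- Node labels are opaque; pairs are canonicalized by native ordering with a
  (type-name, string) fallback so mixed label types cannot crash sorting.
- The sampled-AUC null calibration: with all-equal scores AUC is exactly 0.5.
  With one fixed iid random score assignment, the *exact* AUC is itself a
  null Mann–Whitney draw with sd √((n₁+n₂+1)/(12·n₁·n₂)) — about 0.06 for a
  25-link probe set — so a single assignment is only "approximately 0.5" at
  that scale; averaging over independent assignments recovers 0.5 tightly.
  The acceptance script therefore averages 400 seeded assignments (250
  comparisons each, 100,000 total).
- Problem sizes in tests (graphs of 20–100 nodes, 10⁵ Monte-Carlo trials,
  benchmark repetitions 3–20) were chosen so each check resolves its
  tolerance comfortably while the whole suite stays interactive.

## Known limitations

- Undirected, unweighted, simple graphs only; no attribute-based prediction.
- The conditional estimators assume feature-variable independence; densely
  overlapping neighborhoods violate it, and scores then double-count shared
  evidence.
- Scoring all candidate pairs is O(|V|²) pairs × local-neighborhood work —
  fine up to tens of thousands of nodes, but no sparse top-k shortcut is
  implemented.
- λ and ε are fixed constants, not fitted; λ = 0.1 is a robust default, not
  an optimum for any particular network.
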