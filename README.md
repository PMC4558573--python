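# nsilink

Information-theoretic link prediction for undirected simple networks —
protein-interaction maps, neural wiring diagrams, ecological webs, social
graphs — anywhere the observed edge list is incomplete and you want to rank
the unobserved node pairs by how likely they are to be true links.

## The model

Link prediction is framed as evaluating the *conditional self-information* of
the connection event. For a candidate pair (x, y), let L¹ₓᵧ denote "x and y
are connected" and let Ω be the set of feature variables extracted from some
structural feature (for example, the common neighbors of x and y). The
likelihood score is

```
s(x, y) = −I(L¹ₓᵧ | Ω)
```

and under independence of the feature variables,

```
I(L¹ₓᵧ | Ω) = I(L¹ₓᵧ) − Σ_{ω ∈ Ω} [ I(L¹ₓᵧ) − I(L¹ₓᵧ | ω) ]
            = prior information − Σ information gains.
```

Several features Ω₁, …, Ω_k combine additively with weights λᵢ:
`s = −Σᵢ λᵢ · I(L¹ₓᵧ | Ωᵢ)`.

The **Neighbor Set Information (NSI)** index instantiates this with two local
features — the common neighbors of the pair, and the links running across the
two neighbor sets — with weight ratio λ = λ₂/λ₁ (default 0.1):

```
s_NSI(x, y) = −(1 + λ)·I(L¹ₓᵧ) + Σ_{z ∈ CN(x,y)} gain(z) + λ·Σ_{l ∈ cross(x,y)} gain(l)
```

The prior is the degree-based placement probability
`p(L¹ₓᵧ) = 1 − C(M − kₓ, kᵧ)/C(M, kᵧ)` (M training links); each common
neighbor's conditional is its Laplace-smoothed clustering statistic
`c_z = (N_Δz + 1)/(N_Δz + N_Λz + 2)`; each cross link's conditional mirrors it
over the node pairs the edge bridges. Unlike count-based indices, two
common neighbors with equal degree but different clustering contribute
*differently* — a shared neighbor whose neighborhood is tightly knit is
stronger evidence of a link.

Also included: the single-feature **Mutual Information (MI)** index and five
classical baselines — Common Neighbors (CN), Adamic–Adar (AA), Resource
Allocation (RA), Preferential Attachment (PA), Local Path (LP, ε = 0.001) —
plus a full evaluation harness: random 90/10 train/probe splits, sampled and
exact AUC, Precision@L (default L = 100), and a repeated-benchmark runner
reporting mean(sd×10⁴) tables.

## Worked example

Generate a small-world benchmark graph, rank its candidate links, and
benchmark four indices over 20 random 90/10 splits:

```bash
nsilink generate --model watts_strogatz --n 100 --k 6 --p 0.1 --seed 2 --out ws.edgelist
nsilink predict ws.edgelist --index NSI --top-k 3 --out ws_scores.csv
nsilink evaluate ws.edgelist --index CN --index LP --index MI --index NSI \
    --reps 20 --seed 5 --auc-samples 20000 --out bench.json
```

The predict step logs the three top-ranked candidate pairs (scores are
negative conditional self-information in bits; higher = more likely):

```
27  31  5.2326
54  58  5.16182
55  59  5.14444
```

and the evaluate step prints a benchmark table (AUC/Precision@100 means over
20 splits, standard deviations ×10⁴ in parentheses):

```
index   auc         precision
CN      0.882(279)  0.125(166)
LP      0.898(319)  0.114(191)
MI      0.801(442)  0.102(203)
NSI     0.804(430)  0.097(241)
```

All four indices sit far above the chance level of 0.5 on this clustered
graph: a randomly hidden tenth of the edges is recovered ahead of random
non-edges roughly 80–90% of the time. The same pipeline is available from
Python (`load_edge_list`, `score_all`, `split_train_probe`, `run_benchmark`,
…); real networks are supplied as plain edge lists (two whitespace-separated
labels per line, `#` comments).

Where LP sees only path counts, NSI reads the clustering around each common
neighbor: `nsilink.lp_tie_fixture()` builds a graph with two candidate pairs
that LP scores identically for *every* ε but NSI separates for every λ ≥ 0,
in the direction of the pair whose shared neighbors cluster more.

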