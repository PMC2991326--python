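# Methods

## The model

An AP-MS pull-down on a bait protein recovers not only the bait's direct
physical partners but everything connected to it through chains of
simultaneous contacts.  `ppidecon` models the hidden direct-interaction
network as a probabilistic graph G = (V, E): every direct interaction
survives the purification independently with a uniform probability p̂
(default 0.5), and the quantity a saturating experiment observes for a
pair (u, v) is the probability P_G(u, v) that u and v remain connected in
a random realization — the *two-terminal reliability* of the pair.  The
symmetric matrix of these probabilities is the **connectivity matrix**.
Exact computation of P_G is #P-complete, so matrices are estimated by
Monte-Carlo sampling: one connected-component labelling per realization,
all same-component pairs incremented at once (realizations are batched
into one block-diagonal sparse labelling call).

The inference problem is the inverse: given an observed matrix M and a
tolerance δ, find the graph G maximizing the number of pairs with
|P_G(u, v) − M(u, v)| ≤ δ.

### Tolerances

A Monte-Carlo entry is a binomial proportion; its worst-case (p = 0.5)
95% half-width is δ = z₀.₉₇₅ / (2√n): 0.007 at n = 20,000 (input
matrices) and 0.04 at n = 500 (fitness evaluations inside the genetic
algorithm).  δ is attached to every matrix at creation.

Where the method compares an observed entry with a model value, the
window is widened beyond a single 95% interval, because hundreds of such
comparisons run per matrix and a per-test 5% miss rate would
systematically break detectors that are exact in the noiseless limit:

* equality tests against p̂ (cut-edge condition (i)) use ±2δ (≈3.9
  standard errors — family-wise safe for the few hundred true edges
  tested);
* products of three estimated factors (cut-edge condition (ii), degree-2
  condition (iii)) use τ = 3δ, absorbing first-order error accumulation;
* one-sided bounds stated by the theory with a "+δ" allowance keep it.

On exact matrices (δ = 0) every test reduces to an exact comparison.

## Phase I — weakly connected vertices

**Cut edges.**  A pair (u, v) is a cut edge (bridge) iff M(u, v) = p̂ and
the partition V_u = {x : M(x, u) ≥ M(x, v)}, V_v = complement satisfies
M(s, t) = M(s, u)·p̂·M(v, t) for every cross pair — connectivity
factorizes across a bridge.  Detection is recursive: split the matrix on
a detected cut edge and recurse into both sides (removing a bridge leaves
within-side entries unchanged).  A vertex reduced to a singleton with at
least one incident cut edge is a *1-cut vertex*; on a tree matrix the
recursion reconstructs the entire graph.

When several candidate pairs qualify inside one sub-problem, the split
uses the pair with the smallest factorization residual
max|M(s,t) − M(s,u)·p̂·M(v,t)| rather than lexicographic order: a
bottleneck through a nearby cut vertex x (series product
P(u,x)·p̂ ≈ p̂ when P(u,x) ≈ 1) can pass the tolerance test, and the true
bridge always carries the noise-level residual.  Pairs with P(u,x) within
noise of 1 remain genuinely ambiguous at finite sample size; the method
then attributes the bridge to one of the probabilistically
indistinguishable endpoints.

**Degree-2 vertices.**  A degree-2 vertex s with neighbours u, v
satisfies three necessary conditions: (i) M(s, t) < 2p̂ − p̂² for every t
(it disconnects when both its edges fail); (ii) its two largest row
entries are equal and belong to u and v; (iii) M(s, t) <
max{M(u, t), M(v, t)} for every other t.  Flagged vertices are marked,
not removed — removing them would perturb the remaining entries.  The
two argmax entries define the predicted edges.  An exact three-way tie
(a star centre on an exact matrix) is ambiguous and rejected; on sampled
matrices a third entry may fall within noise of the top pair, in which
case the stable argmax pair is kept and the predicted neighbour can
occasionally be wrong — this is the source of the detector's small
false-discovery rate and is tolerated.

The two detectors run alternately to a fixpoint; what survives is the
densely connected **hard core** (in scale-free networks roughly 25–30%
of the vertices).

**Reduction.**  Chains of flagged degree-2 vertices between two core
vertices are contracted to *meta-edges*: k parallel forced paths of
lengths L₁..L_k join their endpoints with survival probability
1 − Π(1 − p̂^{L_i}).  A chain that branches or shares an interior vertex
with another chain violates the independence behind parallel composition
and is left unmerged.  Every pair incident to a flagged vertex other than
its two predicted edges is forbidden; every core pair (including pairs
already carrying a meta-edge — the bundle encodes forced chains, a
*direct* edge between the same endpoints is still undetermined) is a
candidate with a stable integer index.

## Phase II — dense regions

Within a k-clique every pair is connected with probability at least
CliqueConn(k, p̂), the two-terminal reliability of K_k, because structure
outside the clique can only raise connectivity.  Thresholding M at
t_k = CliqueConn(k, p̂) − δ and enumerating maximal cliques of size ≥ k
per connected component therefore finds every true k-clique (the δ slack
keeps the guarantee under sampling noise at 95% confidence); dense
quasi-cliques pass the same filter, so false discoveries are expected and
tolerated — regions only seed and guide the genetic search.  The default
sweep is k = 7, 6, 5 with larger-k regions taking precedence; overlapping
regions are merged into disjoint super-regions (union-find) wherever a
partition into blocks is needed.  Components larger than 60 vertices are
reported whole instead of enumerated.

CliqueConn uses the identity
P = Σ_{i=2..k} C(k−2, i−2) · C_i(p̂) · (1−p̂)^{i(k−i)}, where C_i(p̂) is
the probability that i labelled vertices induce a connected spanning
subgraph, computed exactly from the edge-generating polynomial of
connected labelled graphs (an integer recurrence; at p̂ = ½ the formula
reduces to the classical count γ_i of connected graphs over
2^{C(i,2)}).  The formula is cross-checked in the tests against exhaustive
subset enumeration up to K₆.

## Phase III — cut-based genetic algorithm

The hard core is searched as subsets of the candidate-pair table
(meta-edges are implicit in every candidate; a candidate must keep each
instance component connected).  Fitness of a candidate is the number of
core pairs whose 500-sample Monte-Carlo connectivity falls within
δ = max(matrix δ, 0.04) of M.  One block of random seeds is shared by all
evaluations within a generation (common random numbers), so ranking noise
is correlated across candidates.

* **Initial population** — vertices enter in a random order biased by
  average connectivity avgCon(u) = (1/|V|)Σ_v M(u, v) (strongly
  correlated with true degree), each newcomer attaching 1–2 candidate
  edges to earlier vertices drawn proportionally to current degree;
  dense-region edges are included in every individual; a greedy repair
  adds the highest-M candidate edges until connected.
* **Crossover** — guided by a sparse balanced cut: dense super-regions
  are contracted to weighted blocks and the blocks are split into two
  sides balanced within 20% (never splitting a block).  The children
  inherit each side's subgraph wholesale and keep crossing edges only
  where both parents agree.
* **Mutation** — independent membership flips with expected flip count
  mutation_rate × |current edges| (default rate 7.5%, within the 5–10%
  band), followed by greedy connectivity repair.  Flip *probabilities*
  are aimed by the candidate's cached residual M − P̂ from its last
  evaluation: a pair the candidate under-connects is the most promising
  insertion, an edge whose own pair it over-connects the most promising
  deletion; crossover children inherit the mean of their parents'
  residuals.  Uniform flips explore a 2^|pairs| space far too slowly for
  desk-scale budgets (in a controlled run they reached ~40% of the
  fitness the true graph attains); aiming the same number of flips closes
  most of that gap without changing the operator's contract.
* **Selection** — parents drawn with probability ∝ fitness − minFit
  (worst candidate weight 0; uniform when all tie); generational
  replacement with 5 elites carried over, so the best-ever fitness
  history is non-decreasing.
* **Budget** — 200 generations (default) or a wall-clock cap, whichever
  first.

The final prediction is the union of the detected cut edges, the
degree-2 edges, the meta-edges re-expanded into their constituent chains,
and the GA-selected candidate pairs.

## Synthetic networks

Two growth models emulate scale-free interaction networks, at the sizes
and densities the evaluation uses:

* **Preferential attachment (PAM)** — seed edge; every new vertex
  attaches 1 or 2 edges (uniform, expected 1.5) to degree-proportional
  targets.  At n = 1000 this yields ≈1500 edges.  Structurally, a new
  vertex contributes at most two edges, so no K₄ ever closes: the clique
  number is ≤ 3 and no edge lies in a 5-clique.
* **Duplication model (DM)** — seed triangle; each step duplicates a
  degree-proportional vertex, retaining each copied edge with probability
  0.5 (redrawn when nothing survives, so the graph stays connected; the
  duplicate is not joined to its parent).  Duplication copies shared
  neighbourhoods, giving far more triangles and dense clusters than PAM.
  With these rules the edge count at n = 1000 lands in the tens of
  thousands rather than the ~2000 of a comparably sized biological
  network; the mechanism as described is denser than the networks it is
  meant to emulate, and the tests assert its structural properties
  (connected, simple, triangle-rich) rather than a density band.

What the generators do *not* emulate: measurement noise other than
edge-survival sampling, non-uniform interaction strengths, protein
misidentification or contaminants — passing tests therefore demonstrate
correctness of the inference under the stated survival model, not
robustness to the full error structure of real AP-MS data.

## AP-MS quantification

Peptide counts are biased toward long proteins; each count is divided by
the prey's sequence length (the count being prey-specific) to give
abundance ratios R(i, j), reciprocal observations are averaged, and the
symmetrized ratios are mapped through a logistic
M(i, j) = 1/(1 + e^{−(R−α)/β}) with shipped defaults α = 2.8921,
β = −0.6318.  Two deliberate choices: (1) unobserved pairs map to 0 —
an absent observation carries no evidence of connectivity, whereas the
logistic at R = 0 with the default parameters would assert ≈0.99;
(2) the negative default β makes the map *decrease* with the normalized
count, which looks inverted relative to the model's intuition — the
implementation follows the fitted constants but exposes the sign.
Parameter fitting minimizes the χ² distance between the histogram of
transformed values (20 equal-width bins on [0, 1]) and a reference
connectivity distribution; because the binned objective is piecewise
constant, a small quantile-matching term breaks plateau ties, and the
search is seeded differential evolution over both β signs with a
Nelder-Mead polish.

## Exact oracles and numerical choices

* `exact_connectivity` factorizes over the block-cut tree: reliability
  within each biconnected block by subset enumeration (exact dyadic
  floats at p̂ = ½), series-multiplied along the unique path of blocks.
  Blocks above 22 edges (configurable) are refused — the enumeration is
  exponential and the cap bounds it at ~4M subsets.
* Ties and degenerate inputs: vertices sort by a deterministic key;
  equal-fitness bests keep the first encountered; a core that contracts
  to fewer than two blocks, or admits no balanced block partition within
  20%, raises a degenerate-cut error and the GA falls back to cloning
  parents; an empty candidate table short-circuits the GA.
* Determinism: every run derives all randomness from one master seed via
  child streams; identical seeds give bit-identical matrices, populations
  and histories.

## Problem sizes used in the shipped evaluation

The method is designed for networks of a thousand proteins with
hours-long search budgets; the shipped evaluation scales this to desk
size.  The 1-cut exactness benchmark uses 200-vertex PAM networks with
20,000-sample matrices; the end-to-end comparison uses 150-vertex PAM
networks, a GA of 150 individuals for 60 generations (minutes), 1500
hill-climbing iterations, and reports the mean of three replicate
networks because a single 150-vertex realization swings the rates by
several points.  At this scale the pipeline lands at roughly 25-30%
overall FDR/FNR while pure hill-climbing sits above 90%; larger networks
resolve a greater share of their vertices in Phase I and correspondingly
more of the error budget shifts to the core.

## Known limitations

* Uniform p̂ and simultaneous, independent interactions are modelling
  fictions; correlated edge failures make direct/indirect separation
  near-impossible and are out of scope.
* Degree-2 prediction is necessary-condition screening: rare
  higher-degree vertices pass it, and on noisy matrices a predicted
  neighbour can be wrong; both kinds of error corrupt the reduced
  instance the GA sees and dominate the end-to-end error at desk scale.
* Bridges whose far endpoint connects to an alternative vertex with
  reliability within noise of 1 are not identifiable from the matrix.
* The dense-region detector reports quasi-cliques as cliques by design;
  its output is guidance, not a final claim.
* The hard core is only weakly identifiable at δ ≈ 0.04 fitness
  tolerance: materially different graphs can fit M equally well, which
  bounds what any search can achieve on the core.
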