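# Methods

## Model and state space

Tumor sites are treated as biogeographic areas; a lineage's geographic
range is a non-empty subset of sites with at most two members. The state
space therefore contains C(n,1) + C(n,2) ranges for n sites (3 for n = 2 up
to 66 for n = 11), ordered canonically (singletons by area id, then pairs
lexicographically) so matrix indices and serialized output are stable. Two
conventions follow from how clones are sampled: the null (empty) range is
removed — a clone exists at least at its sampling site — and, because the
null range is removed, singleton ranges have no extinction exit, which
makes the anagenetic generator Q conservative (rows sum to zero) and every
P(t) = exp(Qt) a proper stochastic matrix.

Anagenesis is a CTMC with two rates, both per unit branch length: *d*, the
rate of adding one specific area to the range (so a singleton in an n-site
system has total expansion rate (n−1)d), and *e*, the rate of losing one
occupied area from a widespread range. No distance-dependent dispersal
multipliers or time stratification are modeled: uniform d for every area
addition.

Cladogenesis distributes a parent range R to ordered daughter pairs:

* **BAYAREALIKE** — (R, R) only; ranges never change at nodes.
* **DEC** — singleton parents are copied; widespread parents undergo subset
  sympatry ({a}, R) / (R, {a}) for each a ∈ R, or vicariance into disjoint
  subsets (with max range size 2, both daughters are singletons).
* **DIVALIKE** — as DEC but without subset sympatry.

The `+J` variants add founder events (R, {x}) and ({x}, R) for every site
x ∉ R. Every allowed non-jump ordered event has weight 1 and every jump
event weight j, normalized per parent. This is the simplest scheme in which
all allowed non-founder events are equiprobable and j acts as a relative
founder propensity; it is *not* numerically identical to other
parameterizations that rescale non-jump weights as j grows, so absolute
log-likelihoods are comparable only within this package. Model ranks, LRTs
on nested pairs, and ancestral annotations are the meaningful outputs. At
j = 0 the jump events vanish exactly, making each +J model contain its base
model identically — the nesting the LRT relies on.

## Likelihood, fitting, and model comparison

Tip conditionals are indicators of the observed singleton range (clones
reported in more than one site are pre-split beforehand, see below).
Felsenstein pruning propagates conditionals through P(t) along branches and
through the cladogenetic table at nodes; per-node rescaling guards against
underflow. The root combines its two children through the same table and is
integrated against a uniform prior over all ranges — the common default in
the absence of prior knowledge, and one that preserves exact nesting
between base and +J models. Trees must be binary (polytomies are rejected,
degree-2 pass-through nodes are collapsed by branch-length addition); tips
attached by zero-length branches represent ancestral clones and need no
special treatment since P(0) = I.

P(t) for the many branch lengths visited during optimization is computed
from one spectral decomposition of Q per parameter proposal, with an
automatic fallback to a dense scaling-and-squaring matrix exponential per
branch when the eigendecomposition reconstruction error exceeds 1e-10
(near-defective Q, e.g. d or e at a bound). State spaces never exceed 66
states, so dense linear algebra is trivial.

Maximization uses bounded L-BFGS-B from a fixed four-point start grid —
d, e ∈ [1e-9, 5] and j ∈ [1e-6, 10] — so fits are deterministic; the best
of the four local optima is reported. A proposal with zero data probability
returns a large finite penalty rather than −∞ so finite differences remain
defined. Information criteria use k = 2 (or 3 with founder events) and
n = number of clone tips: AIC = 2k − 2lnL, AICc = AIC + 2k(k+1)/(n−k−1),
BIC = k ln n − 2lnL. Base-vs-+J LRTs use the plain χ²(1) upper tail by
default; since j = 0 lies on the parameter boundary, the conservative 50:50
mixture correction is available as an option but off by default.

Marginal ancestral range probabilities at internal nodes come from a
standard two-pass (inside/outside) algorithm in which the outside pass
distributes the parent's distribution through the cladogenetic events and
the sibling's propagated conditional; marginals are validated in the test
suite against exhaustive enumeration over all ancestral state assignments.

## Annotation, migration paths, and scoring

Each internal node is annotated with its highest-probability range
(argmax of the marginals; exact ties broken by canonical state order and
flagged). Tips keep their observed site with probability 1. For every tree
edge whose parent and child annotations differ, one migration path is
emitted per site present in the child but absent from the parent, with the
parent's full annotated site set as the source. When the source spans two
sites the path is flagged and, during scoring, each source site yields a
candidate pair; credit is given if any candidate matches the truth,
otherwise all candidates count as erroneous — the most permissive reading
of single-source path derivation, applied symmetrically across models.
Paths are classed P→M, M→M, or M→P by the primary-site flag.

Scoring is over directed source→recipient site pairs: TP (inferred and
true), FP (inferred only), FN (true only); precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean (conventions: an empty–empty
comparison scores 1, a one-sided empty comparison 0). The default
"unique-pairs" mode deduplicates repeated pairs before matching — two
clones taking the same route count once — with a "multiset" mode retained
for sensitivity analysis. Per-class correct/erroneous/not-inferred counts
always sum to the overall TP/FP/FN.

## The seeding-scenario simulator

The generator emulates the statistical structure of the standard
80-dataset metastatic-seeding benchmark: 5–7 ("m5") or 8–11 ("m8") tumor
sites, 7–28 clones, 9–99 SNVs, four scenarios. A clone tree is grown
forward: lineages split within their current site, and scheduled migration
events split a source-site lineage into one daughter that stays and one
that seeds the recipient. Scenario semantics:

* **mS** — each metastasis seeded by exactly one clone, all from the
  primary (a single non-primary source would itself need seeding,
  contradicting "single source").
* **pS** — 2–3 seeding clones per metastasis, all from the primary.
* **pM** — 2–3 seeding clones per metastasis, each source drawn from the
  already-colonized sites; at least two distinct source sites guaranteed.
* **pR** — as pM plus reseeding edges into already-colonized sites, always
  including at least one edge back into the primary.

Colonization order is a random permutation of the metastases, so sources
are always colonized before they seed and the truth graph connects the
primary to every metastasis. When the 28-clone budget cannot accommodate
all polyclonal seeding events (large m8 configurations), surplus seeding
clones are trimmed, never below two per recipient.

SNVs follow the infinite-sites model: each variant arises once on one
branch, genotypes are the union of root-path variants, and branch lengths
are per-branch SNV counts divided by the total SNV count (mutations per
site as a time proxy; the implied outgroup carries no mutations). Each
migration branch carries at least one private SNV — a founding clone is a
genotypically distinct clone — which also guarantees every dataset has
positive likelihood under the copy-only BAYAREALIKE cladogenesis (a forced
site change across a zero-length branch would otherwise have probability
exactly zero). Genotype matrices are homoplasy-free by construction and
admit a perfect phylogeny; the test suite re-derives the generating
topology by exhaustive maximum parsimony on small instances.

What the generator does *not* emulate: clone-size dynamics, driver
selection, sequencing noise, or clone-phylogeny estimation error (analyses
assume the true tree, as in the benchmark it mirrors). Passing benchmarks
here therefore speak to the inference machinery under correct trees and
clean genotypes, not to robustness against phylogeny error.

`make_benchmark(n_per_cell, seed)` produces the factorial (m-group ×
scenario) design; 10 per cell reproduces the classic 80-dataset layout.
The acceptance script uses 2 per cell (16 datasets) to keep a single-CPU
run in the minutes range; the aggregate pattern (fit ranks, F1 ordering,
multiple-range collapse under +J) is already stable at that size.

## Model-based simulation and parameter recovery

`simulate_under_model` is the generative counterpart of the likelihood:
uniform root state, cladogenetic events sampled from the normalized table,
Gillespie simulation of the anagenetic CTMC along exponential branches
(default mean 1.5, Yule-style topology). Each tip reports one sampling site
drawn uniformly from its realized range; the full realized range is also
exposed.

The recovery experiment in the acceptance suite (50 replicates, 20 clones,
4 sites, DEC at d = 0.2, e = 0.05, mean branch length 6.0 chosen a priori
so that several extinction events are expected per tree) observes the full
realized tip range via the multi-site pre-split convention. This choice is
deliberate and worth recording: if a tip whose true range spans two sites
is instead collapsed to a single sampled site, the likelihood must invoke a
spurious contraction on that terminal branch, and the extinction-rate
estimate is driven to its upper bound — we verified ê = 5.0 (the bound)
across branch-length regimes under singleton-collapsed observation, while d̂
remains accurate either way. This is the estimation-side mirror of the
motivation for pre-splitting multi-site clones in empirical data. Under
range-faithful observation both rates recover within a factor of 2 in the
median, and the base-vs-+J LRT detects a true founder weight j = 1 with
power near 1 at α = 0.05.

## Numerical conventions and edge cases

* Annotation tie tolerance 1e-9 (relative); ties flagged, broken by
  canonical state order.
* Optimizer convergence: L-BFGS-B ftol 1e-10, gtol 1e-8; four fixed starts;
  `converged` reports optimizer success, and boundary estimates (d at 1e-9,
  e at 5) are legitimate MLEs on short mutation-scaled trees, not failures.
* AICc degenerates to +∞ when n ≤ k + 1 (fits remain comparable by AIC).
* Geography files use the PHYLIP-style presence-matrix dialect
  (`n m (labels)` header, 0/1 rows) for interoperability with existing
  biogeography tooling; exactly one presence per row after pre-splitting.
* All randomness flows through numpy Generators seeded from explicit
  configuration; identical seeds give byte-identical datasets and outputs.

## Known limitations

* Ranges are capped at two sites (configurable, untested beyond two); with
  many-site colonization histories the cap can force sequential paths.
* The cladogenetic weight convention differs from packages that rescale
  non-jump weights with j; absolute lnL values are not cross-package
  comparable (ranks and annotations are).
* No confidence intervals on (d, e, j) and no Bayesian fitting.
* Migration timing within a branch is not resolved — paths are attributed
  to edges, not to positions along them.
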