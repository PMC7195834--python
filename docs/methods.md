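# Methods

This note documents the models and algorithms implemented in `vicarange`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that affect
results.  Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic data (`vicarange.simulate`)

The generator emulates a single-locus phylogeographic study of a
dispersal-limited freshwater clade: ~10 species sampled for a ~1.1 kb
protein-coding mitochondrial marker, distributed over a handful of endemic
areas arranged on an adjacency graph, with tree depths on a 0–30 Ma scale.

**Dated tree.** Forward Gillespie birth–death simulation from two root
lineages, conditioned on the extant count reaching `n_species`: when the
count first equals the target, the stop time is drawn uniformly within the
interval during which the count stays there; extinct lineages are pruned
(suppressing unifurcations) and trees whose pruned root age exceeds
`root_age_bound` (default 30 Ma) are rejected.  Defaults `birth_rate=0.3`,
`death_rate=0` events/lineage/Ma give 10-tip trees with root ages of a few
Ma to ~20 Ma.  Non-viable parameter combinations fail after a bounded
number of rejection attempts.

**Biogeographic history.** The root receives a single random area (or a
caller-supplied set).  Along each branch a lineage occupying set *S*
disperses into an unoccupied area adjacent to *S* at total rate
`dispersal_rate` (0.1/lineage/Ma default; target uniform among candidates)
and loses one occupied area at total rate `extinction_rate` (0.3 default)
whenever |*S*| > 1 — ranges never empty.  At nodes, multi-area sets split
by a uniformly random ordered disjoint bipartition (vicariance, matching
the zero-cost cladogenetic events of the reconstruction stage);
single-area sets duplicate.  The event log records, for cladogenetic
events, the set inherited by each daughter, so the entire history can be
replayed from the log alone (a test oracle).

**Alignment.** HKY (default κ=4, unequal base frequencies) with the rate
matrix scaled to one expected substitution per site per unit branch
length.  Strict clock: every branch evolves at `clock_rate_mean`
(default 0.01 substitutions/site/Ma); relaxed: i.i.d. lognormal branch
rates with that real-space mean and SD `relaxed_sd`.  The root sequence is
drawn codon-wise from the stationary frequencies, rejecting the vertebrate
mitochondrial stop codons (TAA, TAG, AGA, AGG) in frame 0, so the
quality-control stage sees a clean coding frame at low divergence.
Haplotype sampling within species is emulated by grafting shallow
random-join clades (crown depth uniform within `within_species_depth`,
default 0.15 Ma, and always inside the terminal branch) onto species tips;
full coalescent gene-tree simulation is deliberately out of scope, as are
indels and selection.

With a fixed seed all generators are bit-reproducible.

**What passing tests on these data do not show.** The generator has no
rate heterogeneity across sites, no saturation beyond what HKY implies, no
misalignment or missing data, and its within-species structure is a
caricature of a coalescent.  Recovery statistics on it validate the
estimators' correctness, not their robustness to real-data pathologies.

## 2. Sequence preparation (`vicarange.seqprep`)

Haplotype identity defaults to exact site-by-site match over the full
symbol alphabet (reproducible and order-independent); `ignore_missing`
skips sites where either record has `-`, `?` or `N` and groups by the
transitive closure of that pairwise relation (union–find).  The coding
check translates in a caller-chosen frame under an NCBI genetic-code table
(vertebrate mitochondrial, id 2, by default — appropriate for cytochrome
b), reporting internal stops and untranslatable codons; a terminal stop is
not a violation.

## 3. Node dating (`vicarange.dating`)

Node ages are estimated on a **fixed rooted topology** — the package's
dating question is about ages given a well-supported topology; topology
search is out of scope.

*Posterior.* `p(t, r, κ, α | D) ∝ P(D | ·) · p(t) · Π_c N₊(t_c; μ_c, σ_c)
· p(r) · p(κ) · p(α)` with

- **Likelihood:** Felsenstein pruning under HKY+Γ on compressed site
  patterns, branch lengths `r_e · Δt_e`.  An incremental engine caches
  per-node transition matrices and scaled partials so a node-age proposal
  only recomputes its root path; its output is tested to 1e-9 against the
  plain implementation and the plain implementation to 1e-8 against
  brute-force summation over all ancestral states.
- **Tree prior:** pure-birth style density `λ^(n−1) e^(−λL)` (L = total
  tree length in Ma) with fixed λ (default 0.3/Ma), or a flat ordering
  indicator (`tree_prior="uniform"`).  The literature rarely states
  tree-prior hyperpriors for this kind of analysis; fixing λ keeps the
  prior explicit and cheap, and the synthetic dating experiments generate
  their trees under the matching pure-birth process.
- **Calibrations:** normal densities truncated at 0 Ma on the MRCA of
  named tip sets.  The five stock schemes carry the standard constraint
  set for the Middle American cichlid problem: I = heroine fossil
  (44.25 ± 2.7 Ma) + Cuba–Hispaniola split (22.5 ± 1.5) +
  Orinoco–Magdalena separation (10.95 ± 0.6); II drops the fossil; III is
  fossil-only; IV is the secondary *Caquetaia*-split calibration (23 ± 2);
  V is the barrier calibration itself (7.5 Ma; the source gives a point
  age, so the SD defaults to 0.5 and is configurable).
- **Clock:** strict (one rate, diffuse lognormal hyperprior, median 0.01,
  σ=2) or UCLN (i.i.d. lognormal branch-rate multipliers with mean 1,
  stdev σ ~ Exponential(1)).
- **Substitution nuisances:** κ sampled with a lognormal prior; the
  discrete-Γ shape α sampled (Exponential(1)) when `gamma_ncat > 1`.
  Desk-scale experiments use one rate category to match the generator.

*Sampler.* Metropolis-within-Gibbs sweeps: each internal node age proposed
uniformly within (oldest child, parent) — a symmetric bounded move — with
a multiplier move for the root; multiplier moves for rate(s), κ, α and the
UCLN σ.  Post-burn-in draws (default 25% burn-in, thinning 2) are
summarised by medians and shortest-interval HPDs; effective sample sizes
use the initial-positive-sequence autocorrelation estimator and small
values are flagged, not fatal.  Prior-only sampling (likelihood off) under
the flat tree prior reproduces the calibration priors at calibrated nodes
within Monte-Carlo error — the standard sampler-correctness check.

*Model choice.* Marginal likelihoods by stepping-stone sampling over power
posteriors spaced as Beta(0.3, 1) quantiles (32 rungs by default; tests
use 8–12 with short chains).  Stepping stone replaces fancier estimators
because the decision target is simply the ranking of clock models, and the
estimator's Monte-Carlo SE is reported with the ranking.

*Experiment sizes.* The coverage experiment uses 20 replicates of 10-tip
strict-clock datasets (1,137 bp) at 2,500 sweeps; the end-to-end barrier
test uses 20 replicates of an 8 + 1 + 1-tip design (focal split at 14 Ma,
root calibrated at its true 20 Ma) at 1,500 sweeps.  These sizes give
stable pass/fail behaviour at desk scale; larger chains sharpen the same
conclusions.

## 4. Species delimitation (`vicarange.delimit`)

**GMYC (single threshold).** Internal node ages are ordered oldest-first
(ties broken parent-before-child, then by clade content, so results are
invariant to tip relabeling).  Taking the k oldest nodes as the
between-species (Yule) phase defines k+1 clusters; the interval likelihood
is `Σ_i [event_i]·log b_i − b_i x_i` with
`b_i = λ_Y k_i^{p_Y} + λ_C Σ_j (n_{j,i}(n_{j,i}−1))^{p_C}`, including the
event-free final interval down to the tips as a censored survival term.
Rates are fitted by Nelder-Mead per candidate k; the exponents default to
1 (configurable) for stable desk-scale fits.  The null model is the
single-process fit (k = n−1); the LR is referred to a one-tailed χ² with
df = 2 by default (configurable, and the raw LR is always reported).  When
the threshold model is not significant at α = 0.05 the reported partition
is the null's — every branching is diversification and every tip its own
entity; `alpha=None` returns the raw ML partition.  The gate matters: under
the pure interval likelihood the all-singleton solution is always weakly
dominated (absorbing the youngest cherry into a cluster with λ_C→0 leaves
all event terms unchanged and improves tail survival), so "no significant
clustering" is the model's honest way of saying "all singletons".

**PTP-style delimitation.** On substitution-scaled trees, a species
partition is a set of crown nodes covering every tip exactly once; edges
strictly inside crowns are within-species, all others between-species, and
each class gets an exponential length model with its rate profiled out.
Two identifiability constraints: the single-class partition spanning the
root is excluded, and the within-class mean must be strictly shorter than
the between-class mean (coalescent branches are shorter than speciation
branches) — without them the two-class ML degenerates onto tiny edge
subsets.  Search: greedy hill-climbing (split a crown into its children /
merge sibling crowns) from 50 seeded random starts plus the all-singleton
start; exact ties break toward fewer species.  On 4-tip trees the search
provably matches exhaustive enumeration over all valid partitions (tested).

**Recovery regime.** Both delimiters are validated on trees with deep
species divergences (all interspecific nodes ≥ 1 Ma, enforced by
rejection) and shallow intraspecific clades (≤ 0.15 Ma), 5 species × 8
haplotypes — proportions mirroring a well-sampled single-locus study.  For
PTP the tree is rescaled to substitutions (duration × 0.01/site/Ma ×
lognormal jitter, σ=0.3), which yields between- and within-species length
classes roughly an order of magnitude apart.  Under literal i.i.d.
two-class exponential lengths at a 10× ratio, exact-count ML recovery is
intrinsically ~60% — the classes overlap enough that boundary edges
misclassify at ~5–10% each — which is a property of the model, not the
search (hill-climbing finds the global optimum in the tested cases).

**Concordance.** Per reference species and method: `exact` (one cluster
equals the species), `split`, `merged`, or `mixed`; the consensus count is
the number of species exact under every method.  The multispecies
coalescent delimitation enters only as an externally supplied partition.

## 5. Ancestral areas (`vicarange.diva`)

DIVA is formalised as a Sankoff dynamic program over all nonempty area
subsets of size ≤ `maxareas` (bitmask representation, ≤ 16 areas):
cladogenesis is free for vicariance (ordered disjoint bipartition of the
ancestral set) and duplication (single-area ancestor inherited by both
daughters; an optional relaxed mode also allows a widespread daughter plus
subset), and the branch cost from inherited set *S* to child set *C* is
the symmetric difference |C∖S| + |S∖C| (dispersals + extinctions, one
event unit each).  Area adjacency is deliberately **not** part of the
cost — classic dispersal–vicariance analysis is adjacency-blind — and
enters only in the extinction-inference stage.

An up-pass/down-pass over the DP yields, per node, **every** area set that
participates in some globally minimal reconstruction, with uniform
conditional frequencies; ties are never broken silently.  A brute-force
enumerator over all ancestral assignments serves as an independent
reference and agrees exactly on 1,000 random 4-tip/3-area instances.

S-DIVA summaries match nodes across a tree sample by tip bipartition and
average the per-tree uniform distributions over the trees containing the
bipartition; `clade_support` records the occurrence fraction, and
support-weighted frequencies sum to that fraction (within-node conditional
frequencies always sum to 1).  `maxareas` sensitivity reports, per node,
whether optimal sets agree across the requested settings, lists
per-setting alternatives where they differ, and flags settings smaller
than the largest tip range as rejected.  Minimal cost is non-increasing in
`maxareas`, and reconstructions are equivariant under area relabeling
(both tested).

## 6. Extinction inference (`vicarange.extinction`)

The rule: a node whose daughter ranges overlap, or contain any
graph-adjacent pair of areas, is vicariant and needs no extinction;
otherwise the split implies dispersal followed by local extinction in the
intervening areas — the union of the interiors of **all** shortest
adjacency paths between the two ranges at the minimal range-to-range
distance (a `single_path` option keeps one path for minimal-extinction
counting).  When equally optimal DIVA sets disagree on the verdict the
node is reported `ambiguous` with per-reconstruction verdicts, never
averaged away.  Each postulated extinction in area *x* at node *v* is
dated to the stem branch [age(parent(v)), age(v)] (the root uses its own
age); the stem convention is configurable in interpretation but is the
one under which a reconstructed range gap must have arisen.

Detectability limit: the rule can only see losses that sever a range
between two daughter clades and that DIVA places on the stem of the
classified node.  Free-running histories lose areas mostly at range edges,
leaving no non-adjacent disjunction; the planted-loss recovery experiment
therefore plants the detectable scenario (widespread ancestor loses the
middle area on a stem, then splits across the gap), where the inferred
window contains the true loss time in ≥ 90% of replicates.  On histories
simulated with zero extinction and adjacency-respecting dispersal, fewer
than 10% of nodes (empirically ~0–1%) are called
dispersal-with-extinction.

## 7. Sea level and elevation (`vicarange.sealevel`)

Elevation grids (plain-text ESRI ASCII format) are classified into three
habitat classes with the boundary conventions `< sea_cut` (strict),
`sea_cut ≤ e ≤ upland_cut` (inclusive), `> upland_cut` (strict); defaults
60 m (Neogene high-stand ceiling) and 1,000 m (the usual altitudinal limit
of the study group).  Habitat connectivity uses 4-connectivity by default
(rivers and lowland corridors share edges, not corners; 8-connectivity by
flag).  Connectivity is monotone in the *refinement* sense: as sea level
drops, habitable area grows and every component at the higher level lies
inside exactly one component at the lower level.  The raw component count
is **not** monotone — a dropping sea can expose isolated new islands — so
the tests check the refinement property, which is what "more land means
more merging" actually guarantees.

High stands are extracted from a piecewise-linear sea-level curve with
crossing ages solved exactly on each segment (verified against closed-form
segment algebra to 1e-9); a curve sitting exactly at the threshold yields
one full-domain interval (documented edge case).  Interval concordance
reports the overlap fraction (summed overlap / summed target length) plus
a one-tailed permutation p-value whose null repositions each target
interval uniformly, length-preserving, within [0, root_bound]; at least
100 permutations are required, and the null mean matches the closed-form
uniform-shift expectation (tested).  The permutation test is this
package's own formalisation of what is usually argued visually; the raw
overlaps are always reported alongside it.

## 8. Orchestration (`vicarange.pipeline`)

`run_pdm_test` dates the focal split under every requested calibration
scheme and applies an explicit verdict rule, stated verbatim in the
report: *predates barrier* iff the minimum 95% HPD lower bound across
barrier-free schemes exceeds the barrier window's older bound (default
window 5–7.5 Ma); barrier-calibrated schemes are reported for contrast
only.  `run_biogeo_chain` chains DIVA → node classification → extinction
dating → high-stand concordance into one JSON report.  Both reports embed
the resolved configuration and seeds and carry a content checksum; reruns
with the same inputs are byte-identical.

## 9. Known limitations

- Topology is taken as given everywhere; uncertainty in it propagates only
  through the S-DIVA tree-sample summaries.
- The tree prior is a fixed-rate pure-birth density, not a full birth–death
  prior with sampled hyperparameters.
- GMYC support values and Bayesian PTP supports are not computed; the
  delimiters return point partitions plus the GMYC LR test.
- The DIVA DP is exact but exhaustive in subsets; beyond ~16 areas a
  different representation would be needed.
- Extinction inference sees only range-severing losses (section 6).
- The permutation concordance test treats target intervals as independent,
  which is optimistic when extinction windows share tree branches.
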