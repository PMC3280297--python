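# Methods

This note records the statistical model implemented by `pathscope`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Reaction graph and edge weights

The reconstruction's substrate/product relations are collapsed into a
directed reaction–reaction graph: u → v whenever some compound produced by
u is consumed by v. Stoichiometric coefficients are deliberately ignored —
the analysis asks which *pathways of co-expression* exist, not which flux
distributions are feasible. Seventeen currency compounds (H+, CoA, H2O,
CO2, orthophosphate, ATP, ADP, AMP, FAD, FADH2, GDP, GTP, NAD, NADH, NADP,
NADPH, UTP) are matched by compartment-free base name and removed before
any edge is drawn; without this step the cofactor pool connects nearly
everything to everything. Reversible reactions contribute connectivity in
both directions. Parallel mediations between the same reaction pair
collapse to one edge (all mediating compounds retained as metadata).

Edge weights are the maximum Pearson correlation over all gene pairs of the
two incident reactions, computed on one condition's time course after
averaging the replicates per time point. Averaging first (rather than
correlating concatenated replicates) matches the time-profile reading of
the data and suppresses replicate noise at the cost of per-point degrees of
freedom; with 6–12 time points this is the stabler choice. Reactions
without measured genes produce no weighted edge (configurable to receive
the network's median weight instead); zero-variance genes are skipped
pair-wise.

## Path score and significance

All edge weights of the network define an empirical weight distribution.
Two tail functionals of it appear in the package:

* `EdgeWeightECDF.cdf`, the right-closed lower tail F(w) = #{weights ≤ w}/m,
  reported for descriptive purposes;
* `EdgeWeightECDF.upper`, the right-closed upper tail u(w) = #{weights ≥ w}/m,
  which drives significance. Right-closure means no observed weight ever
  maps to 0, keeping logarithms finite.

A path of length L (L weighted edges; the pseudo-edges attaching the
terminal compounds carry no weight) has score −Σ ln u(wᵢ) ≥ 0 and product
q = Π u(wᵢ) ∈ (0,1]. Under the null that the L weights are independent
draws from the network's weight distribution, each u(wᵢ) is approximately
Uniform(0,1), so

    p = P(Π Uᵢ ≤ q) = q · Σ_{k<L} (−ln q)^k / k! = P(Gamma(L,1) ≥ −ln q),

implemented through the regularized incomplete gamma function. The formula
is strictly increasing in q, equals q at L = 1 and 1 at q = 1, and is
verified in the test suite against direct Monte-Carlo simulation of
uniform products and against the explicit series to 1e−10.

Maximizing the score at fixed length is equivalent to minimizing p at that
length, which is what makes the per-length dynamic program sufficient:
keep, for every length 1…Lmax, the best-scoring walk, then evaluate p for
each and take the minimum. Ranking by raw score alone would always favor
short paths (every additional edge costs score); the length-indexed p-value
is exactly the correction for that bias.

**Walks versus simple paths.** Finding the best *simple* path per length is
NP-hard, so the recurrence runs over walks with states = (last edge), which
structurally forbids immediate backtracking u → v → u. Reconstructed
best walks that revisit a node are discarded in score order (up to ten
reconstruction attempts per length) and the length falls back to its next
best simple walk or is dropped. Ties break deterministically toward the
predecessor edge with the lexicographically smallest source reaction;
across lengths, toward the shorter path, then lexicographic order.

The single forward pass from a source-reaction set serves every candidate
target set, so extracting one compound's whole scope costs one dynamic
program plus one table lookup per target.

## Metropolis reference distribution

The closed form assumes independently drawn edge weights; real networks
violate this. The empirical alternative samples walks from the network
itself, one Metropolis chain per length stratum, with the **uniform
distribution over walks of that length** as the stationary law. Proposals
mix (probability 0.5 each) suffix regrowth from a uniformly chosen cut
point and full restarts from a uniformly chosen node, both using a random
walk whose step probabilities are proportional to u(w); the
Metropolis–Hastings ratio corrects the proposal bias. Each stratum is
split over five independent chains (burn-in 1000 steps, thinning 25) so
chain autocorrelation does not distort the empirical distribution.

Uniform sampling is the right target because the reference must estimate
the *null* distribution of path products over the actual network: on a
graph with iid weights, the closed-form p-values of uniformly sampled walks
are Uniform(0,1) (verified by Kolmogorov–Smirnov at 10,000 samples against
the 1% critical value), and the empirical p-value

    p_emp = (1 + #{reference paths with closed-form p ≤ candidate's}) / (1 + N)

then reproduces the closed form wherever the independence assumption
actually holds (Pearson r > 0.95 over random query walks) while remaining
honest where it does not. Reference paths of all lengths are pooled — the
closed form already normalizes for length; a per-length stratified variant
would only reduce the effective reference size. The sampler also exposes a
`bias` exponent that tilts the target toward high-probability paths for
exploratory use; the default (0) is what `pvalue_empirical` assumes.

## Scopes, multiple testing, minimum cover

The scope of compound c is computed by a brute-force sweep: for every other
compound c', attach pseudo-nodes (s to all reactions consuming c, t to all
reactions producing c'), and admit c' when the most significant path has
p ≤ α/n, where α = 0.05 and n is the number of metabolites in the network
— the Bonferroni correction for testing every possible target. Among
significant lengths the shortest path is stored as the witness. Compounds
whose producing or consuming reactions all lack measured genes simply get
empty scopes. Currency compounds are excluded from the sweep entirely:
their edges were removed by preprocessing, and re-attaching them through
pseudo-nodes would undo the currency correction (ATP would otherwise
acquire a scope spanning half the network through its cofactor couplings).
A single-reaction conversion (c and c' on the same reaction) has no
weighted edge and hence no testable correlation signal; such pairs are not
scope members by definition (path length ≥ 1).

The cover problem — choose the fewest scopes whose union is the set of all
compounds appearing in any scope — is the classic minimum set cover binary
integer program, solved exactly with HiGHS branch-and-cut. Because optima
are rarely unique, all optimal solutions are enumerated by re-solving with
a no-good cut per found solution (cap 1000, flagged if hit), and their
union is reported as the combined minimum set. Scopes enter the model in
descending size order, making output order reproducible. "Covered
reactions" counts distinct reactions on any witness path of any
combined-set scope.

## Hub analysis

Witness paths of the combined set collapse, direction dropped, into a
traversal graph with edge weight = number of paths using the edge. A
maximum spanning forest (Kruskal; ties broken by sorted endpoint order)
extracts the most commonly traversed backbone, and hubs are its
highest-degree nodes — tree degree first, total incident traversal weight
as tie-break, then id. Tree degree rather than raw traversal-graph degree
is used because the tree removes redundant heavy cliques and exposes the
junction structure; both graphs are available to callers. Hub gene
profiles are z-scaled per gene, clustered with k-means (k = 9, 20 restarts,
fixed seed; k reduced with a warning when fewer distinct profiles exist),
and cluster mean profiles are correlated with the metabolite profiles;
constant profiles yield missing correlations rather than errors.

## Distance profiles and enrichment

For a target metabolite, reactions able to produce it form distance layer
1; walking the reaction graph against edge direction adds one layer per
step, and each gene counts only at its first appearance. Per distance the
package reports max/mean/min Pearson correlation between gene and
metabolite profiles, against an envelope of min/max correlations under
permutations of the metabolite's time points (expression fixed, replicates
averaged first, 1000 permutations by default). Conditions are weighted
equally when profiles are averaged across them.

The enrichment check ranks all edges by weight and walks a GSEA-style
running sum — up by |w|/Σ|w| over member edges (weighting exponent p = 1,
the standard recommendation), down by 1/(N−n) otherwise; the score is the
signed maximum deviation. Significance comes from re-drawing random edge
sets of the same size (the data have no phenotype axis to permute, so the
permutation unit is the edge set itself).

## Synthetic study design

The generator produces the package's test bed and reproduction study. Its
defaults *are* the study conditions: 8 time points × 3 biological
replicates, within-pathway gene correlation ρ_in = 0.95 against a
ρ_out = 0.05 background, replicate noise SD 0.25, and three planted source
metabolites.

Topology (72 compounds, 157 reactions): each source feeds a 4-reaction
main chain; the three main chains converge on one shared terminal hub
reaction producing three final compounds; each source also feeds a private
4-reaction spur. Twelve satellite reactions each consume a hub product and
produce a compound nothing else produces. 120 background reactions (two
substrates, two products) wire the remaining compounds at random; they may
consume planted compounds (downstream leakage, as in a real network) but
never produce them, preserving the sources' seed role. A configurable
fraction of reactions carries an ATP/H2O couple in either direction to
exercise currency removal. Planted reactions carry 3 genes, background
reactions 2, and the hub 2 genes per converging chain.

Gene correlations decay geometrically with the number of reaction steps
separating two genes within a branch — exactly ρ_in for same-reaction and
consecutive-reaction pairs, floored at ρ_out — and sit at ρ_out elsewhere.
This first-order (Markov) structure is essentially positive definite (a
small same-position conflict is repaired by eigenvalue clipping and
re-normalization) and, importantly, keeps the sampling fluctuations of
different chain edges nearly independent. Latent profiles are n_time draws
from the multivariate normal; replicates add iid noise; hub-coupled
metabolites follow ρ_m × z(hub mean profile) plus scaled noise, uncoupled
metabolites are pure noise.

Several of these choices exist for statistical identifiability at the
designed effect sizes and must be understood as such:

* With only 8 time points, a single gene pair's sample correlation has a
  Fisher-z standard deviation near 0.45, so an individual true-0.95 edge
  occasionally realizes near the background maximum. Multi-gene reactions
  make the max-pairwise edge weight a maximum over ≥ 4 high pairs, which
  removes that weak-edge tail; a single global correlation block would
  instead make all chains share one latent factor and fail together
  whenever its 8-point sample variance dips.
* The private spur makes each source the only compound whose scope spans
  both of its branches, so the planted sources form the *unique* minimum
  cover rather than one of several optima.
* Witness paths take the shortest significant route; in a dense random
  background the hub's traffic would reroute around it. The satellite
  compounds, having no alternative producer, pin their witness paths
  through the hub and make it the top-degree tree node by construction.
* The study's path-length cap is 6, about 1.5× the deepest planted
  pathway; longer caps admit progressively more best-of-many background
  walks whose selection-biased p-values inflate scopes — visible at full
  scale in genome-scale analyses, where scopes span half the network.

What the generator does **not** emulate: measurement error structure of
microarrays or GC-MS, multiple stress conditions with aligned time grids,
compartmentalization, reversible planted reactions, and realistic degree
distributions (background wiring is Erdős–Rényi-like, not scale-free). A
passing recovery run therefore demonstrates correctness of the inference
machinery under the designed signal-to-noise regime, not performance on
real stress-response data.

## Numerical and degenerate-input conventions

* p-values are computed via `scipy.special.gammaincc`; q = 1 maps to p = 1
  and the smallest achievable p on a network of m edges at length L is the
  gamma tail at L·ln m.
* Empty graphs, empty references, constant metabolite profiles, unknown
  compounds, and infeasible covers raise explicit errors; empty scopes,
  missing strata, and fewer-than-k hubs degrade with warnings.
* All stochastic components (Metropolis, permutation tests, k-means,
  generator) take explicit seeds and are bit-reproducible under them.
* The acceptance script scales its re-computation to the synthetic study
  (72 compounds) and to 20 recovery / 100 envelope replicates, the sizes
  at which all reported quantities were designed to be measured.

## Known limitations

* The walk relaxation can in principle discard a length whose best walks
  are all non-simple; the next length usually supplies a witness, but a
  simple-path-optimal variant would be exponential.
* The closed-form null treats the ECDF as continuous; on very small
  networks (tens of edges) the discreteness of u(w) makes p conservative
  at the extremes.
* Bonferroni over all metabolites is deliberately blunt: it controls the
  family-wise error of one scope sweep but ignores the positive dependence
  between overlapping target tests.
* Selecting the *best* path per pair before thresholding induces selection
  bias that the per-path p-value does not correct; with generous length
  caps this inflates scope sizes, which is intrinsic to the method rather
  than an implementation artifact.
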