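# Methods

This note records the models, conventions, numerical choices and known
limitations behind `phylospace`. It is the package's account of its own
science; every number quoted here is computed by the test suite or
`scripts/acceptance.py`, not asserted from elsewhere.

## Trees and the node indexing convention

A `TreeRecord` stores a rooted phylogeny as flat parent / branch-length
arrays: tips first (input order), internal nodes in postorder, root last,
so `parent[i] > i` for every non-root node and a single index sweep visits
children before parents. The MGL spectrum is invariant to node order
(permutation similarity), so the convention is cosmetic — but it is fixed
so that matrices, resolutions and serializations reproduce exactly.

Crown age is measured from the first split (the first node with two or
more children), per the usual "crown age" usage. A root (stem) edge
annotated in the source Newick is kept for round-tripping but enters
neither the crown age nor the distance matrix: a stem edge has only one
endpoint among the tree's nodes, so including it would require inventing a
stem node that changes the matrix dimension — we do not.

Ultrametricity is checked with a tolerance relative to tree height
(default 1e-8), configurable per call.

**Mean-path-length (MPL) ultrametricization.** Several MPL dialects
exist; we adopt the simplest: each internal node's age is the mean path
length from the node to its descendant tips, a child age exceeding its
parent's is clamped to the parent age, and branch lengths become parent
age minus child age. The output is ultrametric by construction and the
transform is a fixed point on ultrametric inputs. Inversions needing the
clamp are rare on near-clocklike trees. On `((A:1,B:3):1,C:4);` this puts
the internal node at age 2 and the root at age 10/3.

## The modified graph Laplacian and its profile

`M = D − A` over *all* nodes (tips, internals, root), where `A` holds
all-pairs path lengths and `D` the row sums. Rows sum to zero, so the
spectrum has exactly one structural zero; all other eigenvalues are
positive. Two exact identities anchor the tests: `trace(M)` equals twice
the sum of path lengths over unordered node pairs, and rescaling every
branch by `c` rescales the whole spectrum by `c`.

The profile is computed as follows:

* eigenvalues from a dense symmetric solver (`scipy.linalg.eigvalsh`;
  trees are capped at ~700 tips, i.e. ≤ ~1400×1400 matrices, well within
  desk scale);
* structural zeros (|λ| ≤ 1e-8·λmax, configurable) dropped before the ln
  transform — ln 0 is undefined and the zero carries no shape information;
* Gaussian KDE of the ln-eigenvalues with Silverman's rule-of-thumb
  bandwidth, evaluated on a uniform 512-point grid spanning
  [min − 3h, max + 3h] and renormalized to unit integral on the grid. The
  bandwidth rule is recorded with the profile; profiles are comparable
  only within one bandwidth rule;
* ψ is the moment skewness of the **ln**-eigenvalues (the ln convention is
  what the statistics' names advertise; computing it on raw eigenvalues is
  a documented alternative — the directional behavior we tested is the same
  on both scales);
* η is the maximum of the unit-integral density, making it comparable
  across trees of different node counts;
* modality is the 1-based position of the largest gap between
  descending-ranked eigenvalues (ties toward smaller positions, search
  optionally capped). Degenerate trees with long, equal internal edges can
  push the largest gap to the last position (the drop to the zero
  eigenvalue); this is a property of the statistic, not a bug — the tests
  pin the implementation to an independent dense-solver oracle rather than
  to intuitions about particular trees.

## Comparing profiles and clustering

Profiles are re-evaluated on a shared uniform grid spanning the union of
supports, renormalized to probability vectors, and compared with the
Jensen–Shannon divergence (natural log ⇒ values in [0, ln 2]). √JSD is a
metric; the suite checks the triangle inequality on random triples.

*Hierarchical*: average linkage on the JSD matrix. Bootstrap support for a
clade is the fraction of replicates — resampling shared-grid density
ordinates (columns) with replacement, renormalizing, recomputing JSD and
re-clustering — in which the same tip set reappears; ≥ 0.95 counts as
significant. What exactly the original analysis resampled is unstated; the
ordinate bootstrap is our documented choice.

*k-medoids*: PAM (greedy BUILD, best-improvement SWAP; the objective is
non-increasing) run for k = 2..10, selected by optimum average silhouette
width; s̄ > 0.5 flags supported structure. With degenerate (all-equal)
distances no k is supported and a single cluster is reported.

*Stability*: corpora re-clustered and matched to a reference by
maximum-agreement Hungarian assignment — "identical distribution" is
otherwise ill-defined under label permutation.

*Class composition*: for a class with x trees, x multinomial draws over
clusters (probabilities ∝ cluster sizes), repeated n_iter (default 500)
times; an observed count in the lower/upper 5% tail is significant. The
empirical tails converge to exact binomial values (checked at 0.5³ = 0.125
and 0.5¹⁰ ≈ 0.001 on two-cluster toys).

## Phylogenetic space and archetypes

Coordinates are min–max normalized per statistic before polytope fitting
and contribution computation — λ\*, ψ, η have incommensurate scales, and
per-vertex percentage contributions (each row summing to 100) only make
sense on a common scale.

The polytope fitter is archetypal analysis in the Cutler–Breiman form:
minimize ‖X − A B X‖² with the rows of A (point weights) and B (vertex
weights) on probability simplexes, by projected-gradient alternating
minimization. Constraining vertices to convex combinations of the data
matters: with free vertices the zero-residual optimum is non-unique (any
enclosing simplex fits perfectly) and vertex recovery fails. Explained
variance is 1 − SSE/SStot; fits are warm-started from k to k+1 (previous
vertices plus the worst-fit point), which makes explained variance
provably non-decreasing in k. The selected k is the first whose marginal
gain falls below 5% (configurable), else k_max.

Two finishing steps follow the selected fit: a *support polish* (each
vertex snaps to the extreme data point in its direction from the vertex
centroid — this completes the slow tail of the projected-gradient
optimization when the optimum has vertices at extreme points) and a
*gauge inflation* (vertices scale about their centroid by the smallest
s ≥ 1 enclosing every point, judged inside the vertices' affine hull —
a triangle fitted to 3-D points is flat, so enclosure is evaluated on the
projection). On 500 points uniform in a triangle the recovered vertices
land within 5% of the bounding-box diagonal of the truth; on points
uniform in a square the elbow moves to four vertices.

The t-ratio test compares the convex-hull volume of the points to the
fitted k-polytope's volume (projecting to the top k−1 principal components
when the polytope is flat in the ambient space); the p-value is the
fraction of axis-wise independently permuted datasets with a t-ratio at
least as large. The permutation scheme and volume estimator follow the
archetype literature's spirit, not a specific published implementation.

Trade-off and trajectory regressions fit {constant, linear, logarithmic,
quadratic, cubic} candidate forms by OLS and select with small-sample
AICc; the logarithmic form is skipped (not errored) for non-positive
predictors. The selected form's F-test p-value is Bonferroni-adjusted for
the number of candidate forms tried — without this, picking the best of
four forms inflates the false-trend rate well above the nominal level
(we measured ~16% at α = 0.05 on pure noise; adjusted, ~4%). The constant
model competes too, so "no significant trend" is a possible outcome.

Occupancy and overlap between point sets use axis-aligned bounding boxes
(occupancy: volume of A's box as % of B's; overlap: intersection over
union). Both are invariant to common rescaling. Type regions are convex
hulls in the full 3-D space; membership queries use the hull's Delaunay
triangulation, points in several hulls go to the nearest centroid, and
clusters too small or degenerate for a 3-D hull are flagged and skipped.

Rarefaction fixes k = 3, refits on bootstrap samples of increasing size
with normalization pinned to the full data, matches fitted vertices to the
full-data archetypes by nearest assignment, and summarizes each vertex's
maximum normalized coordinate as mean ± sd per sample size, with a
logarithmic saturation curve per vertex.

## The space available to trees

Random phylogeny-type networks are drawn as graph Laplacians — symmetric
M-matrices with non-positive off-diagonals and zero row sums — and
converted to trees: Dijkstra all-pairs distances over the implied weighted
graph (weights are the off-diagonal magnitudes; the only reading that
yields finite path lengths), complete-linkage clustering (merge height h ⇒
node age h/2, so cophenetic distances equal merge heights), MPL
ultrametricization (a fixed point here, since the dendrogram is already
ultrametric), and polytomy resolution.

λ\* is constrained on the **final tree** by linear branch rescaling, not
only on the initial matrix — linkage and ultrametricization change the
spectrum, so rescaling afterwards is the only way the constraint is exact
(the spectrum is linear in branch lengths, so the target is attained to
machine precision).

The off-diagonal law is a free choice the source method leaves open. A
dense i.i.d. Exponential(1) law produces nearly interchangeable trees
whose (ψ, η) range is *narrower* than matched constant-rate birth–death
trees — useless for charting available space. The default is therefore a
heterogeneous mixture: per-tree lognormal weight dispersion
σ ~ U(0.2, 2.5) and per-tree edge density log-uniform between a
connectivity floor (~2 ln n / n) and 1, resampling disconnected draws.
This charts a (ψ, η) bounding box roughly twice the area of a matched
constant-rate corpus's at n = 150. The dense exponential law remains
available (`SamplerConfig(edge_density=1.0, weight_law="exponential")`).

## Birth–death simulation

Forward simulation from two crown lineages, conditioned on the crown age
(t = 0 at the crown) and on crown survival — both founding lineages must
leave extant descendants, otherwise the run is rejected and reported (not
silently retried). Speciation schedules: constant b; decreasing α·e^{−βt}
(high early rates ⇒ stemmy trees); increasing α·e^{+βt} (late bursts ⇒
tippy trees); and a two-epoch shift form (b then b2 after t_shift) for
clustered late radiations. Extinction is a constant d; extinct lineages
are pruned and the resulting unifurcations suppressed. Event times come
from thinning against the rate's maximum over the remaining interval —
exact for these bounded schedules. The pure-birth closed form
E[N(T)] = 2e^{bT} anchors the simulator's moments (2,000-replicate check
within 3 standard errors); crown age is exact by construction.

Richness outside configured bounds (default 20–700, matching family-level
inclusion rules) is a reported rejection.

**What ψ does and does not track.** Decreasing-rate trees measure lower ψ
than increasing-rate trees at matched size and age — the stemmy/tippy
direction the statistic is named for. But ψ is *not* monotone in decay
strength: at fixed size, pushing β up drives trees toward stars whose
near-degenerate spectra have skewness near zero, so mean ψ *rises* with β;
constant-rate trees also measure lower ψ than moderately decreasing ones.
Tests assert only the robust decreasing-vs-increasing direction.

## The synthetic study (what the generator emulates, and what not)

`planted_type_corpus` stands in for a literature-compiled, family-level
empirical corpus: binary ultrametric trees, 20–700 tips, crown ages ~9–110
My, five diversification regimes. Each regime conditions on a crown-age
window and a richness window, with the speciation schedule solved so the
cumulative integral ∫λ dt hits ln(N_target/2) at the drawn age (pure-birth
expectation E[N] = 2e^∫λ). The five regimes:

| regime | ages (My) | tips | schedule |
|---|---|---|---|
| small_constant | 9–11 | 22–32 | constant |
| increasing | 18–22 | 55–80 | α·e^{+0.15t} |
| decreasing | 40–48 | 130–180 | α·e^{−0.15t} |
| shift | 70–80 | 240–330 | low b, then high b2 over the last 10 My |
| large_constant | 100–110 | 440–620 | constant |

The windows place the regimes on a ladder of distinct λ\* levels while the
schedules differentiate their shapes. The tight conditioning is essential:
a tree's ln-eigenvalue density spans only ~1 nat, so within-regime λ\*
spread of that order pushes Jensen–Shannon distances toward their ln 2
ceiling and dissolves cluster structure. Extinction is left at d = 0 so
the shape signal is attributable to the speciation schedule alone (the
plausible empirical range includes 0).

Passing the planted-recovery checks therefore shows the pipeline recovers
*well-separated* generative structure; it does **not** show that empirical
vertebrate families form five clusters — real corpora have overlapping
sizes and ages, non-zero extinction, incomplete sampling, and no ground
truth. Results for real vertebrate corpora depend on literature-compiled
family trees that this repository does not contain and are not reproduced
here; the acceptance script reports the synthetic-study analogues it
actually computes.

## Problem sizes and determinism

Default study sizes (150 trees, ≤ ~620 tips; 200-replicate bootstraps and
permutations; 200 sampled networks) are chosen so a full run completes in
a few minutes on one CPU. Every stochastic operation takes an explicit
seed; the pipeline fans a single global seed out to per-stage seeds via
`numpy.random.SeedSequence`, and two runs with the same config produce
byte-identical numeric outputs (the manifest additionally records
wall-clock timings, which naturally differ).

## Known limitations

* Profiles are comparable only under a single bandwidth rule (Silverman)
  and grid convention; mixing rules silently degrades JSD comparisons.
* The eigengap modality can report the position before the zero eigenvalue
  on trees whose non-zero spectrum is nearly flat (see above).
* JSD saturates at ln 2 for location-separated spectra, so clustering is
  dominated by λ\*-scale differences when corpora span wide size ranges.
* The archetypal optimizer is a local method; restarts and warm starts
  make the reported fits reproducible but global optimality is not
  guaranteed (nor needed for the enclosure contract).
* Bounding-box volumes over-estimate occupied space for non-box-shaped
  clouds; a convex-hull overlap mode is not provided.
* NEXUS/phyloXML input, divergence-time estimation and taxon-sampling
  imputation are out of scope; non-ultrametric inputs are accepted but
  flagged by `tree_metrics`.
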