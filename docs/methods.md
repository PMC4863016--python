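# Methods

`assemblage` implements a community-assembly analysis for nested samples of
taxa (the motivating system is benthic stream insects identified to genus):
it asks whether the taxa that co-occur in a sample are more similar
(*clustering*) or less similar (*overdispersion*) than expected by chance,
where "similar" is measured either on a dated phylogeny or on mixed-type
trait data, and where the traits can be partitioned into *alpha-niche*
traits (resource use within a community — reophily, microhabitat preference,
trophic position) and *beta-niche* traits (tolerance of the habitat —
respiration mode and a BMWP-style pollution-tolerance score). Under classical
assembly theory, environmental filtering should cluster beta-niche traits and
limiting similarity should overdisperse alpha-niche traits.

## Distances

**Phylogenetic.** The distance between two taxa is the cophenetic (patristic)
distance on the dated tree; for an ultrametric tree this is twice the age of
the pair's most recent common ancestor. Trees with only partial age
information are dated first with a BLADJ-style even-spacing rule: processing
nodes in preorder, an undated node's parent is already dated; the nearest
originally-fixed node or tip below it is located by node steps (ties broken
by younger age, then label), and the node receives the age obtained by even
interpolation along that chain. This local rule reproduces even spacing on
chains exactly (a chain root(10) -> u -> v -> tip yields u = 20/3, v = 10/3)
and, like the original adjuster, resolves branching ambiguity in favour of
the shortest chain. Fixed ages are never moved; dating an already fully
dated tree is a no-op.

**Traits.** The trait dissimilarity is a modified Gower coefficient. Each
trait contributes c_t(i,j) in [0, 1]:

* nominal — 0 if the states match, 1 otherwise;
* quantitative — |x_i − x_j| / range_t, the range taken over the full trait
  table (not per pool, so that distances are invariant to the taxon pool and
  the taxa-shuffle null permutes labels on a fixed matrix);
* ordinal — Podani's tie-corrected rank difference: with average ranks r and
  tie-group sizes T,
  c = (|r_i − r_j| − (T_i−1)/2 − (T_j−1)/2) / (r_max − r_min − (T_max−1)/2 − (T_min−1)/2),
  and 0 for tied pairs.

The pairwise distance is the weighted mean of c_t over the traits observed
in both taxa (pairwise deletion; equal weights by default). A pair sharing
no observed trait is an error; a zero-range quantitative trait contributes 0
with a warning. Quantitative/ordinal normalizers are computed once from the
full table, so subset distances are consistent across the combinatorial
screen.

## Phylogenetic signal

* **Mantel test** — Pearson correlation between the element-wise square root
  of the phylogenetic distances and a trait distance, over the off-diagonal
  upper triangle; the null jointly permutes rows and columns of one matrix.
  One-tailed (positive signal) by default, two-sided available. The square
  root damps the influence of the deepest divergences.
* **Mantel correlogram** — equal-frequency classes of phylogenetic distance
  (default 5); per class, the Mantel correlation between the trait distances
  and the 0/1 "pair in class k" indicator, so a *negative* r in the nearest
  class means close relatives are more similar than average. Per-class
  permutation p-values are Holm-corrected.
* **Parsimony (nominal traits)** — the minimum number of state changes via
  Hartigan's generalization of Fitch counting, which is exact on
  multifurcations (the supertree-like inputs contain polytomies); the
  significance test compares the observed count with counts on tip-state
  permutations, rejecting when the observed count is *smaller* than chance.
* **K family (continuous and rank-transformed ordinal traits)** — Blomberg's
  K = [MSE0/MSE]_obs / E[MSE0/MSE]_BM, where MSE0 is the trait variance
  around the phylogenetic generalized-least-squares root estimate, MSE the
  variance in the tree's covariance metric (z' V^-1 z), and the Brownian
  expectation is (tr V − n/(1'V^-1 1))/(n−1). K* replaces the GLS root
  estimate by the arithmetic mean (expectation via the trace expressions
  tr(CVC) and tr(V^-1 CVC) with C the centering projector), and Kw is the
  abundance-weighted generalization: deviations from the weighted mean,
  numerator weighted by relative abundances p, with C_w = I − 1p' in the
  expectations. Kw with equal weights reduces exactly to K* (tested).
  Significance permutes tip values and rejects when the observed MSE is
  smaller than chance. K ≈ 1 under Brownian motion; on an exact star tree
  the expectation cancels and K = 1 identically.

Near-singular tree covariances (splits very close to the present) receive a
ridge of 1e-10 of the mean diagonal before Cholesky factorization.

## Community structure

For each community, **MPD** (mean pairwise distance) and **MNND** (mean
nearest-neighbor distance) are computed in incidence form (over present
taxa) and abundance form (MPD: sum f_i f_j d_ij / sum f_i f_j over distinct
pairs; MNND: abundance-weighted mean of nearest-neighbor distances). The
null model is the **taxa shuffle**: one permutation applied jointly to rows
and columns of the pool-restricted distance matrix, preserving each sample's
richness and abundance structure and randomizing only taxon identity.
Standardized effect sizes follow the usual sign convention,
NRI = −SES(MPD) and NTI = −SES(MNND), so positive = clustering. The
two-tailed rank p is 2·min(#{null ≤ obs}+1, #{null ≥ obs}+1)/(n_rand+1),
capped at 1. A null standard deviation within 1e-9 (relative) of zero —
e.g., when a community contains its whole pool — flags the index undefined;
sites with fewer than two present taxa are excluded with a logged count.

Pools are nested: stream (taxa of the focal site's stream), basin (all taxa
observed), regional (basin plus a supplied list); restriction to the pool
happens *before* shuffling. Aggregation across sites uses a two-tailed
Wilcoxon signed-rank test of median zero at the 0.01 level; a direction
(clustered/overdispersed) is declared only below that threshold.

**APD.** The taxa shuffle can be liberal when abundances are themselves
nonrandomly placed on the distance structure. The Abundance Deviation
diagnostic computes Dp, the abundance-weighted MPD over the whole taxon set
using pooled counts, against permutations of the abundance vector across
taxa: APD = 1 − Dp_obs/mean(Dp_null), positive when abundance concentrates
on mutually close taxa. One code path serves phylogenetic and trait
distances — the trait version is exactly the same statistic with the
distance matrix swapped.

## Trait-subset screen and RDA

All 2^T − 1 nonempty trait subsets (4095 for T = 12; enumeration is guarded
at T = 20) are evaluated: per subset, the Gower distance is rebuilt and the
median NRI/NTI recorded per condition (2 metrics x 2 scales x 2 weightings;
medians over defined sites only; 200 randomizations by default in screen
mode — coarser p floors are irrelevant because only medians feed the
summary). Each subset draws its permutation stream deterministically from
(master seed, subset mask), making the screen bit-reproducible and
order-independent. Subsets on which all taxa are identical are flagged and
excluded downstream.

The screen is summarized by redundancy analysis: the condition medians
(columns centered and standardized to unit variance, so indices on
different scales contribute equally) are regressed on the centered 0/1
trait-membership matrix; the constrained axes are the principal axes of the
fitted values. Reported: the constrained proportion of variance, per-axis
variances (summing exactly to the constrained variance), the first axis's
share, predictor coordinates (correlation of each trait indicator with the
axis scores) and response loadings. Axes are oriented so each axis's
largest-|loading| response is positive; signs are reported raw, with the
reading rule ("which sign means clustering") left to the response loadings
rather than hidden sign flips. Exactly collinear predictors are dropped
left-to-right with a record. No permutation test of the RDA is provided.

## Synthetic data

The generator emulates the nested survey design: a pure-birth ultrametric
tree (root age normalized to 1, optional polytomy injection by collapsing
the shortest internal edges), twelve traits (8 nominal, 3 ordinal via
thresholded Brownian liabilities, 1 quantitative rescaled to the BMWP range
[1, 10]) evolved independently, and 13 streams x 10 riffles with per-riffle
richness Poisson(12) truncated to [2, pool size] and lognormal(1.5, 1.0)
abundances. The richness and abundance settings are the package's own
choices of realistic survey values — benthic counts are strongly
right-skewed — since no per-sample values are prescribed by the design being
emulated. Nominal traits evolve by a symmetric-rate Markov chain (rate 2 per
unit tree depth by default, enough mixing for state diversity while
retaining clade structure); a per-trait `signal_lambda` shrinks shared
branch lengths toward a star tree (0 = i.i.d. tips, 1 = full tree).

Assembly scenarios: *neutral* draws taxa uniformly; *filtering* gives each
riffle an optimum on the [0, 1]-coded filter trait (nominal states mapped to
equally spaced points — a documented modeling convenience) and accepts taxa
with Gaussian kernel weight (sd 0.15 by default); *limiting similarity*
assembles sequentially, rejecting candidates closer than 0.3 alpha-niche
Gower distance to any resident; *mixed* composes the two. All randomness
descends from one seed through named sub-streams (tree / traits /
communities; per-site streams inside the SES engine), so serial and chunked
evaluations agree bit for bit.

What the generator does **not** emulate: real genus compositions or any
real supertree's topology, spatial autocorrelation among neighboring
riffles, trait correlations beyond shared phylogeny, detection error, or
abundance-trait covariance (abundances are independent of trait values, so
the APD diagnostic is centered near zero under neutrality by construction).
Passing calibration tests therefore demonstrates statistical correctness of
the machinery under the stated design, not fidelity to any particular field
data set.

## Numerical and design choices

* Permutation p-values always include the observed arrangement:
  p ≥ 1/(n_perm+1). Defaults: 999 randomizations for single analyses, 200
  in screen mode, both configurable.
* Type-I calibration experiments use 1000 neutral riffles at 999 shuffles;
  the signal calibrations use 64-tip trees with 200 Brownian replicates and
  1000 i.i.d.-trait trials. The parsimony calibration uses a 10-state
  i.i.d. trait so the discrete change-count null is close to continuous;
  with few states the permutation test is conservative (ties inflate the
  rank p), which is a property of the statistic, not a defect of the test.
* The parsimony-count oracle equivalence is checked exhaustively over every
  rooted binary labeled 4-tip topology x every 3-state assignment, plus
  seeded random 5- and 6-tip topologies with polytomies; full exhaustion at
  6 tips is combinatorially out of reach of a test suite and adds no new
  structure beyond the cases covered.
* Taxon-name matching is exact and case-sensitive after whitespace
  trimming; `reconcile_names` reports taxa present in one input but absent
  from another. Family-level taxa are ordinary tips.
* Incidence views are derived on demand from counts, never stored.
* The pipeline manifest contains only deterministic content (seed, versions,
  checksums, counts); wall-clock stage timings go to a separate `run.log`.

## Known limitations

* Only the taxa-shuffle null is implemented (no independent/trial swap or
  frequency nulls); the APD diagnostic is the guard for its key assumption.
* K*/Kw follow the cross-product construction described above; other
  published weightings of abundance into phylogenetic signal exist.
* BLADJ even spacing is over node counts, not accumulated original branch
  lengths, and the shortest-chain tie rule can differ from other
  implementations on pathological topologies.
* The screen's cost grows as 2^T; beyond 20 traits subsets must be sampled.
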