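# Methods

This note documents the statistical models behind `hydromap`, the parameters
that matter, the design choices made where conventions diverge, and what the
synthetic-data generator does and does not emulate.

## Trait and sign conventions

Ψ50 is stored in MPa and is strictly negative (the input validator rejects
non-negative values). "More resistant" means more negative. The square- and
cube-root transforms used to normalise skewed trait distributions operate on
|Ψ50|, so resistance maps onto *larger* transformed values; the node-level
randomisation's default upper tail therefore flags "more resistant than
chance" clades. The transform is chosen by trying none, √, ∛ in that order
and keeping the first whose Shapiro-Wilk p ≥ 0.05 (else the best p); the
decision trace is logged.

## Phylogenetic signal

Blomberg's *K* follows the 2003 convention: both MSE₀ (identity covariance)
and MSE (Brownian covariance V) are computed about the phylogenetic GLS mean
â, and the observed MSE₀/MSE ratio is scaled by its Brownian expectation
[tr(V) − n/(1ᵀV⁻¹1)]/(n−1). This matches what standard comparative-methods
software reports; our implementation agrees with R's `picante::Kcalc` to
~1e-12 on a fixture tree (frozen in the test suite). *K* is invariant to
affine transformation of the trait and to uniform rescaling of branch
lengths (property-tested). Degenerate inputs — constant traits, singular V
(condition number > 1e12) — raise typed errors rather than returning
numbers.

Significance is a tip randomisation: values are shuffled across tips, *K*
recomputed per shuffle (vectorised as one triangular solve over the whole
shuffle batch), and the observed *K* is called significant when outside the
2.5–97.5 percentile band of the null; the reported p doubles the add-one
tail probability (1+extreme)/(1+B), capped at 1. Trees with at least ~20
matched genera are recommended; below that a warning is issued.

Ancestral states are the maximum-likelihood (GLS) Brownian reconstruction,
computed as the conditional mean of the joint Gaussian with the root at â.
Because the reconstruction is linear in the tip values, the node-level
randomisation reduces each 1000-shuffle null to a single matrix product.
Agreement with R's `phytools::fastAnc` is frozen in the tests (1e-8). Node
ranks use a relative tolerance of 1e-9 on the null values so float
summation-order noise cannot flag nodes on constant data. Polytomies are
accepted throughout; the n−1 internal-node count applies only to strictly
binary trees.

Genus matching between tree and trait table is exact after case/whitespace
normalisation; unmatched entries on either side are dropped with a logged
count (the tree is pruned, or equivalently the covariance submatrix is
used). No fuzzy synonymy is attempted.

## Taxonomic comparisons

The nested ANOVA exploits strict nesting (species within genus within
family): the Type-I chain of models is then a sequence of group-mean fits,
so sequential sums of squares are within-group SS differences, each term's F
uses the residual mean square, and the family term has (families − 1)
degrees of freedom. The replication filter keeps genera with >1 species or
>1 site and families with ≥2 such genera or >1 site.

The family one-way ANOVA first drops families present in fewer than
`min_sites` (default 3) sites. Tukey HSD comes from statsmodels; the compact
letter display uses the insert-and-absorb algorithm, and the adjusted p
values are independently checked against the studentized-range distribution
in the tests (1e-4).

The rank-sum test reports W = (rank sum of the first group) − n₁(n₁+1)/2,
the convention in which R's `wilcox.test` prints W. p-values are exact
(no ties and n₁·n₂ ≤ 400) or a normal approximation with tie-corrected
variance and 0.5 continuity correction; the tied case reproduces R to 1e-9
on a frozen example. The family contrast puts the focal family (Fabaceae in
field use) first, so W > n₁n₂/2 means the focal family ranks less negative.

## Community-weighted means

Gap-filling resolves each stem at the finest level with data: species mean,
genus mean, family mean, then the basal-area-weighted mean of the already
resolved stems in the same plot (an unweighted option exists; weighted is
the default for consistency with CWM weighting). Genus/family means average
raw species-site records by default; a mean-of-species-means mode is a
switch. The coverage filter computes the fraction of *dicot* basal area in
families present in the trait table and keeps plots at ≥ 60 %; monocots are
excluded from the coverage denominator but keep their trait values in the
CWM when available. Plot-level metadata screens (elevation, flooding,
disturbance) are expected as upstream boolean columns, not derived from GIS
layers here.

The gap-fill validation replaces species values with family means on plots
whose basal area is ≥ 80 % species-resolved and regresses the degraded CWMs
on the species-level CWMs; R² near 1 indicates family membership carries
most of the community-level signal. On default synthetic studies this R² is
~0.85–0.95, bracketing what degradation experiments on real Amazonian plots
report (~0.7–0.8).

## Regional patterns

**Clustering.** Pseudo-inertia of cluster C under dissimilarity d is
I(C) = Σ_{i<j∈C} d²ij/|C| (uniform weights). Merges greedily minimise
(1−α)·δ0 + α·δ1 where δ is the merge increment of I in the feature (D0) and
geographic (D1) space; both matrices are max-normalised before mixing so α
is unit-free (switchable). The implementation maintains cross-sum matrices
for O(n²) steps and is verified against an exhaustive from-scratch greedy
oracle at n = 8. Q0/Q1 report the explained pseudo-inertia of the cut at k
in each raw space; `select_alpha` codifies the usual graphical rule as "the
largest α whose Q0 is within `q0_tolerance` (default 0.1) of Q0(0)", and
always returns the full curves so a human can override. The cluster count
is a user choice; the tool reports diagnostics rather than deciding.

**Interpolation.** IDW predicts a convex combination of the `nmax` nearest
values with weights d^(−idp); queries within 1e-9 map units of a data point
return that point's value. The LOOCV search is coarse-to-fine: each of 3
steps scores the idp × nmax grid by leave-one-out RMSE, then re-centres the
idp grid on the incumbent with a factor-3 shrink, clamped to the original
grid range; RMSE ties (within float tolerance) break toward smaller idp,
then smaller nmax. The final map interpolates each fold's complement,
smooths with a truncated (edge-aware) square mean filter — default 9×9 —
and averages fold surfaces cell-wise; a use-all-points training mode
exists.

**Validation.** Spatially blocked CV holds out one cluster at a time:
per-fold RMSE, pooled RMSE, and VEcv = (1 − SSE/SST)·100 over all held-out
predictions (SST about the observed mean; VEcv ≤ 100, negative when worse
than predicting the mean). Cluster agreement compares each cluster's
point-average with the mean of surface cells inside its convex hull
(shapely). MESS uses the canonical rank-based formula per variable — with f
the percentage of reference values strictly below the query: 100(q−min)/range
at f=0, 2f for f ≤ 50, 2(100−f) for f < 100, 100(max−q)/range at f=100 —
and takes the worst score across variables, recording the limiting
variable. Note that the rank-based formula gives 50 at the 25th/75th
percentile, not at the centre of the min–max range; informal descriptions
sometimes say otherwise, but the rank convention is what reference
implementations compute, and it is what we implement. A zero-range
reference variable scores 100 on exact matches and a large negative
sentinel (with a warning) otherwise.

All geometry is planar in km. Projecting longitude/latitude to an
equal-area plane is a documented pre-processing step left to the user;
cartographic specifics (projection codes, masking layers) are out of scope.

## Synthetic studies

The generator produces internally consistent bundles: a Yule tree (root
split at t=0, Exp(k·λ) waits, final Exp(n·λ) stub so terminal branches are
positive); Brownian traits mixed on the deviation scale,
x = root + λ·(BM − root) + (1−λ)·ε with Var(ε) equal to the Brownian tip
variance, so λ=1 calibrates to K ≈ 1 and λ=0 to K ≈ 0 while the mean stays
at the root value for every λ; families and orders cut as monophyletic
clades at fixed depth fractions (0.35 and 0.15 of tree depth — the family
cut controls the between-family share of trait variance); and site records
scattered around species means (SD 0.25/0.15 MPa).

Inventory defaults describe a realistic mapping study: 150 plots of 150
stems on a 2000 × 1500 km domain (1-ha Amazonian plots hold hundreds of
stems). The designated resistant family — the largest family, recentred to
sit exactly 0.8 MPa below the other-family mean so the planted contrast is
a guaranteed ground truth — gains log-odds of dominance linearly west to
east (strength 4.0) plus a smooth regional patchiness field (amplitude 0.8,
correlation length 700 km, the scale of the Guiana/Brazilian shield
pattern). Purely monotone composition gradients were deliberately avoided
as the *only* structure: hold-one-region-out validation of any convex
interpolator is pure extrapolation under a monotone trend, which says
nothing about interpolation skill. Basal areas are log-normal (right-skewed
stem sizes); 5 % of stems are palm-like monocots and 3 % dicots of an
unknown family, exercising the coverage and plot-mean paths. Environmental
rasters are Gaussian-filtered noise plus a west–east trend scaled to
MCWD-like (negative mm) and water-table-depth-like (m) units.

A bundle seed deterministically derives all stage seeds
(`SeedSequence.spawn`), and bundles are byte-reproducible.

What the generator does *not* emulate: real species pools and their
abundance distributions, climate fields, taxonomic noise (synonyms,
morphospecies), multi-census dynamics, or the spatial clustering of real
plot networks. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under controlled structure, not predictive
validity on real forests.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 100-tip trees with 1000
permutations (200 and 100 replicates respectively) for *K* calibration;
100/50 replicates for planted-clade recovery (clade of 4–6 tips shifted by
+5 marginal SD; the MRCA must be recovered while nodes disjoint from the
clade stay at the nominal 5 % flag rate — nodes inside the clade or on its
root path contain shifted tips and are genuine detections); 500 seeds for
rank-test null uniformity; and 50 bundles at the default study conditions
for the end-to-end gradient-direction and VEcv-versus-shuffled checks,
with spatial CV folds built at α = 0.7, k = 8 (stronger spatial blocking
than the mapping clusters themselves, which is the appropriate design for
transfer validation) and the IDW search run at 2 refinement steps.

Other numerical choices: covariance condition-number guard at 1e12; IDW
exact-hit tolerance 1e-9 map units; LOOCV tie tolerance 1e-10 relative to
the value scale; truncated (never padded) smoothing at raster edges; merge
ties broken toward the lexicographically smallest cluster pair.

## Known limitations

* No Pagel's λ or Ornstein-Uhlenbeck alternatives to Brownian motion; *K*
  and BM reconstruction only.
* No kriging; IDW surfaces are visualisation aids, and the spatially
  blocked VEcv should temper any pixel-level use.
* Taxonomic matching is exact (normalised); no name-resolution service.
* ESRI ASCII grids only; no GeoTIFF, no projection handling.
* The nested ANOVA assumes strictly nested, internally consistent taxonomy
  and rejects tables where a genus maps to several families.
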