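# Methods

## The statistical model

Let `y_i` be log range size (natural log throughout) of species `i` and
`x_i ∈ {0,1}` an epiphyte indicator. The phylogenetic regression is

    y = α + β x + ε,   ε ~ N(0, σ² C_λ)

where `C` is the Brownian-motion covariance of the rooted tree —
`C[i,j]` is the shared root-to-MRCA path length, `C[i,i]` the root-to-tip
path length (root depth 0) — and `C_λ` scales the off-diagonal entries by
Pagel's λ ∈ [0,1]. λ = 0 is phylogenetic independence, λ = 1 the full
Brownian structure; it is estimated by profile maximum likelihood:
for each λ the GLS estimate `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V = C_λ`
profiles out `σ̂²_ML = eᵀV⁻¹e/n`, giving

    ℓ(λ) = −½ [ n·ln(2π σ̂²_ML) + ln det V + n ].

The scalar search is Brent-style bounded optimization on [0,1] with
absolute tolerance 1e-6; both endpoints are evaluated explicitly so
boundary optima are exact. λ is restricted to [0,1] because values above 1
can make `C_λ` indefinite on ultrametric trees. All solves go through a
Cholesky factorization of `V`; an explicit inverse is never formed, and a
dense-covariance cap (20,000 taxa, O(n²) memory) turns oversized problems
into an explicit error advising tree pruning.

Standard errors use the `n − p` denominator (`eᵀV⁻¹e/(n−p)` times
`diag((XᵀV⁻¹X)⁻¹)`) while λ is profiled under ML — the common
comparative-methods convention. Effects on range size are reported as
percentage differences `100·(e^β − 1)` with Wald 95% intervals
(`z = 1.959964`) on the log scale.

Companion models: ordinary least squares on log-transformed responses
(classical SEs), and a quasi-Poisson GLM for the botanical-country count —
log-link Poisson score equations solved by IRLS to relative tolerance
1e-10 (max 100 iterations), with dispersion `φ = Σ r_Pearson² / (n−p)`
scaling the Poisson SEs by √φ. PGLS is never paired with the count metric
(a quasi-likelihood model has no tractable phylogenetic GLS analogue
here), and a group indicator whose group has all-zero counts is rejected
(the MLE is infinite).

Uncertainty from the placement of taxa lacking molecular data is
propagated by fitting each of a set of trees and reporting the
coefficient-wise mean and the between-tree standard deviation of the
estimates (the spread itself, not spread/√m; both the spread and the mean
within-fit SE are retained so either convention can be reported).

## Range metrics and geodesy

Three range-size measures with different coverage/precision trade-offs:
the native botanical-country count (defined for every species), the
cleaned specimen count (a range and collection-abundance proxy), and the
extent of occurrence (EOO). Specimen count and EOO are restricted to
species native to at most four botanical countries — up to four units can
meet at a point, so even point-like ranges can span four — and EOO
additionally requires at least three georeferenced records. Species with
zero cleaned records get a *missing* specimen count by default ("never
observed", excluded downstream) rather than zero; a flag flips this.

EOO is the convex hull of the cleaned points, hulled in the lon-lat plane
(valid for the small extents the metric targets; point sets spanning more
than 180° of longitude are recentred, polar caps are an error) and
evaluated as a geodesic polygon on a sphere of authalic radius
6371.0072 km via the Chamberlain–Duquette line integral

    A = (R²/2) |Σ (λ_{k+1} − λ_k)(2 + sin φ_k + sin φ_{k+1})|.

This is exact for meridian/parallel-bounded figures (the 1°×1° equatorial
square equals the spherical-zone closed form `R²·Δλ·Δsinφ` ≈ 12,364 km²
to machine precision) and agrees with a cylindrical equal-area projection
oracle to well under 0.5% for extents below 5°. Degenerate (collinear)
point sets yield EOO 0 rather than exclusion, and are distinguishable
from the missing (<3 points) case.

## Cleaning

Georeferenced records pass four filters in a fixed, audited order —
native-range (point-in-polygon against native botanical countries,
boundaries inclusive), precision (stated uncertainty strictly greater
than 100 km removed; *missing* uncertainty retained, since most herbarium
records lack the field), suspect coordinates (exact latitude==longitude or
either ==0 on the parsed values, and great-circle proximity within a
configurable 1 km of country centroids/capitals/institutions), then
per-species deduplication (identical coordinates after rounding to 3
decimals; first record in input order wins) with spatial thinning (at most
one record per 110 m × 110 m cell, equirectangular at the record's
latitude — "110 m" matching the ~111 m that 0.001° spans at the equator).
Cheap, implausible-record filters run before spatial thinning so thinning
operates on plausible records. Non-georeferenced records are deduplicated
on normalized locality (case-folded, whitespace-collapsed), then on
(year, administrative unit) pairs when both present, then checked against
native countries via the ISO→botanical-country mapping (missing country
codes are retained). Every filter conserves counts, preserves input order,
logs a reason per removal, and the composite is idempotent.

## The synthetic generator

The generator produces the full input bundle with ground truth: a Yule
tree (simulation starts at the root bifurcation and adds one final
waiting time at n lineages, so expected depth is `Σ_{k=2..n} 1/(kλ_b)`);
a two-state Markov lifeform evolved root-to-tip with the root drawn from
the stationary distribution; log range sizes from the PGLS generative
model above; and occurrence records drawn uniformly in a disc inside the
species' native region, the disc sized by the Monte-Carlo-calibrated
expected hull fraction so the *expected* hull area equals the species'
EOO target. Clean records avoid, by construction, every violation trigger
(zero/equal coordinates, reference-point buffers, shared 3-dp roundings
or thinning cells within a species), and each planted violation record
carries exactly one labelled role — so the per-filter attribution of the
cleaning arm can be scored with precision and recall of 1. Per-species
record counts scale with `exp(0.5·(y−α))`, mimicking the correlation of
collection effort with range size that makes specimen count a usable
range proxy. One global seed expands into per-stage child seeds by fixed
offsets, so stages are independently reproducible and a fixed seed yields
byte-identical files.

Scenario conditions (chosen once):

| scenario | key settings | purpose |
|---|---|---|
| `baseline` | n=200, λ=0.8, σ²=0.2, β=ln 1.5, Mk rates (0.25, 0.5), occ_mean 16 | recovery of β and λ |
| `confounded_clades` | two depth-1 Yule clades on stems of length 1000, λ=1, σ²=0.1, β=+ln 1.5, P(epiphyte)=0.9/0.1 | ordinary-vs-phylogenetic sign reversal |
| `null_effect` | baseline with β=0 | interval coverage |

In the confounded scenario the epiphyte-rich clade is assigned to the
clade whose realized deep-branch Brownian displacement is lower, so the
between-clade contrast opposes the true within-clade effect every
replicate. The stem length was set by a power argument: with clade
displacement SD 10 (`√(σ²·stem)`), the conditioned between-clade gap is
almost always large enough for the ordinary model to show a significantly
*negative* lifeform effect while PGLS recovers the planted positive one.
EOO targets are clipped to [50, 1.5×10⁵] km² so the sampling disc fits a
toy region; under the extreme clade displacements this clipping saturates
the realized occurrence metrics, which is why end-to-end demonstrations
through the occurrence pipeline use a milder stem (60) — the regression
properties themselves are exercised on the unclipped log-range responses.

What the generator does *not* emulate: empirical GBIF record-count and
region-frequency distributions, real polygon geometry (regions are
rectangles on the equatorial band), spatial sampling bias, taxonomic
name noise, or extinction in the tree (pure birth only). Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to every artefact of real aggregated occurrence
data.

## Numerical and design choices

- Natural log everywhere; the percent-difference transform requires it.
- Longitudes are normalized to (−180, 180]; latitudes are never wrapped —
  an out-of-range latitude invalidates the coordinate pair (silent
  wrapping hides errors). Unparsable values become missing with a
  validation-log entry; rows are only rejected for a missing species name.
- Non-binomial species names are flagged (not dropped) as likely
  fuzzy-matching artefacts.
- Tie-breaks: deduplication keeps the first record in input order;
  checklist order defines range-table order.
- Rarity denominators are species with the metric *defined* ("of species
  for which EOO was estimated"), thresholds are strict-< for EOO and ≤
  for specimens.
- Tropics boundary ±23.436°; the tropical subset uses the simple
  (unweighted) mean of native-region centroid latitudes. Island exclusion
  drops species with *any* oceanic-island native region by default
  (configurable to *all*).
- Species missing from a given tree are dropped from that tree's PGLS fit
  only, with a logged count; ordinary models keep them. Within-group
  (e.g., per-family) PGLS re-estimates λ per group.
- Tip-label matching trims whitespace and treats underscores and spaces
  as equivalent, then matches exactly; verbatim tip labels are preserved
  on read and recovered for fitting.

## Known limitations

- Wald intervals with profiled λ and estimated σ² are slightly
  anti-conservative at a few hundred tips (the null-scenario coverage the
  acceptance script measures runs a little below the nominal 95%); a
  parametric bootstrap would tighten this at real-data scale.
- The Chamberlain–Duquette area treats hull edges as loxodrome-like
  segments; for continental-scale hulls (≫5°) an ellipsoidal geodesic
  area would be preferable.
- The quasi-Poisson dispersion is a moment estimator; φ below 1
  (underdispersion) is reported as-is, and a degenerate all-equal-counts
  fit reports φ = 0 with a warning.
- Cleaning cannot detect duplicates across the georeferenced and
  non-georeferenced arms (the same collection digitized twice with and
  without coordinates counts twice), matching the two-arm design.
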