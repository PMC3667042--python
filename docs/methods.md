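# Methods

## The problem

Range size alone misranks extinction risk when habitat is fragmented: two
species with identical remaining range differ sharply in risk if one range is
a contiguous forest block and the other a constellation of small fragments.
`fragcap` quantifies that difference with a modified metapopulation capacity
computed directly from a binary habitat raster, alongside the simpler metrics
(total range area with threshold screens; cumulative fragment-area curves)
that it is meant to replace or complement.

## Modified metapopulation capacity

Given patches with areas `A_i` (km²) and minimum edge-to-edge distances
`D_ij` (km), the landscape matrix is

    m_ij = A_i^x · f(D_ij) · A_j

and the capacity λ is its leading eigenvalue.  `x ≥ 0` scales per-patch
extinction risk with inverse area (default `x = 1`, extinction risk ∝ 1/A;
exposed in config, since no single value is canonical).  The modification is
the diagonal: retaining `m_ii = A_i^(x+1)` (because `f(0) = 1`) lets a patch
contribute to its own recolonization — the within-patch rescue effect that
makes one large patch worth more than many small ones of the same total
area.  We call this variant `λ_self`; zeroing the diagonal gives the classic
capacity `λ_classic ≤ λ_self`.  Units are relative ("Levins patch
equivalents"); the metric is a peer-group ranking, not an absolute
persistence probability, which is why the cohort layer works on ranks and
clusters rather than on λ's raw scale.

The alternative reading of the element, `m_ij = A_j^x f(D_ij) A_i`, is the
transpose of the matrix above and therefore has the same spectrum; the
ambiguity is immaterial for λ and is covered by a test.

### Numerical route

`M = diag(A^x) · F · diag(A)` with `F` symmetric is similar to the symmetric
matrix `S = diag(A^((x+1)/2)) · F · diag(A^((x+1)/2))` (conjugate by
`diag(A^((1−x)/2))`).  All eigenvalues are therefore real, and the leading
eigenpair is computed with a symmetric solver (`scipy.linalg.eigh` dense up
to 2,000 patches, Lanczos `eigsh` beyond); the eigenvector is back-transformed,
clipped at zero and normalized to sum 1 (Perron–Frobenius guarantees a
nonnegative leading vector).  The generic `leading_eigen` entry point for
arbitrary nonnegative matrices uses dense `eig`/sparse `eigs` and is
cross-checked against plain power iteration in the tests.  An empty
landscape has λ = 0 by convention; a single patch gives `λ_self = A^(1+x)`
exactly.

## Dispersal-survival kernel

`f(D)` is the probability of dispersing at least distance `D`.  The primary
kernel is the survival transformation of the log-sech dispersal kernel,

    f(D) = 1 − (2/π)·arctan((D/α)^(1/β)),

a heavy-tailed law under which log-distance follows a hyperbolic-secant
distribution.  `α` (km) is the median dispersal distance — `f(α) = 1/2` for
every shape `β`, which is why this parameterization was chosen — and `β`
controls tail weight (`β → 0` approaches a step function at `α`).  The
defaults `α = 1 km, β = 0.5` are placeholders for tests and demonstrations:
no fitted forest-bird values are bundled, and the CLI refuses assessment runs
without explicit kernel parameters.  Any one-argument survival function with
`f(0) = 1`, nonincreasing, can be plugged in; a negative-exponential
`exp(−D/α)` (classical incidence-function form, `α` = mean distance) ships
for comparison.  The identity `1 − f(D) = ∫₀^D p(s) ds` with the log-sech
density is verified by quadrature to 1e-6.

## Patches and distances

* Grids are binary lattices at a nominal 1 km² cell scale (any positive cell
  size is supported; cell area = `cell_size_km²`).  No-data values are read
  as non-habitat, the conservative choice for connectivity.
* Connected-component labeling uses 8-connectivity by default (diagonal
  cells touch), exposed as a flag; patch ids are assigned in decreasing area
  order with a deterministic row-major tie-break.  Labeling is checked
  against an independent flood-fill oracle.
* `D_ij` is the minimum Euclidean distance between boundary-**cell centers**
  of the two patches (a boundary cell has at least one non-habitat or
  off-grid neighbor under the labeling connectivity).  Cell centers rather
  than cell edges keep the convention simple and bit-reproducible at 1-km
  resolution; distances are planar km (projected rasters; no great-circle
  support).  The self-distance is 0, consistent with the self-colonization
  diagonal.  The production path (pairwise distance blocks, k-d tree above
  40,000 boundary-cell pairs) is exact and is tested against an all-pairs
  brute force at 1e-12 km.
* Single-cell patches are legal; an optional `--min-patch-km2` filter exists
  (minimum-viable-fragment screening) but no filter is applied by default.
* Raster formats: ESRI ASCII grid (cell size and origin from the header) and
  single-band TIFF via `tifffile` (cell size must be given explicitly; geo
  tags are not parsed).

One caveat on a tempting invariant: the edge-to-edge distance is *not*
always bounded by the centroid distance — concave interlocking patches can
have centroids closer than any boundary pair.  The bound holds for convex
patches (exactly for single-cell patches) and is tested in that form.

## Comparison metrics

**Range area and thresholds.** Total range = Σ areas.  Two screens, both
strict `<` (a species exactly at a threshold is not flagged; configurable):
11,000 km² for habitat-trimmed ranges and 20,000 km² for extent-of-occurrence
style ranges.

**Cumulative fragment-area curve.** Points `(a, cumulative area in patches
of size ≤ a)` over ascending distinct sizes, ties merged into the cumulative
total through that size (keeps the x-axis a function; base-10 logs
throughout).  The log-log OLS slope needs ≥ 2 distinct sizes, otherwise it
is reported as NaN rather than 0.  The right-most point always reads off the
largest fragment (x) and the total area (y) exactly.  The slope is the
metric's known weakness: surrounding a few large patches with hundreds of
small fragments raises the intercept in every case and lowers the slope in
nearly every case — *nearly*, because a lone far-left point sits on the
`y = x` diagonal and can lever a shallow fit upward, so the slope statement
is an ensemble regularity, not a per-input identity, and is tested as such.

## Cohort layer

Log₁₀ capacities across a cohort are partitioned into "low" and "high" by
the exact 1-D two-group split: sort, enumerate all n−1 ordered split points,
minimize within-group sum of squares.  This is deterministic and exact (no
k-means initialization), and reduces to the brute-force enumeration of all
order-respecting 2-partitions.  A bimodality diagnostic (between-group /
total sum of squares ∈ [0, 1]) accompanies the labels so callers can reject
unimodal cohorts; all-identical values yield no split and NA labels.  A
fixed log₁₀ λ threshold can be supplied instead to mimic manual histogram
binning.  Note the split is invariant to affine transforms of the values but
not to arbitrary monotone maps (those can move the variance-optimal split).

Red List categories CR/EN/VU count as threatened, NT/LC as non-threatened;
anything else (DD, NE, missing) maps to NA and is excluded from omission
arithmetic.  The omission rate of a cluster is the fraction of its members
with known category that are listed NT/LC; the complementary count of
threatened members ("capture") is returned alongside.  Slopegraph export
ranks species on two metrics ascending (rank 1 = smallest value = greatest
risk, the top of the graph) with ties sharing mean ranks.

## Synthetic landscapes

The generator seeds `n_seeds` nuclei uniformly at random (without
replacement) and accretes uniformly chosen 4-adjacent frontier cells until
each nucleus exhausts its budget; total habitat is `n_seeds × (1 +
growth_steps)` cells.  `big_patch_fraction` routes that fraction of the
whole budget to a single nucleus grown first (1.0 collapses to a single
nucleus, hence exactly one patch).  Same spec + seed ⇒ identical grid.  The
generator emulates the structural contrast that matters for capacity — one
dominant block versus scattered fragments at matched total area — but *not*
other features of real forest maps: no spatial autocorrelation beyond
accretion, no elevation or land-cover structure, no anisotropy, no realistic
patch-size power laws.  Passing tests therefore demonstrate the metric's
mathematical behavior and its coupling to occupancy dynamics, not agreement
with any particular real landscape.

## SPOM validation

The discrete-time stochastic patch occupancy model shares M's ingredients:
per step, an occupied patch goes extinct with `E_i = min(1, e/A_i^x)`;
colonization pressure is `C_i = 1 − exp(−c · Σ_j p_j A_j f(D_ij))` with the
self term included iff rescue is on, in which case a patch suffering
extinction can be recolonized in the same step from start-of-step occupancy
(without rescue, a patch's own population never rescues it, and a single
patch has exactly geometric extinction time with mean `A^x/e` — used as a
closed-form check within Monte-Carlo error).  All patches start occupied
(the tool assesses remaining ranges of extant species); metapopulation
extinction is absorbing, and runs are censored at the horizon.  Discrete
time was chosen over continuous for reproducibility and vectorization; the
validation claim is rank-correlational — capacity orders landscapes by
persistence — not threshold-exact.

The validation experiment generates 20 landscapes on a 60×60 km grid with
habitat budgets swept geometrically from 6 to 180 cells and the dominant-patch
fraction from 0 to 0.9, so λ_self spans ≳ 4 orders of magnitude; each runs
100 replicates × 500 steps at `e = 1, c = 0.05, x = 1` with the log-sech
kernel (`α = 2 km, β = 0.5`).  These sizes keep the whole experiment around
two seconds while leaving the rank correlation strong (ρ ≈ 0.98 across
seeds); Spearman ρ between log₁₀ λ_self and median extinction time ≥ 0.7 is
the package's own acceptance bar.

## Known limitations

* Capacity is relative: comparisons are meaningful within a peer group
  analyzed with the same kernel and exponent, not across parameterizations.
* No kernel fitting from movement data; parameters must come from the
  literature or the user.
* Straight-line distances ignore matrix permeability and movement behavior.
* Vector (polygon) geometry, reprojection and range-map construction from
  elevation/land-cover are out of scope; inputs are already-binary rasters.
* The two-group split will happily partition a unimodal cohort — always
  check the bimodality diagnostic before reading the labels.
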