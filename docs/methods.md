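# Methods

## Problem and model

The package quantifies immunohistochemical positivity on whole slides that
have already been segmented and classified by image-analysis software, so the
unit of input is a *marked planar point pattern*: cell centroids in microns
(origin top-left, y down, matching image conventions) each carrying a binary
positive/negative stain call. Two statistics are computed per slide:

1. **Overall percent positivity** — 100 × positive / total over all cells
   retained after artifact exclusion. The denominator is total cells (not
   positive-candidate cells), consistent with expressing the eligibility
   cutoff as a share of total cells.
2. **Hot-spot percent positivity** — the same ratio restricted to the
   1 mm-diameter disc centered on the positive cell with the greatest number
   of other positive cells within 500 μm. "1 mm hot spot" is read as the disc
   of *radius* 500 μm, the same length scale that defines the center, so the
   center's counted neighbors are exactly the positive cells of its disc.

Cases whose overall positivity does not strictly exceed the eligibility
threshold (0.05% of total cells by default) are classified immunonegative and
are not submitted for hot-spot analysis; their hot-spot value is *missing*,
never zero, and stays out of all extrema and means.

## Procedure details and tie-breaks

- **Artifact exclusion** removes every cell whose centroid lies inside any
  supplied polygon, boundary included. Boundary cells are excluded because
  the regions exist precisely where the staining is untrustworthy; the
  conservative call costs at most a ring of centroids. Exclusion precedes all
  computation (overall %, eligibility, hot spot). With overlapping regions a
  cell is excluded once but attributed to every containing region in the
  filter report, so per-region counts can sum to more than the exclusion
  count.
- **Neighbor counting** uses a k-d tree (`scipy.spatial.cKDTree`) over the
  positive cells only, with closed balls (distance exactly equal to the
  radius counts) and self excluded. The contract is exact equality with the
  quadratic all-pairs count; the test suite and the acceptance script verify
  this against an independently coded `cdist`/pure-Python oracle.
  Self-exclusion is a fixed convention: including self would shift every
  count by one and could not change the argmax.
- **Center selection** takes the maximal count, ties broken by smallest cell
  id. Ids are file-order indices, so the rule is deterministic and
  reproducible across runs and machines.
- **Downsampling** before neighbor counting is a uniform random subsample
  without replacement of size ⌈n/k⌉, k = 4 by default, drawn from a seeded
  generator recorded in the run manifest; factor 1 disables it. A systematic
  every-k-th mode exists for sensitivity checks. Downsampling exists purely
  for speed, so by default the reported disc statistic is computed on the
  full post-exclusion table, not the subsample (`stats_on="downsampled"`
  reports the subsample statistic instead, for comparison with workflows
  that never return to the full table).
- **Disc statistics** use the closed disc and no edge correction: a hot spot
  near the tissue border simply contains fewer cells. The center is always a
  cell, so the disc is never empty.
- **Degenerate inputs**: an empty cell table raises an empty-input error —
  distinct from a 0% result; a slide with no positive cell after
  downsampling yields the "no hot spot" outcome with that reason.

## Synthetic slides

`phoxspot.simulate` generates slides as homogeneous Poisson point processes:
cell count ~ Poisson(density × area) (a fixed-count option exists for exact
tests), positions uniform on the rectangle, labels Bernoulli with a
location-dependent probability — baseline everywhere, a cluster's fraction
inside each planted disc, an artifact fraction inside artifact polygons.
Where clusters overlap, the innermost (smallest radius, listed order breaking
ties) wins, so each location has one well-defined label probability; clusters
beat artifacts; clusters must not depress positivity below baseline. The
recorded truth includes the analytically expected overall positive fraction,
computed as an exact area-weighted mixture over the disjoint regions induced
by those priorities (shapely geometry, clusters clipped to the slide;
circular discs are 2048-gon approximations, a relative area error below
1e-6, negligible against Monte-Carlo noise).

Reference conditions, used as defaults and throughout the tests: 10×10 mm
slide, 2000 cells/mm² (≈200k cells), baseline positive fraction 0.005, and —
where a cluster is planted — radius 500 μm with local positive fraction
0.30. Density and slide size are chosen for tractability as plausible
whole-slide magnitudes; published slide-level percentages come with no
density or geometry metadata to emulate.

What the generator does *not* emulate: segmentation and classification
errors, intensity gradations (labels are already binary), anisotropic or
clumped background cellularity, tissue-shaped domains (the slide is a full
rectangle), and multiple competing hot spots. Passing recovery tests
therefore shows the *procedure* is correct and stable under Poisson/binomial
sampling noise, not that any upstream cell classifier is accurate.

## Cohort aggregation and the packaged reference table

The packaged 51-case cohort table (`data/table1_cohort.csv`) transcribes a
published pediatric study cohort: 7 ETMR, one *PLAGL2*-amplified embryonal
tumor NEC, 27 other CNS tumors (other embryonal entities, gliomas, ATRT,
medulloblastoma, pineoblastoma), and 16 peripheral neuroblastomas (8 primary,
8 metastatic) as the comparison arm. Derived statistics recomputed from it:
22/51 cases above the 0.05% cutoff, 5/7 ETMR above, all 27 non-ETMR
non-PLAGL2 CNS tumors below (essentially immunonegative), ETMR overall range
0.0374–4.939% with hot spots to 39.01%, neuroblastoma overall range
1.819–79.22% with every hot spot above 7.5%. The source's running text gives
a narrower ETMR range (0.03–1.98%, hot spot to 37.19%) than its own case
table; the table values are used and the discrepancy is noted here rather
than resolved. No diffuse-vs-focal classifier is implemented — no formal
definition exists for one — so reports print overall %, hot-spot % and leave
the qualitative call to the reader.

## Choices that were genuinely open

- **Statistic on full vs downsampled cells**: source workflows are ambiguous;
  full is the default (no precision loss; downsampling is motivated only by
  efficiency), downsampled is available and recorded in the result.
- **Downsampling scheme**: unspecified upstream; uniform random with a
  recorded seed (default 0) was chosen, with systematic as an alternative.
- **Eligibility comparison**: strictly greater than the threshold; a case at
  exactly 0.05% is ineligible.
- **Classification string mapping**: detection exports vary; any class string
  containing a configurable token (default "positive", case-insensitive)
  maps to positive, collapsing intensity bins.

## Test and acceptance problem sizes

Monte-Carlo checks use 200 replicate slides for the expected-fraction
consistency (mean within 3–4 standard errors of the analytic value), 20
replicate reference-condition slides for cluster recovery (center within
300 μm and disc percentage within ±5 points of the planted 30%, each in at
least 18 of 20 seeds), and 50 random slides of up to 2000 cells for exact
oracle equivalence. On uniformly labeled slides the argmax selection biases
the hot-spot percentage upward slightly (≈1.5 points at 30% baseline with
the default subsample); the scale-consistency check therefore compares the
replicate mean against the overall percentage within four binomial standard
errors of a single disc, which comfortably contains that bias.

## Known limitations

- Hot-spot detection returns a single disc; slides with several comparable
  foci report only the maximal one, with ties resolved by cell id.
- Point-in-polygon uses shapely's predicate on simple rings; self-intersecting
  exclusion polygons are outside the supported input class.
- Percentages on very small retained-cell counts are unstable; the QC flag
  `low-count` (fewer than 1000 retained cells) marks them but no correction
  is applied.
- Coordinates must be (convertible to) microns; no other calibration handling
  exists.
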