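# Methods

## The measurement

`aggscreen` quantifies keratin aggregation in keratinocytes that express a
GFP-tagged keratin-14 reporter. In cells carrying severe epidermolysis
bullosa simplex (EBS) mutations the reporter collapses into bright
cytoplasmic puncta ("aggregates") on top of a dim filamentous GFP
background; treatments that restore filament formation reduce the fraction
of aggregate-positive cells. The assay readout for one microscope field is

```
percent_positive = 100 * n_aggregate_positive_regions / n_analyzable_regions
```

where a *region* is the Voronoi cell of one segmented nucleus, standing in
for one cell.

## Per-field pipeline

Each field carries two channels, `nuclei` and `gfp`, stored as floats in
[0, 1] (integer images are divided by their dtype maximum on read).

1. **Blur rejection.** The sharpness score is the mean Sobel gradient
   magnitude. The score is computed on the nuclei channel: its edge content
   is fixed by cell density, whereas GFP edge content varies with the very
   quantity being measured (aggregate load), which would make QC acceptance
   depend on treatment. Fields scoring below `qc_threshold` (default 0.016;
   in-focus synthetic fields score ~0.02–0.03, fields defocused by a 4 px
   Gaussian fall to ~0.015) are reported as rejected and excluded from well
   summaries. The original procedure states only the intent ("reject images
   that are too blurred"), so both the operator and the threshold are this
   package's choices.
2. **Nuclei segmentation.** Gaussian blur (σ = 2 px) → threshold (Otsu by
   default, or fixed) → fill holes → distance-transform watershed to split
   touching nuclei (markers from local maxima of the smoothed distance map;
   4-connected ridges) → drop components smaller than `min_nucleus_area`
   (default 30 px) → relabel 1..n. A blank channel yields zero labels rather
   than an error. Otsu carries a contrast guard (`min_contrast`, default
   0.02): if foreground and background means separate by less than it, the
   channel is treated as empty instead of thresholding noise — this is what
   lets a signal-free EthD-1 channel count zero dead cells.
3. **Voronoi tessellation.** Every pixel is assigned to the nucleus
   *component* (not centroid) whose nearest pixel is closest in Euclidean
   distance; exact ties go to the smaller label. The implementation runs one
   distance transform per label in ascending order with strictly-less
   updates, cropped to a window that provably contains the label's influence
   zone, so the tie-break is exact; it matches a brute-force per-pixel
   search bit-for-bit on test fixtures.
4. **Region exclusion.** Regions touching the image border are excluded
   first ("edge"); remaining regions whose coverage by the GFP foreground
   mask is below `background_coverage_min` (default 0.2) are excluded as
   background. The GFP foreground threshold is the *lowest* cut of a 3-class
   Otsu on the blurred channel: the GFP histogram can hold three populations
   (dark background, dim filaments, bright puncta) and a 2-class Otsu can
   land between filaments and puncta, flagging whole cells as background.
   The coverage-fraction criterion itself is this package's formalisation of
   "remove background portions"; no quantitative rule was published.
5. **Aggregate detection.** Difference of Gaussians (σ = 1 and 4 px,
   reflect boundaries) enhances puncta. The response is thresholded at
   `intensity_min`; by default this resolves to 10 × the response's robust
   scale (1.4826 × MAD), a cut calibrated on synthetic fixtures where
   filament texture peaks stay below ~6 robust SDs while planted puncta
   exceed ~25. Connected components (8-connectivity) with area in the
   inclusive window [4, 120] px are kept as puncta; the maximum approximates
   one nucleus footprint and rejects whole-cell brightness artefacts.
   A component straddling a region border belongs to the region holding its
   maximum-response pixel. A region is positive when it holds ≥ 1 punctum.

Raising `intensity_min`, `punctum_area_min` or the fragment `min_fragment_area`
can only remove detections, so positive counts are monotone non-increasing
in every threshold — a property the test suite checks directly.

## Screen logic

Well summaries average percent-positive over QC-accepted fields (sd = 0 for
a single field; wells with every field rejected are flagged and excluded).
The DMSO baseline is the unweighted mean over negative-control well means.
Each remaining well's reduction is `(baseline − well) / baseline`; a *test*
well is a hit when its reduction is **at least** the cut-off (default 0.25,
boundary inclusive). Positive-control wells (wild-type reporter cells) are
reported with reductions but never enter the baseline or the hit set. The
cut-off applies to well means rather than per replicate — the published
account does not say which, and well means are the quantity the plate map
displays. Dose–response refinement sorts a compound's (concentration, mean)
points, averages duplicate concentrations, flags non-strict monotone
decrease, and reports the Spearman rank correlation as the trend statistic
(0 for a constant series). No IC50 fitting is attempted.

## Auxiliary assays

**Dispase fragments.** The dish is located as the filled convex hull of the
largest component above the lowest 3-class Otsu cut (separating the dark
surround from dish floor + fragments); `full_frame` mode skips detection.
Fragments are components above an in-dish Otsu (or fixed) threshold with
in-dish area ≥ `min_fragment_area` (default 500 px, inclusive — an area of
exactly 500 counts). Two guards return zero fragments instead of artefacts
on empty dishes: negligible bright/dim contrast, or a "bright" class
covering most of the dish (that split is floor-vs-rim, not fragments).

**LIVE/DEAD.** Total nuclei are counted on the Hoechst channel and dead
nuclei on the EthD-1 channel with the same nuclei segmentation; live =
total − dead. The channels are counted independently (no colocalisation
matching), mirroring the macro being reproduced; if dead > total the live
count clamps to 0 and the result is flagged inconsistent.

## Synthetic data: what it emulates and what it does not

The generator is the package's only data source and defines its study
conditions. A reporter field (default 384 × 384 px) contains ~80
non-overlapping cells (rejection-sampled nucleus centres, minimum spacing
2 r + 8 px); cell footprints are centre-Voronoi cells clipped to a 24 px
radius. The GFP channel is background (0.06) plus oriented band-pass noise
standing in for filament texture (amplitude 0.12) inside footprints, plus a
Gaussian punctum (σ = 2 px, peak 0.85) per planted aggregate, plus additive
Gaussian noise (σ = 0.01) clipped to [0, 1]. The default aggregate fraction
is 0.75 — the untreated regime in which 70–80% of cells are positive — and
the number of positive cells is round-half-up(fraction × n); treated
regimes in the simulated screen use fractions 0.10–0.20, the measured range
after effective treatment. Puncta are placed uniformly over eligible
footprint pixels, in the outer half of the cell radius with probability
`peripheral_bias` (default 0.7, reflecting the peripheral bias of real
aggregates), and at pairwise separation ≥ 4σ + 3 so every planted punctum
stays a separate connected component.

Deliberately absent: optical PSF modelling, uneven illumination, photon
(Poisson) noise, cell-shape irregularity, aggregate size/brightness
heterogeneity, and mitotic or overlapping nuclei. Passing tests therefore
show that the algorithm recovers known ground truth under controlled,
favourable imaging — they bound implementation correctness, not performance
on real micrographs, where thresholds would need recalibration.

Dish images plant Eden-growth blobs of *exactly* the requested pixel areas
(the ±5% contract is met with equality), ≥ 2 px apart, fully inside the
dish — which is what makes the 499/500 boundary test meaningful. Viability
fields render dead nuclei co-located with their Hoechst blobs and calcein
cytoplasm for live cells only.

## Problem sizes and numerical choices

Simulated screens use 96-well plates with 8 DMSO wells, 2 positive-control
wells, 5 active wells and 2 fields per well of 80 cells each; with ~45
analyzable interior regions per field this puts the worst-case false-hit
probability per plate at the percent level, so the designed hit set is
recovered exactly in ≥ 9 of 10 seeds. Recovery benchmarks use 10 seeds at
planted fractions 0%, 20% and 70%. All randomness flows through
`numpy.random.default_rng` seeded from configuration; identical
(config, seed) gives bit-identical images, and the analysis path contains
no randomness at all. Degenerate inputs are defined rather than accidental:
blank channels segment to zero nuclei, zero segmented nuclei make Voronoi
tessellation an error ("no cells segmented"), zero analyzable regions make
region calling an error ("nothing to call"), and percent positive is
undefined (an error) for zero regions.

## Known limitations

* Published cut-offs exist only for the hit threshold (25% reduction) and
  the fragment minimum (500 px). DoG scales, the intensity multiplier, the
  area window, the QC threshold and the background-coverage minimum were
  never published and are calibrated against the synthetic fixtures; on
  real data they are starting points, not facts.
* The Voronoi region of a nucleus is a proxy for the cell body; at low
  confluence it overestimates cell area, and peripheral puncta can be
  attributed to a neighbouring cell (visible as a small precision loss in
  the per-cell benchmark).
* Edge exclusion removes the entire border ring of cells, so small fields
  with few cells can have no analyzable regions at all.
* The dish detector assumes one bright, roughly convex dish per frame.
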