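# Methods

## Measurement model

The quantity of interest is the fraction of a Petri dish covered by a
mycelial colony, estimated purely from per-pixel red intensity. The
assumptions are:

- the scene contains three intensity classes — dark background, medium
  (the agar-filled dish), and colony — and under the default
  `light_colony` orientation they are ordered background < medium <
  colony. White aerial mycelium on darker medium satisfies this; a
  pigmented colony darker than its medium is handled by the
  `dark_colony` orientation, which reverses every comparison;
- class membership is decided per pixel by two thresholds on the red
  channel alone. No spatial reasoning is used: the dish domain is not a
  fitted circle but exactly the set of pixels clearing the dish
  threshold. This keeps the implementation faithful to a plain
  dual-threshold screen and makes the result independent of colony
  position and shape;
- the colony domain is intersected with the dish domain, so
  A_c <= A_d structurally and the per-plate ratio is always in [0, 1].

The group statistic eta = 100 * mean_i(A_c^i / A_d^i) is the mean of
per-plate ratios, not the ratio of summed areas, so plates with
different dish footprints contribute equally. Dispersion is the sample
standard deviation (n−1 denominator) of the per-plate ratios, reported
in percentage points and defined as 0 for n = 1.

## Preprocessing

Images are decoded to 8-bit RGB (grayscale promoted to three equal
channels, alpha dropped, deeper bit depths linearly rescaled with a
logged warning), reduced to the red channel, and resampled to a square
working raster (default 1024 px, minimum 16). Resampling is
nearest-neighbour with the pixel-centre mapping
`src = floor((dst + 0.5) * n_src / n_dst)`: it introduces no new
intensity values, so thresholds partition exactly the original
intensity set and the histogram's support is preserved. Non-square
inputs are stretched on both axes independently; aspect distortion does
not bias a pixel-count ratio. Since eta is a ratio, the working size
only controls discretization — eta for the same plate at 256, 512 and
1024 px agrees to well under 1 percentage point (the acceptance script
measures the spread, typically ~0.03 pp).

## Thresholds

Thresholds are intended to be selected manually from the red histogram,
mirroring how an operator screens a plate series; per-plate provenance
(file, thresholds, A_d, A_c) is logged to stderr so such runs are
auditable. Comparisons are inclusive on the bright side (`>=` under
`light_colony`), a fixed tie convention that makes results
bit-reproducible.

For unattended runs, `auto_thresholds` minimizes the total within-class
intensity variance over all two-threshold partitions of [0, 255]
(three-class Otsu by exhaustive search over the ~32k admissible pairs),
considering only partitions where all three classes are populated, with
ties broken to the lexicographically smallest pair. Known limitation:
variance minimization cannot place a boundary around a class carrying
negligible mass. Plates with no colony (bimodal histogram) raise a
"not trimodal-capable" error or, with noise, can split the medium mode;
a colony under roughly 1–2% of the frame is similarly invisible to it.
Degenerate or near-degenerate plates should be quantified with manual
thresholds.

## Growth rates and group comparison

Rates are difference quotients between two imaging days, in percentage
points per day (NCAR) or mm per day (diameter); for the standard day
9 → day 13 design the denominator is 4 days. Negative rates are kept
but logged as anomalous, since colonies do not shrink — on near-static
colonies thresholding noise can produce them. Fold changes of mean
rates are reported as undefined (an error, not infinity) when the
denominator rate is non-positive.

Groups are compared by one-way ANOVA followed by Tukey's HSD at
family-wise level alpha (default 0.05), requiring at least two groups
with two replicates each and nonzero within-group variance. The compact
letter display uses the insert-and-absorb construction ordered by
descending group mean (mean ties broken lexicographically by label):
it guarantees that two groups share a letter exactly when their
Tukey-adjusted comparison is non-significant. The test suite verifies
this equivalence against an independent studentized-range computation.
A Tukey-style procedure is the conventional reading of letter displays
at a stated family-wise confidence level with small balanced groups;
no other family-wise method is offered.

## Synthetic plates

The generator emulates the imaging design the toolkit targets: a bright
circular dish (radius 44% of the frame, i.e. a 90 mm dish spanning 88%
of the image) on a dark background with a concentric brighter colony,
three treatment groups with distinct radial growth rates, three
replicate plates per group, imaged on days 9 and 13. Default class
intensities are (10, 120, 230), giving inter-class gaps of 110. A pixel
belongs to a disk iff its centre (i + 0.5, j + 0.5) lies within the
radius — one documented convention shared by the renderer and the
brute-force oracle in the tests, which is what makes exact ground-truth
recovery a meaningful check. Noise is additive Gaussian on intensity,
clipped to [0, 255] after rounding, reproducible from the seed; no blur
is applied because the segmentation has no denoising stage to exercise.

Colony growth is linear in radius and capped at the dish radius:
`r(t) = min(r0 + rate * (t − d0), R)`. The default study starts all
groups at r0 ≈ 23 mm on day 9 (a 1.5 mm inoculum grown 9 days at the
control rate, all plates pre-incubated identically) with radial rates
of 2.385, 3.28 and 0.29 mm/day for the control-like, moderate-stress
and severe-stress groups — half the diameter rates of 4.77, 6.56 and
0.58 mm/day. Replicate variation is a multiplicative jitter on the
radial rate (relative SD, default 5% in the bundled study). Because
eta grows with the *square* of the radius, the NCAR-rate contrast
between groups is larger than the radial-rate contrast; the helper
`radial_rates_for_ncar_rates` inverts eta = 100 (r/R)^2 to construct
series with prescribed NCAR growth rates when the contrast is to be
controlled in NCAR space.

What the generator does not emulate: hyphal-front texture or edge
morphology, uneven illumination, lens distortion, reflections, colour
casts, or non-circular colonies. Passing tests therefore demonstrate
the correctness of the counting, ratio, rate and letter machinery on
images satisfying the three-class intensity model — not robustness to
real-world photographic artefacts, which manual thresholding is meant
to absorb.

## Numerical conventions and problem sizes

- eta is accumulated with compensated summation (`math.fsum`) of the
  per-plate ratios; exactness checks compare pixel counts as integers
  and eta with the identical floating-point expression 100 * (A_c/A_d).
- All randomness flows through `numpy.random.default_rng`; the
  timeseries simulator derives independent child seeds per plate from
  one `SeedSequence`, so outputs are byte-identical across runs and
  insensitive to rendering order.
- Tests and the acceptance script run on 96–512 px rasters and
  21-plate coverage sweeps; these sizes give exact ground-truth
  recovery and sub-0.1 pp discretization effects while keeping a full
  run to seconds. The defaults for actual use remain 1024 px.

## Design choices that were genuinely open

- Red channel vs grayscale: the toolkit reads the red channel of the
  original RGB image. For grayscale photographs the two coincide; for
  colour photographs the red channel best separates white mycelium
  from typically amber media.
- Working size (unspecified by the underlying procedure): default
  1024 px, CLI-configurable; it cancels in eta, which the scale
  invariance property verifies.
- Group/day metadata travels in a manifest CSV rather than being
  parsed from filenames: unambiguous and testable.
- The rate denominator is (d2 − d1) in days (4 for the standard
  design), equivalent to re-expressing the 96 h window.
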