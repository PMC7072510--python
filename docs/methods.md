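# Methods

This note documents the model behind `mnquant`, its tunable parameters, the
synthetic-data generator used as the test surface, the numerical choices
that were genuinely open, and the limitations of both.

## The assay model

The pipeline assumes an asynchronous adherent culture, fixed and
counterstained with a DNA dye, imaged at constant exposure in one 16-bit
grayscale channel per field, with several non-overlapping fields per well of
a multiwell plate. Under these assumptions micronuclei are identifiable
purely geometrically and photometrically: small (conventionally ≤ ⅓ of the
average nucleus), DNA-positive, close to — but disjoint from — a parent
nucleus. The pipeline encodes exactly that definition:

* **Thresholding is global and absolute** (a.u. on the camera scale), not
  adaptive. The built-in profiles' detection thresholds (7000 a.u. for
  nuclei, 3000 a.u. for spots) are meaningful only because exposure is held
  constant within an experiment; intensities are never normalised before
  thresholding. Otsu-style adaptive thresholding is deliberately not the
  default — it would decouple the profile values from their calibrated
  meaning — though nothing prevents a caller from deriving a threshold and
  passing it in.
* **Nuclei are solid objects.** DNA-stained nuclei often have dimmer
  interiors (nucleoli), so candidate components are hole-filled before
  measurement. 8-connectivity throughout.
* **Cell bodies are rings.** Without a membrane marker the cell boundary is
  unknowable from the DNA channel; a fixed-width annulus around each
  nucleus (10–15 µm depending on cell line) is the operational stand-in.
  Its width is a first-class profile parameter because cytoplasm size is
  strongly cell-line dependent.
* **No watershed splitting by default.** Touching nuclei merged by the
  threshold are resolved by adjusting the threshold, mirroring how the
  plate-imager workflow this reimplements is operated; automatic splitting
  is out of scope for the default path.

## Parameters

Per cell line (`SegmentationParams`; sizes are equivalent circular
diameters):

| parameter | HCT116 | FT194 | FT246 | meaning |
|---|---|---|---|---|
| Min/Max OS (µm) | 10/100 | 10/100 | 10/100 | nucleus size gate |
| DT primary (a.u.) | 7000 | 7000 | 7000 | nuclear mask threshold |
| ring width (µm) | 10 | 15 | 15 | cell-body annulus |
| Min/Max SS (µm) | 1/5 | 1/6 | 1/6 | spot size gate |
| DT spot (a.u.) | 3000 | 3000 | 3000 | spot threshold |

Optional features: `reduce_primary_mask_um` erodes each nucleus by a disk
before ring construction (recovers micronuclei hugging the nuclear
boundary); `background_flatten` subtracts a morphological background
(grayscale opening with a disk of `rolling_ball_radius_um`) before
thresholding, for fields with autofluorescent or uneven background. Both
default off: the clean default path should reproduce the plain
threshold-based method.

Filters (`FilterParams`): `periphery_margin_um` defaults to 30 µm — at 20×
magnification this reliably removes nuclei truncated by the field border.
`mn_area_fraction` defaults to ⅓. The maximal mean-intensity cutoff has no
default: it must be calibrated per experiment (see below).

**Pixel size is mandatory user input.** Every size parameter is physical
(µm), and the µm/pixel of a given scope/camera/objective combination cannot
be guessed; silently defaulting it would corrupt every size gate, so a
missing pixel size is a configuration error.

## Calibration

Two quantities are derived from control-condition data and then applied
plate-wide (pooled across control wells for stability; per-well calibration
is possible but noisier):

* **Intensity cutoff** — midpoint between the mean intensities of the
  interphase population to keep and the bright mitotic/apoptotic population
  to remove. The automated splitter treats objects brighter than 1.25× the
  median per-object mean intensity as the bright population; condensed
  chromatin is brighter than interphase chromatin by a wide margin, while
  interphase-to-interphase variation stays well under that ratio. (A plain
  Otsu split on the per-object means fails here: with bright bodies at a
  few percent abundance Otsu cuts inside the interphase bulk.) The cutoff
  is a suggestion; callers can always override it.
* **Micronucleus size cap** — the mean area of retained control nuclei
  times `mn_area_fraction`. The cap is inclusive (a spot exactly at ⅓ is
  still a micronucleus). Area-based capping is the default; the
  diameter-based variant (cap on equivalent diameter) is available as
  `mn_size_mode="diameter"`, since the ⅓ convention is stated sometimes in
  area and sometimes in diameter in the literature and the two differ
  (⅓ diameter ≈ 1/9 area).

## Scoring and statistics

The well frequency is the **ratio of pooled totals**, not the mean of
per-field ratios: fields differ in cell number, and pooling weights each
nucleus equally, which also makes the statistic robust to confluency
differences between conditions. Wells with zero retained nuclei (cytotoxic
doses; dead cells lift off) are flagged and dropped rather than scored 0 —
scoring 0 would bias dose-response curves downward exactly where toxicity
is highest. The replicate SD is the sample (n−1) standard deviation.

Mann–Whitney: U from rank sums with midranks for ties. With combined
n₁+n₂ ≤ 16 and a tie-free pooled sample the p-value is exact (full
enumeration of all C(n₁+n₂, n₁) rank assignments — at most 12 870 terms —
with two-sided p = min(1, 2 × one-sided)); otherwise the normal
approximation with tie-corrected variance and continuity correction.
Replicate groups in this assay are typically triplicates, so the exact path
is the one that matters; note a 3-vs-3 exact two-sided test cannot give
p < 0.1, which bounds what significance claims triplicate designs can
support. Ties force the approximation (exact conditional enumeration with
ties is not implemented). KS: D = sup |ECDF difference|, asymptotic p with
the n₁n₂/(n₁+n₂) effective size. **No multiple-testing correction is
applied** — comparisons are reported against a fixed α as is conventional
for per-cell-line tests; screens with many conditions should correct
downstream.

## The synthetic generator

`SyntheticSpec` defaults describe the conditions the pipeline targets:
1024×1024 px fields at 0.5 µm/px (20×-like), 111 interior interphase nuclei
per field so a 9-field well holds ~1000 nuclei, nucleus diameters 12–25 µm
at 45 000 ± 3 000 a.u. (≈ 0.7× saturation, matching the exposure guidance
of setting the longest exposure that keeps typical nuclei at ~80 % of
saturation), micronuclei of 1.5–3.5 µm at 20 000 ± 3 000 a.u. planted
1–5 µm beyond the parent boundary with per-nucleus Bernoulli probability
`mn_probability`, 3 near-saturation bright bodies (63 000 ± 1 000 a.u.,
11–14 µm), 4 nuclei forced into the 30 µm periphery band, background
500 a.u. plus a 300 a.u. planar ramp, Gaussian noise σ = 100 a.u., and
Gaussian edge softening σ = 0.125 µm.

Placement is rejection sampling with *geometric guarantees* chosen so that
noise-free renders are an exact-match surface: objects never overlap
(≥ 2 µm boundary gaps), interior nuclei stay ≥ 1 µm clear of the periphery
band while edge nuclei always enter it (so the pixel-level periphery filter
and the geometric rule-checker cannot disagree at the band boundary), and
every micronucleus is wholly inside its parent's ring, wholly outside all
nuclei, and strictly nearer its parent than any other object with ≥ 1–2 µm
margins. Intensity draws are truncated so the interphase and bright
populations can never straddle the calibrated midpoint cutoff. Exceeding
the per-object attempt budget raises an error naming the budget rather than
silently under-planting (silent skips would bias the planted frequency the
recovery tests estimate).

The edge-softening default deserves a note: the σ must stay well below a
pixel. A heavily blurred nucleus edge produces a shell of intermediate
intensities between the spot threshold (3000) and the primary threshold
(7000); that shell lies outside the primary mask and inside the ring, and
at σ ≳ 0.5 px it aliases into connected arcs large enough to pass the 1 µm
minimum spot size — i.e. structural false positives. At σ = 0.25 px the
shell is ≤ 0.12 px wide and its pixel-grid fragments stay below the minimum
spot size everywhere. Real images put noise and PSF blur in this band too,
which is exactly why the real assay needs threshold optimisation; the
generator keeps the regime where planted truth is exactly recoverable.

An independent rule-checker (`expected_retained_counts`) recomputes the
expected retained nucleus/micronucleus counts from the planted geometry
alone — ellipse extents vs the periphery band, planted intensities vs the
cutoff, planted areas vs the size cap — never from pixels. Tests assert the
pixel pipeline equals it exactly on noise-free renders (and, thanks to the
margins, it continues to match at the default noise level).

What the generator does **not** emulate: optical PSF, photobleaching,
debris and autofluorescent junk, micronucleus clusters, overlapping or
touching nuclei, chromatin texture. Passing tests therefore demonstrate the
*scoring machinery* is exact and unbiased under controlled conditions; they
do not validate segmentation robustness on difficult real images, which
remains the responsibility of the per-cell-line threshold optimisation the
workflow prescribes.

Determinism: one integer seed per field; plate fields derive seeds via
`SeedSequence([seed, well_index, field_index])`, making every well
independent yet bit-reproducible and any field re-renderable in isolation.

## Numerical choices

* Equivalent diameter (2√(area/π)) is the size measure for both gates; the
  profile tables give one length per bound, and equivalent circular
  diameter is the conventional reading for near-round objects.
* Ring ownership uses the exact Euclidean feature transform
  (`distance_transform_edt` with indices). Pixels exactly equidistant from
  two nuclei follow the transform's deterministic scan order; a
  lowest-label tie rule would cost an O(n_nuclei × image) distance stack
  per field for a measure-zero set of bisector pixels no result depends on.
* Spots straddling a ring boundary are kept iff ≥ 50 % of their area is in
  a ring (majority rule), then clipped to the majority owner's ring; owner
  ties break to the lower label.
* Mean intensities are always measured on the original image, never the
  background-flattened one, so the intensity filter sees true stain
  brightness.
* The periphery band is defined on pixel centers (a pixel is in the band
  when its center is within the margin of an image edge); a margin
  covering the whole field is a configuration error, not an empty result.
* Degenerate inputs: empty object lists are valid everywhere (an empty
  field is a result, not an error); wells with zero retained nuclei have
  undefined frequency and are dropped from statistics with a warning;
  fold-change normalisation refuses an all-zero siControl.

## Problem sizes in the test-suite and acceptance runs

Oracle-equivalence checks run 50 noise-free 256×256 px fields against a
pure-Python exhaustive flood-fill checker. Parameter-recovery runs 20
independent single-well plates of 9 × 1024×1024 px fields (~1000 nuclei per
well) at a planted rate of 0.05; dose-response runs a vehicle + 4-dose
triplicate ladder at the same well size. These sizes give binomial standard
errors small enough for 3-SE recovery bounds while keeping a full run in
the minutes range on one CPU.

## Known limitations

* Micronucleus clusters (several micronuclei fused into one mass, typical
  of mitotic slippage) are not detected as such; they fail the size gate or
  merge into one spot.
* Touching nuclei are not split; the method's remedy is threshold
  adjustment, not watershed.
* The intensity filter is one-dimensional (mean brightness); it cannot
  separate a dim apoptotic body from a nucleus.
* Exact Mann–Whitney is unavailable in the presence of ties; midrank +
  normal approximation is used instead.
* The KS p-value is asymptotic and conservative for very small size
  samples.
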