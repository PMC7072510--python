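# mnquant — automated micronucleus scoring from fluorescence micrographs

Micronuclei are small, membrane-bound, DNA-containing bodies found outside
the primary cell nucleus. They are a hallmark of genotoxic stress and
chromosome instability (CIN), and the *frequency* of micronucleus formation
— not just its presence — is what ranks the severity of a drug treatment or
a gene-silencing condition. `mnquant` is a scriptable, single-cell
quantitative imaging pipeline for exactly that measurement: it takes 16-bit
DNA-stain (Hoechst-type) fields from a multiwell plate and returns per-well
micronucleus frequencies, dose-response curves, silencing fold changes, and
rank-based statistics. It is aimed at imaging and toxicology labs that want
an open, reproducible alternative to proprietary plate-imager analysis
software for micronucleus assays, including moderate-throughput chemical or
siRNA screens.

## The measurement

For each field the pipeline computes three masks and one statistic:

1. **Primary (nuclear) mask** — pixels ≥ a detection threshold *DT*₁ (a.u.)
   form 8-connected, hole-filled components; components with equivalent
   circular diameter outside [Min OS, Max OS] (µm) are discarded.
2. **Secondary (cell-body) mask** — a ring of fixed width *w* grown outward
   from each nuclear boundary; contested pixels go to the nearest nucleus,
   so rings partition the inter-nuclear space.
3. **Spot (micronucleus) detection** — components of pixels ≥ *DT*₂ that lie
   inside a ring but outside every nucleus, with equivalent diameter in
   [Min SS, Max SS]; each spot is assigned to the nucleus owning its ring.

Three exclusion filters then remove known artefacts: nuclei touching a
30 µm image-periphery band (truncated nuclei masquerade as micronuclei),
objects brighter than a calibrated maximal mean-intensity cutoff (condensed
mitotic chromosomes and apoptotic bodies), and "spots" larger than ⅓ of the
average control-nucleus size (by definition not micronuclei). The per-well
frequency is the ratio of totals pooled over all fields of the well,

    MN frequency = Σ_fields retained micronuclei / Σ_fields retained nuclei,

reported both as a fraction and a percentage. Dose-response points are
mean ± SD over technical replicates relative to the vehicle control;
silencing results are per-replicate fold changes over the mean siControl
frequency (so siControl folds average to exactly 1). Group comparisons use
the Mann–Whitney rank test (exact by full enumeration for the tiny
replicate groups typical of this assay) and the two-sample
Kolmogorov–Smirnov test on micronuclear size distributions.

Built-in, per-cell-line parameter profiles are included for HCT116
colorectal cancer cells and the FT194/FT246 fallopian tube secretory
epithelial lines; `mnquant profile FT246` prints one.

A first-class synthetic-field generator (`mnquant.synthetic`) renders
Hoechst-like fields — elliptical interphase nuclei near 70 % of saturation,
dim planted micronuclei, near-saturation mitotic bodies, periphery-band
nuclei, uneven background, noise — with a complete ground-truth table, so
the entire pipeline is testable with no microscope data.

## Worked example

```python
import mnquant as mq
from mnquant.synthetic import SyntheticSpec, render_field

# render a synthetic field: ~111 nuclei, 5% carry a micronucleus
spec = SyntheticSpec(seed=3, mn_probability=0.05)
image, truth = render_field(spec)

params = mq.builtin_profile("HCT116")      # (10, 100, 7000, 10, 1, 5, 3000)
analysis = mq.analyze_field(image, params)

from mnquant.pipeline import calibrate_from_control_fields
from mnquant.config_io import FilterParams
cutoff, calib = calibrate_from_control_fields([analysis], FilterParams())
analysis = mq.analyze_field(image, params, intensity_cutoff_au=cutoff,
                            size_calibration=calib)
n_nuclei, n_mn = analysis.retained
print(f"cutoff = {cutoff:.0f} a.u., size cap = {calib.mn_max_area_um2:.1f} um^2")
print(f"retained nuclei = {n_nuclei}, micronuclei = {n_mn}, "
      f"frequency = {100 * n_mn / n_nuclei:.2f}%")
```

prints

```
cutoff = 54971 a.u., size cap = 92.8 um^2
retained nuclei = 111, micronuclei = 5, frequency = 4.50%
```

The calibrated intensity cutoff (~55 k a.u.) sits midway between the
interphase nuclei (~45 k) and the bright mitotic bodies (~63 k); the size
cap is one third of the measured mean nuclear area; the 111 retained nuclei
are exactly the planted interior interphase nuclei (the 4 periphery and 3
bright bodies were excluded), and all 5 planted micronuclei were recovered
— a 4.5 % frequency on this field.

The same flow runs from the shell: `mnquant simulate` writes a synthetic
plate as TIFFs + truth CSV, `mnquant segment` turns images into per-object
CSVs, `mnquant score` turns object CSVs plus a plate layout into
well/dose-response/fold-change/statistics tables. See `mnquant --help`.

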