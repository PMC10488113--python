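# Methods

This note documents the models, parameter choices and numerical
decisions behind `myoslice`, and what the synthetic-tissue validation
does and does not demonstrate.

## Thresholding model

Each channel is segmented with a histogram-based threshold on a
background-corrected image. A box-mean filter (edge length
`box_size_um`; default: the whole image) estimates the smooth
background; the residual (image minus background) is thresholded at
`t = c·σ + m`. Locality enters through the box-mean subtraction; `σ`
(standard deviation) and `m` (mode) are global statistics of the
residual. Two readings of this recipe were possible and both are
implemented: the default thresholds the residual itself, and
`threshold_on="original"` applies `t` to the raw intensities; a per-box
`σ` is available behind `local_sigma=True`. The mode is computed on a
histogram with bin width 1 intensity unit (microscopy counts are
integers) with ties broken toward the smallest bin, which makes the
threshold deterministic. Pixels exactly at `t` count as signal.

Degenerate inputs: a constant image has `σ = m = t = 0`, so every pixel
is "signal"; the result is flagged and a warning raised rather than
guessing. A box larger than the image clamps to the whole-image mean.
The mode statistic presumes the background, not the stain, is the modal
pixel population — true for dense myocardium, where myocytes fill most
of the field; on images that are mostly stain (e.g. a WGA channel of
sparse tissue) the threshold lands above the stain's own peak and the
mask comes out empty.

Box-size choice is deliberately *not* automated. Adapting the box to
region-dependent intensity variation is a subjective judgement; an
explicit per-run configuration value keeps results reproducible. The
box edge is bounded below at 10 µm, below which the background estimate
starts tracking the signal.

Channel defaults for `c` are 2 (DAPI), 3 (RyR), 1 (WGA), 0.5 (dextran),
2 (SERCA) and 4 (lipofuscin). After thresholding, the binary lipofuscin
mask (broadband autofluorescent granules, prominent in human
myocardium) is subtracted from the other masks, and each mask is median
filtered with radius 1 (square 3×3 majority window, edge-duplicating
reflection at borders — the kernel shape is a free choice and is fixed
here for determinism).

## Cell segmentation

Cells are separated by watershed on the negated Euclidean distance
transform of the WGA signal, which labels both the extracellular matrix
sheet between cells and the transverse tubules inside them. Those two
structures live at different scales, and this matters for seeding: on
the raw distance map, every inter-tubule pocket is a local maximum
1–3 µm deep, so maxima-based seeding (including h-maxima suppression at
any plausible depth) produces several seeds per cell. Seeds are
therefore derived at the ECM scale: the WGA mask is morphologically
opened with radius `opening_radius_um` (default 0.4 µm — wider than a
t-tubule, narrower than half the ECM sheet), which erases tubules while
preserving cell boundaries; the connected regions of the opened-mask
distance map deeper than `h_min_um` (default 1.0 µm) become one marker
per cell body. The watershed then floods the negated opened-mask
distance map restricted to non-WGA pixels, so t-tubule pixels remain
unlabelled and labelled pixels are never WGA-positive.

Regions smaller than `min_cell_area_um2` (default 100 µm², far below a
myocyte cross-section) are merged into the neighbouring label sharing
the longest boundary, or dropped when isolated; labels are then
renumbered contiguously. All steps are deterministic for a fixed mask
and parameter set. Segmentation faults (a cell split in two, two cells
merged through a gap in the ECM) are accepted rather than manually
corrected; the synthetic benchmark quantifies them.

## Viability classification

Per segment, the fraction of dilated binary-RyR pixels (disk radius
4 px) and dilated binary-dextran pixels (radius 3 px) is computed over
the segment's pixel count. A segment is RyR-positive at fraction
≥ 0.15 and dextran-positive at ≥ 0.2; the four combinations give the
classes live (RyR⁺/Dx⁻), dead (RyR⁻/Dx⁺), double-positive (a dying
intermediate: membrane already permeable, RyR staining not yet lost)
and double-negative (weakly stained myocytes or non-myocytes). Radii
are in pixels, matching the 0.1 µm/px acquisition scale. Dilation uses
an exact Euclidean disk, implemented as a distance-transform threshold
on large images (identical by definition, much faster). A separate
undilated RyR pixel percentage (`raw_ryr_density_pct`) is kept for
density comparisons, where dilation would inflate the value.

Image summaries report double-positive cell and pixel fractions
referenced to the union of RyR- and dextran-positive cells (pixels),
the mean fractions within the dextran⁻/dextran⁺ and RyR⁻/RyR⁺ strata
(pixel-pooled across cells by default, i.e. area-weighted;
`pool_pixels=False` switches to unweighted means of per-cell
fractions), and the Pearson correlation of the raw RyR and dextran
intensities over labelled pixels. The stratum means use the dilated
fractions, consistent with the classification rule.

## Structure metrics

**t-system.** Morphological closing (disk, default radius 5 px =
0.5 µm) of a cell segment fills its tubular invaginations; the closed-
minus-original difference intersected with the WGA mask is the cell's
t-system. The radius must exceed half the tubule width (~0.2–0.4 µm)
without bridging to neighbouring cells; inclusions wider than twice the
radius are not recovered (documented limitation). Crops are padded with
background before closing so the operation behaves as on an unbounded
domain. ΔTT is the mean, over the cell's interior pixels, of the
Euclidean distance to the nearest t-system pixel (µm); an empty
t-system leaves ΔTT undefined rather than infinite. Skeleton density is
the pixel count of the 1-px-thinned t-system divided by the cell's
total pixels, taken as interior ∪ t-system (the denominator could also
be read as the interior alone; the union is the default and the code
keeps both sets explicit).

**Nuclei.** 8-connected DAPI components with area ≥ 10 µm² (floor
suppresses speckle) are measured with equivalent-ellipse axes from
second central moments; circularity = short/long axis. Each nucleus is
assigned to the segment holding the majority of its pixels; nuclei over
background are retained with parent 0.

**RyR pattern.** Density is the undilated RyR-positive percentage of
interior pixels. Regularity is the fraction of AC spectral power at
radial spatial frequencies between 1/2.5 and 1/1.5 µm⁻¹ — the band
bracketing the ~1.9 µm sarcomeric z-line period. The cell's bounding
box is masked to the interior, mean-subtracted over the interior and
zero-padded, so the DC term vanishes exactly; a zero-AC-power cell
scores 0 by convention. The spectrum is 2D and radially integrated,
computed on raw intensities (not the binary mask); both choices were
open, and the 2D/raw combination is orientation-independent and
preserves cluster blur, which is the signature being measured. Cells
whose long axis is shorter than two periods of the slowest band
frequency (5 µm) are flagged not evaluable. Regularity is invariant to
affine intensity rescaling by construction.

## Diagnostic accuracy and statistics

The dextran assay is the gold standard: dextran-positive = dead,
dextran-negative = viable. RyR positivity is the test, and it tests
*for viability*, so TP = RyR⁺∧Dx⁻, FN = RyR⁻∧Dx⁻, TN = RyR⁻∧Dx⁺,
FP = RyR⁺∧Dx⁺. Sensitivity, specificity, PPV and NPV carry
explicit undefined flags on zero denominators instead of NaN
arithmetic. The ROC sweep reclassifies RyR positivity over a threshold
grid against fixed dextran truth; cells are pooled across the image
(per-image ROC averaging is out of scope). Note that genuinely
double-positive (dying) cells bound the achievable ROC area from below:
they carry both signals, so no RyR threshold can classify them
"correctly" against dextran truth — on tissue with mutually exclusive
states the AUC approaches 1.

Force–viability correlation uses OLS with an F-test against the
intercept-only model, via statsmodels. Summary rows report median, mean
and a normal-approximation 95% CI (mean ± 1.96·SE; flagged below n = 5;
a bootstrap CI was considered and left out as the sample sizes here
make the normal approximation adequate). Group comparisons use Welch's
two-tailed t-test, or the paired t-test for matched per-image values;
families of p-values are Holm–Bonferroni adjusted. A paired comparison
with identically zero differences has no defined t statistic and is
reported undefined rather than forced to p = 1.

## Synthetic tissue generator

The generator renders what the stains look like, with known truth:

- rod-shaped cells (default 60 ± 15 µm × 16 ± 3 µm apparent in-plane
  size; 2D confocal planes section myocytes obliquely, so apparent
  lengths sit below the full anatomical cell length) packed by
  rejection sampling with a 1 µm ECM gap, roughly aligned orientations
  (SD 6°), bounded at 50 attempts per requested cell — a shortfall
  returns fewer cells with a warning;
- WGA: the ECM fills all extracellular space; dashed transverse tubule
  lines cross cells at z-lines, carried by 90% of z-lines in live cells
  and 75% in dead/double-positive cells (the printed per-class study
  values differ only slightly, so these densities are kept close), none
  in double-negative cells;
- RyR: Gaussian clusters in rows along z-lines spaced 1.9 µm; live
  cells place clusters densely across the cell (0.3 µm transverse
  spacing, 0.08 µm positional jitter), so after blur the rows merge
  into the quasi-continuous striations characteristic of z-line
  staining; double-positive cells scatter sparser clusters by
  `ryr_jitter_um` (default 1.0 µm) with stronger blur — disorganised
  but still bright; dead and double-negative cells carry no RyR signal;
- dextran: homogeneous cytosolic fill in dead and double-positive
  cells;
- DAPI: one ellipse per cell, long axis along the cell; default areas
  49.4 µm² (live) and 44.0 µm² (dead/double-positive), axis ratios 0.45
  and 0.60 (dying nuclei rounder and smaller, the direction expected
  from pyknosis);
- lipofuscin: sparse granules (0.2 per 100 µm², radius 0.2–0.5 µm)
  bleeding into the other channels as broadband autofluorescence does;
- background: level 60 ADU with a ±20% linear gradient of random
  direction; Poisson shot noise at gain 4 ADU/photon followed by
  Gaussian read noise (SD 10 ADU); 12-bit output.

Absolute signal-to-background ratios are not published for any of the
stains, so the channel amplitudes (RyR 1500, dextran 800, WGA 900,
tubules 540, DAPI 2000, lipofuscin 2500 ADU over background) are
documented assumptions producing clearly bimodal histograms, not
calibrated values. Identical spec + seed reproduces output bit for bit.

What passing the synthetic benchmark shows: the implementation
correctly executes every stage of the published recipe and recovers
known truth when its assumptions hold. What it does not show:
performance on real tissue, where staining variability, out-of-focus
light, deconvolution residues, hypercontracted cells and non-myocyte
structures violate the generator's clean geometry. The benchmark
quantities (≈100 % classification accuracy, near-perfect segmentation)
are upper bounds specific to synthetic conditions.

## Problem sizes

The standard fixtures are a ~100-cell slice at 4600² px (default rod
size) for segmentation recovery and 200-cell slices at 5000² px
(45 ± 10 µm × 13 ± 2 µm rods) for classification and accuracy — chosen
as the smallest tissues in which per-class statistics are stable.
Monte-Carlo calibrations use 400–1000 replicates of 12-slice regression
datasets.

## Known limitations

- 2D only; no PSF or photobleaching simulation; stitched input assumed.
- The watershed accepts occasional split/merge errors by design.
- Double-positive cells are structurally intermediate by construction
  in the generator; real dying cells are more heterogeneous.
- The pixel-pooled stratum means weight large cells more than small
  ones; the unweighted variant is a config switch.
- SERCA channels reuse the RyR pattern metrics; no SERCA-specific
  model.
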