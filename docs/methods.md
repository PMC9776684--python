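# Methods

`pathomsi` implements a fully automatic, bimodal subtyping algorithm for
non-small cell lung cancer sections measured with both digital microscopy
(H&E whole-slide images, WSIs) and MALDI mass spectrometry imaging (MSI).
The algorithm has two stages: (1) a U-Net segments the WSI into tumor /
non-tumor, and (2) the MALDI spectra that fall inside the segmented tumor
regions — located through an anchor-based affine co-registration — are
classified into adenocarcinoma (ADC) vs. squamous cell carcinoma (SqCC) by
a 1-D convolutional network, and aggregated per section by a majority vote
with a quality-control (QC) rule.

Because no paired WSI/MSI cohort with spot-level ground truth is openly
deposited, the package ships a first-class synthetic-cohort generator and
all quantitative claims are made against its known ground truth.

## The two-stage model

**Stage 1 — segmentation.** Images are downsampled (block mean, default
2×), tiled (64 px tiles, 32 px stride, edge tiles anchored or zero-padded),
and classified per pixel by an encoder–decoder network with skip
connections (depth 4; base width 32 for the reference build, 8 for the
desk-scale runs; ~0.5 M–7.7 M parameters). Tile probabilities are stitched
by averaging overlaps into a heatmap; thresholding at 0.5 (ties → tumor)
gives the binary mask. The loss is pixelwise cross-entropy with
inverse-frequency class weights computed per batch — tumor occupies well
under 10% of tissue pixels and an unweighted loss reliably collapses to
the all-background solution. Training tiles are sampled so at least 25%
contain tumor.

Training follows a repeated-training protocol: each configuration is
trained `repetitions` times (default 5; 2 in the desk-scale profile), the
validation IoU is recorded after every epoch, and the single checkpoint
with the best validation IoU over all epochs and repetitions is kept.
Model selection for segmentation uses three-fold cross-validation over the
six TMA-like samples (three groups of two): network Seg*i* is trained on
two groups and validated on the third, which also fixes which network's
masks are used downstream for each group.

**Co-registration.** The MSI spot grid and the WSI live in different
coordinate systems. From ≥ 3 manually set anchor pairs a planar affine map
is fitted by least squares (exact for 3 non-collinear anchors). Collinear
anchor sets are rejected; a large anchor RMSE (> 2 px) logs a warning but
does not reject, since anchors are few and curated. Spot membership in any
mask is decided by sampling the mask at the spot's transformed center,
rounded half-away-from-zero, with integer division by the mask's
downsample; a footprint-majority variant exists behind a flag for
sensitivity checks. Out-of-bounds spots are non-members and tallied; a
transform that maps *every* spot out of bounds raises, as this indicates
misregistration.

**Spectral preprocessing.** Convolutional baseline correction (rolling
minimum over 100 Da, smoothed by an equal-width moving average, clipped at
zero) is applied at import time. The chain proper then runs, in order:

1. m/z restriction to 700–2700 Da;
2. intensity profile normalization — division by a moving median of the
   intensity over a 50 Da window, floored at 1e-8 × the spectrum maximum
   (which makes the output exactly invariant to per-spectrum scaling);
   the moving median is evaluated every quarter window and linearly
   interpolated, which reproduces the dense median at a fraction of the
   cost because the profile is smooth by construction;
3. statistical recalibration — a rigid per-spot mass shift δ ∈ ±0.25 Da is
   estimated by cross-correlation against the channel-wise mean spectrum
   and removed by linear interpolation.  Three numerical details matter:
   the spot's own contribution is excluded from the reference (otherwise
   its noise autocorrelates at zero lag and biases every δ toward 0); both
   sides are high-pass filtered (2 Da moving-average subtraction) so peaks
   rather than baseline carry the correlation; and the correlation is
   evaluated band-limited via the Fourier shift theorem on a quarter-step
   grid with a final parabolic fit, because linear interpolation scallops
   the correlation toward integer lags.  Two passes are run — the first
   reference is blurred by the very shifts being estimated;
4. peptide mass resampling — re-gridding to one channel per nominal
   peptide mass, centers k·λ with λ = 1.000495 Da, each new intensity the
   trapezoidal integral over [k·λ ± λ/2] (1999 channels for 700–2700 Da);
5. spatial smoothing — 3×3 mean over existing grid neighbors, missing
   spots excluded from the average;
6. a second profile normalization (same window as the first);
7. log transform x ↦ ln(1 + x), mapping 0 to 0.

The λ default is the canonical peptide nominal-mass spacing; the profile
window, recalibration bound and smoothing kernel are conventional choices
documented as assumptions, not reconstructions of any particular vendor
chain.

**Stage 2 — spectrum classification.** A small 1-D residual convnet over
the 1999-channel preprocessed spectrum: a width-5 convolution (≈ 5 Da, the
span of a peptide isotope envelope), average pooling, two residual blocks,
then average pooling, flattening and a dense 2-class softmax head. Two
design points deviate from a plain conv-plus-global-pooling architecture,
and deliberately so:

* *Position-aware head.* The ADC and SqCC classes differ in **which**
  masses carry marker peaks, not in local peak shape. A fully
  convolutional network followed by global average pooling is translation
  invariant and therefore cannot represent this distinction at all — on
  synthetic data it cannot even fit its training set, while a logistic
  regression on raw channels is perfect. The dense head over pooled
  positions restores position sensitivity, matching the dense-head design
  of published peptide-imaging classifiers.
* *Input standardization.* Preprocessed spectra are dominated by a flat
  shared level (log of the normalized profile) with the class signal a
  small deviation in few channels; inputs are z-scored per channel with
  training-set statistics stored inside the model.

Training mirrors the segmentation protocol (repetitions + best epoch),
with balanced accuracy on the validation sections as the selection metric.
Exact probability ties at prediction time resolve deterministically to ADC
and are counted.

**Training-set variants.** Three classifiers are trained per run,
differing in where their spectra come from: MALDI1 trains on the TMA
annotation spectra and validates on section annotation spectra; MALDI2
keeps the same training set but validates on Seg1-mask section spectra;
MALDI3 trains on segmentation-derived TMA spectra — each TMA group
contributes the regions found by the network that was *validated* on that
group, so no network labels its own training data — and validates on
Seg1-mask section spectra.

**Evaluation subsets.** Per test section, four spot sets: D1 = inside the
(incomplete) annotations; D2 = inside the segmented tumor; D3 = D2 \ D1;
D4 = the complement of D2. Spectrum-level balanced accuracy treats every
spectrum of a section as carrying the section's diagnosis, so D2–D4
knowingly contain non-tumor spectra.

**Aggregation and QC.** A section is assigned the class of strictly more
than 50% of its classified spectra in the evaluated subset; an exact tie
is inconclusive. The majority fraction p gates quality control: the
verdict counts as conclusive only when p ≥ 0.9 (configurable). Confusion
tables report QC-passing calls per class plus a p-below-threshold column,
so each true-class row sums to its section count; accuracies are reported
with and without QC.

## The synthetic cohort

One labeled scene per sample drives both modalities. A tissue ellipse
holds 2–3 disjoint elliptical tumor regions (all of the section's
diagnosis), ring-shaped bronchus-like confounders, and necrosis patches at
tumor boundaries. The H&E rendering gives tumor a darker hue and ~6×
higher nucleus-dot density than normal tissue, with confounders in
between — hard negatives for the segmenter. The MSI rendering puts, on a
shared 0.1 Da axis over 690–2710 Da, an exponentially decaying baseline,
8 shared tissue peaks, and 4 subtype marker peaks present only under tumor
(attenuated ×0.2 under necrosis, which is labeled non-tumor). Every peak
is an isotope envelope: five Gaussians (σ = 0.1 Da) spaced 1.00335 Da with
Poisson(mass/1800) relative heights. Per spot, a rigid mass shift
~ U(±0.2 Da), a multiplicative log-normal intensity factor (CV 0.15) and
truncated Gaussian noise (σ = 0.1, versus marker heights of ~0.7–1.0, i.e.
markers ≥ 5× noise) are applied. The true spot-grid-to-pixel transform
(default: scale 12, 2° rotation, offset) generates jittered anchor pairs
(σ = 0.3 px). Whole-section annotation masks cover ~30% of the true tumor
area via shrunken, jittered per-region ellipses; TMA annotations are
complete.

What the generator does **not** emulate: realistic histological texture,
stain variability, measurement drift over acquisition time, mass-dependent
(non-rigid) calibration error, biological heterogeneity within a subtype,
and partial-volume spectra at region boundaries. Passing tests therefore
show that the pipeline's machinery recovers planted structure under
controlled noise — not that it would reach the same numbers on clinical
material. One concrete consequence: here D4 (outside the segmentation)
contains essentially no tumor spectra, so its majority votes carry no
subtype information, whereas on real sections D4 still contains tumor the
segmentation missed; the 100%-after-QC check is therefore asserted on
D1–D3.

## Problem sizes and defaults

The desk-scale run profile used by the tests and the acceptance script:
256×256 px scenes; 6 TMA-like samples (3 ADC / 3 SqCC, three
cross-validation groups of two), 6 validation and 8 test sections;
~440 spots per sample at 0.1 Da sampling (20,200 raw channels → 1999
after resampling); segmentation at downsample 2, base width 8, 8 epochs ×
2 repetitions per fold; classifier with 8 feature channels, 15 epochs × 2
repetitions per variant. A full run takes a few minutes on one CPU and is
deterministic for a fixed seed under single-threaded execution; all stage
seeds derive from the one global seed via `numpy.random.SeedSequence`.
The paper-scale cohort layout (14 validation / 16 test sections,
5 repetitions) is available via `CohortConfig.paper_scale()` and the
dataclass defaults.

## Numerical choices and edge cases

* Rounding of transformed spot centers: half away from zero (symmetric).
* Binarization ties at exactly 0.5 → tumor; IoU of two empty masks := 1.
* Exact 50/50 votes → inconclusive, p = 0.5, never random.
* Exact classifier probability ties → ADC, tallied.
* All-zero spectra pass through profile normalization unchanged, tallied.
* Recalibration of a single-spot dataset returns δ = 0 (self-reference).
* Stage caching is keyed on content hashes of the configuration slice and
  upstream stamps; deleting a stage's stamp re-runs it and everything
  downstream.

## Known limitations

* The two network architectures are functional stand-ins at desk scale,
  not reproductions of the published architectures they gesture at; with
  the numpy backprop implementation, large images or cohorts would need a
  GPU framework.
* Recalibration models a rigid shift only; mass-dependent warps are out of
  scope (an extension point in `recalibrate`).
* The profile-normalization median is evaluated on a stride and
  interpolated; for pathological spectra with profile structure narrower
  than a quarter window the dense median would differ.
* Segmentation IoU is reported for the tumor class (plus a class-averaged
  variant); on the small synthetic rasters boundary pixels bound the
  achievable IoU to roughly 0.85–0.9.
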