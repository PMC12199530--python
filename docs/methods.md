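# Methods

This note records the measurement models behind each module, the meaning
and rationale of every default parameter, what the synthetic generators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## 1. Glomerular immunofluorescence (`glomquant`)

**Model.** A kidney cross-section carries a glomerular marker channel
(e.g. synaptopodin) in which glomeruli appear as bright, roughly round
regions tens of microns across, and one or more target channels whose mean
fluorescence intensity (MFI) per glomerulus is the readout. Segmentation
uses only the marker channel; quantification is a plain arithmetic mean of
each channel over each labeled region, so the measurement is unbiased for
any additive-noise model with zero-mean noise.

**Pipeline.** Gaussian smoothing (`sigma_um = 5`, of order a tenth of the
glomerular diameter — large enough to merge intra-glomerular texture,
small enough not to fuse neighbors) → global Otsu threshold → hole filling
→ binary opening (`opening_radius_px = 2`, removes thresholding specks) →
connected components → minimum equivalent-diameter filter
(`d_min_um = 30`, below the size of a real glomerulus, so debris and
partial profiles are discarded).

**Numerical choice: decimated thresholding.** Smoothing at σ = 5 µm
(≈ 13 px at the default 2.64 px/µm) removes all structure finer than σ,
so the smoothing/threshold/morphology stages run on a grid decimated by
`f = max(1, int(sigma_px / 3))` (keeping ≥ 3 px per σ) and the binary
mask is upsampled by pixel replication afterwards. Differences against the
full-resolution pipeline are confined to single-pixel boundary wiggles;
large sections segment ~4× faster, which keeps hundred-cohort simulation
studies within interactive runtimes.

**Pluggability.** `mask_from_array` wraps any externally produced label
image (e.g. a trained network's output) in the same `LabelMask` type, so
measurement and aggregation are segmenter-agnostic; masks record their
`provenance`.

## 2. Filtration-slit morphometry (`pemp`)

**Model.** In super-resolution images of slit-diaphragm proteins, the slit
network is a bright curvilinear ridge ~1 px-scale wide after PSF blurring
(effective resolution ≈ 119 nm FWHM at 30 nm/px sampling). The readout is
the **filtration slit density** FSD = total slit length / capillary area
(µm⁻¹). Healthy capillaries carry dense meandering slits; effacement
straightens and spaces them out, lowering FSD.

**Pipeline.**
1. Matched-filter Gaussian smoothing, `smooth_sigma_um = 0.05`
   (≈ PSF σ ≈ 50 nm): maximizes ridge SNR without broadening slits beyond
   the optical resolution.
2. White top-hat with a disk of `r_th_um = 0.5` (decomposed structuring
   element for speed): removes smooth background and any constant offset,
   so thresholding sees only ridge-scale structure.
3. Hysteresis threshold: seeds above the Otsu level of the top-hat image,
   grown down to half that level. Hysteresis keeps dim slit segments that
   connect to bright ones and rejects isolated noise of the same
   brightness.
4. Topological thinning (`skeletonize`) to 1-px curves; length is summed
   over 8-connected skeleton edges with weight 1 (orthogonal) and √2
   (diagonal). This edge-weighted length is exact for straight axis
   aligned and diagonal lines and biased by at most a few percent for
   oblique ones (the classical staircase bias of grid skeletons).
5. Capillary area from the slit mask itself: Euclidean closing with
   radius `r_close_um = 1` (implemented as two distance transforms, which
   is much faster than a disk-structuring-element closing at this radius
   and exactly equivalent) — the radius exceeds half the typical slit
   spacing so the closing bridges between adjacent slits; hole filling
   absorbs the interior; islands below `a_min_um2 = 4` are dropped.

**Resolution estimator.** `estimate_fwhm` measures the full width at half
maximum of a single-peaked line profile. The baseline is the mean of the
two end samples (robust to a constant offset), the half level sits midway
between baseline and peak, and both crossings are located by linear
interpolation between samples; flat or monotone profiles are rejected.
On a Gaussian of σ = 50.53 nm sampled every 10 nm the estimator returns
119.01 nm (theoretical FWHM = 2√(2 ln 2)·σ = 119.0 nm).

**Marker interchangeability.** `marker_concordance` computes FSD
independently on two channels (default MAGI2 and nephrin) of each image in
a list and correlates the paired per-image values (Pearson by default,
Spearman optionally for rank concordance). Images where either channel
fails are excluded and logged; at least three surviving pairs are
required.

## 3. Larval vasculature (`vasctrack`)

**Model.** A short brightfield movie of a zebrafish tail at 0.65 µm/px:
circulating erythrocytes are the only moving structures, so pixels whose
intensity varies over time mark the perfused lumen. A single gc-eGFP
fluorescence frame then yields mean intravascular plasma fluorescence;
plasma-protein loss (e.g. after knockout of a slit-diaphragm gene) shows
up as a reduced ratio versus the reference group.

**Pipeline.** Each frame is divided by its global mean (exactly cancels
frame-to-frame illumination gain), the per-pixel temporal SD is
thresholded with Otsu, the mask is cleaned by opening
(`opening_radius_px = 1`) and a minimum-area filter (`min_area_px = 50`),
and finally dilated by `dilate_px = 1` to cover lumen margins the moving
erythrocytes did not fully sweep. An all-zero motion map yields an empty
mask with a warning (acquisition failure), and measuring fluorescence
over an empty mask raises — such larvae must be excluded, not silently
scored zero.

**Numerical choice: exact zeros.** `np.std` leaves ~1e-16 residue on
constant pixel series (rounding in the mean); pixels whose normalized
series has zero peak-to-peak range are therefore forced to SD exactly 0,
so "no motion" is a crisp, testable condition.

`normalize_cohort` divides every larva's value by the reference-group
mean, making the reference ratios average exactly 1 by construction.

## 4. Statistics (`stats`)

Dispatch mirrors common practice for imaging and qPCR readouts:

- Normality per group by the Kolmogorov–Smirnov test in its
  estimated-parameters form (Lilliefors); the plain KS test against a
  fully specified normal is anti-conservative when mean and SD come from
  the sample. Groups too small to test (n < 5) cannot reject normality
  and stay on the parametric branch.
- Two groups: Welch's t (unequal variances) or Mann–Whitney U.
- More groups: Brown–Forsythe one-way ANOVA (the F* statistic with
  Satterthwaite denominator df, robust to variance heterogeneity) with
  Dunnett's two-sided comparisons against a declared control; non-normal
  data use Kruskal–Wallis with Bonferroni-adjusted Mann–Whitney
  comparisons versus control.
- The multivariate-t integration inside Dunnett's adjustment is Monte
  Carlo; a fixed random state makes results run-to-run identical.
- ΔΔCt: ΔCt = target − reference per sample, ΔΔCt subtracts the
  calibrator-group mean ΔCt, fold = 2^(−ΔΔCt). The fold is computed with
  a scalar power so the identity `fold == 2**(-ddct)` holds bit-exactly;
  the calibrator group's geometric-mean fold is exactly 1, and folds are
  invariant to any constant Ct shift applied to both genes.
- Type-I error of the full dispatch chain is calibrated: on null
  three-group normal data the control-vs-group comparisons reject at
  5 ± 2 % (verified by simulation in the acceptance tests).

## 5. Synthetic data (`synthdata`)

All generators are seeded (`numpy.random.default_rng`) and return exact
ground truth alongside the images.

**Section phantoms.** 1200×1200 px at 2.64 px/µm; 20 non-overlapping
disk-shaped glomeruli of radius 18–26 µm with a bright marker channel and
a target channel whose per-glomerulus mean encodes the group effect
(control 1.0×, MCD 1.3×, primary FSGS 0.6×, secondary FSGS 1.0× — the
secondary form loses podocytes rather than down-regulating the target,
so its mean is unchanged). Multiplicative per-glomerulus noise has
CV = 0.2 and per-subject scale CV = 0.1. The generator does **not**
emulate tubular autofluorescence, sectioning artifacts or uneven
illumination — it isolates the segmentation-and-ratio question.

**Slit phantoms.** 512×512 px at 30 nm/px, PSF 119 nm FWHM. Slits are
drawn inside an elliptical capillary as evenly spaced parallel chords at
a random orientation, plus a rim curve. Each chord is displaced by a
smooth random meander whose amplitude scales with
`0.30 · spacing · (1 − effacement)`; critically, all chords share one
common smooth displacement field (each chord's displacement is
0.9·common + 0.436·individual). Real interdigitating foot processes
undulate **together** — the slit between two processes meanders, but the
gap between adjacent slits stays near the foot-process width. Independent
meanders would make adjacent slits approach each other at random and
merge below the 119 nm resolution, which is physically wrong and would
bias FSD recovery. The total curve length is trimmed to the budget
`target_fsd · area · (1 − 0.75 · effacement)`, so the ground-truth FSD is
exact, decreases strictly with effacement, and equals `target_fsd_per_um`
(default 3.0) at effacement 0. Both channels rasterize the same curves
(second scaled by `channel_gain_ratio`) with independent additive
Gaussian noise. Not emulated: slit-diaphragm substructure below the PSF,
marker-specific labeling efficiency differences, depth-dependent blur.

**Vessel movies.** 10 frames of 128×160 px at 0.65 µm/px: a straight
vessel band (plasma level 100, background 40), dark erythrocyte-like
specks at 0.05 µm⁻² translating 4 px/frame along the band (wrapping, and
masked so no speck intensity leaks outside the vessel — outside the band
the frames are bit-identical without noise), additive Gaussian noise
SD 2. The fluorescence frame is the plasma level inside the band plus
noise. The knockout cohort generator scales plasma to 70 % with
per-larva CV = 0.25. Not emulated: pulsatile flow, vessel branching,
photobleaching, larva-to-larva anatomy differences.

**Fixture tables.** Two small CSVs bundled as package data describe the
study designs the statistics layer must handle (patient characteristics
with censored proteinuria values, and the animal/cohort group sizes).

## 6. I/O and configuration (`io`)

Images travel as multi-page grayscale TIFF (`photometric="minisblack"`,
so a 3-plane float stack is never misread as RGB) with channel names and
the physical pixel size in a JSON sidecar (`X.tif.json`) — TIFF
resolution tags are dialect-ridden; a sidecar is unambiguous. Integer
data round-trip bit-exactly. `RunConfig` (pydantic, `extra="forbid"`)
validates every stage parameter, rejects unknown keys, and round-trips
losslessly through YAML/JSON; `run_pipeline` logs the fully resolved
parameter set so every result is attributable to an exact configuration
and seed.

## 7. Limitations

- The classical segmenters are tuned for the phantom geometry
  (high-contrast disks, ridge-like slits, a single vessel band); real
  tissue will need parameter adjustment or an injected learned mask.
- Skeleton-based length measurement carries an orientation-dependent
  staircase bias of up to ~8 % for straight oblique lines (typically
  ≤ 5 % on meandering slit networks).
- The FWHM estimator assumes a single-peaked profile over a flat
  baseline; overlapping structures need profile selection upstream.
- Dunnett's comparisons assume the parametric branch was correctly
  taken; with very small groups (n < 5) normality is untestable and is
  assumed.
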