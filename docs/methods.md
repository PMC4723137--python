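# Methods

This note records the scientific and numerical choices behind `marginmap`:
what the pipeline assumes, how each stage is defined at the pixel level, why
the defaults are what they are, and what the synthetic phantoms do and do not
establish.

## Imaging model and units

Analysis images are single-channel 8-bit rasters at a pixel pitch of
1.5 µm/px (a 350×300 px region of interest spans 525×450 µm). Deeper integer
inputs are linearly rescaled so the observed maximum maps to 255; float
images are quantized by a linear map of [0, max] onto [0, 255] with
round-half-up. Color inputs are rejected rather than silently reduced — the
choice of channel is a scientific decision the caller must make.

The optional structured-illumination utility reconstructs an optically
sectioned image from three frames carrying a projected sinusoid at phases
0, 2π/3, 4π/3 with the standard square-law estimator
S = (√2/3)·√((i₀−i₁)² + (i₁−i₂)² + (i₂−i₀)²). For frames c + m·cos(θ+φₖ)
this returns exactly m, independent of the unmodulated background c; the
identity holds to machine precision in float and to one quantization step
after 8-bit rounding of the frames.

## MSER segmentation

Nuclei are **bright** extremal regions (AO staining), so only the
bright-polarity pass is run; dark-region detection is available by inverting
the image. Components use 4-connectivity by default (conservative blob
separation at the small nuclear scale; 8-connectivity is a config switch).

The component tree is built by a single sweep of the distinct gray levels
from high to low: connected components of {I ≥ t} are matched level-to-level;
when components merge, the largest child continues the growth node (ties:
the child containing the smallest row-major pixel) and the others are closed
with a parent link. Each node stores its area at every level where it
changed. Thresholds between occupied gray levels produce identical
super-threshold sets and are handled implicitly.

For a node alive at threshold t the size-variation score is
q(t) = (A(t−δ) − A(t+δ)) / A(t) with δ = ⌈Delta/2⌉, the lookups clamped to
the thresholds at which the node exists. Selection:

* maximal runs of equal q that are lower than both neighboring runs are
  local-minimum plateaus; the **lowest threshold** of a plateau is selected
  (largest area — favors whole-nucleus capture, and is deterministic);
* candidates must satisfy q ≤ MaxVariation and the size band (below);
* the component spanning the entire image is never emitted (a flat image has
  no extremal structure);
* identical pixel sets arising at several thresholds are reduced to the
  lowest-q (then lowest-threshold) instance;
* nested candidates whose relative area difference (A_out − A_in)/A_out is
  below MinDiversity are pruned round-by-round: in each round every
  candidate is compared with its nearest surviving containing candidate and
  the less stable of the pair is dropped (ties drop the inner one); rounds
  repeat to a fixed point, so the result is order-independent.

A region's reported `level` is the highest threshold at which its exact
pixel set is extremal, which equals the minimum intensity over the set.

**Size band units.** The defaults MinArea 3 / MaxArea 15 are interpreted as
equivalent-circle *diameters in pixels* (areas ≈ 7–177 px): at 1.5 µm/px
they correspond to the expected nuclear diameter range (3 px = 4.5 µm < 5 µm;
15 px = 22.5 µm > 20 µm), and the bead-phantom sizing study (measured
equivalent diameters near 12 µm ≈ 48 px area for 10 µm beads) is only
possible under this reading. A literal pixel-area interpretation is
available via `size_unit="area"`.

**Oracle.** `mser_bruteforce` recomputes the identical contract by literally
thresholding at all 256 levels and matching components by set containment.
The test suite asserts pixel-set equality with the tree detector over
hundreds of random images and configurations; this is the primary
correctness argument for the sweep implementation.

**A property worth knowing.** Because q is clamped to a node's lifetime, a
component that exists at only one or two thresholds has q ≈ 0 and is
"perfectly stable". On flat backgrounds, uncorrelated pixel noise of even
±1 gray level therefore produces many spurious in-band detections. Real
images from the modeled instrument oversample the 4.4 µm optical resolution
about 3× at 1.5 µm/px, which suppresses single-pixel noise at the analysis
scale; images from other sources should be checked for this regime (a light
pre-smoothing restores it).

## Bin-level morphometry

ROIs are tiled by disjoint 50×50 px bins anchored at the origin
(⌊w/50⌋×⌊h/50⌋ bins; trailing partial strips are discarded — the canonical
ROI divides evenly into 42 bins). Per bin:

* **area fraction** — segmented pixels inside the bin / 2500, strictly
  pixel-wise (a region straddling a boundary contributes its pixels to each
  bin it touches), so bin area fractions sum exactly to the segmented area;
* **average diameter** — unweighted mean of 2√(A/π)·pitch over the regions
  whose *centroid* lies in the bin (a straddling region contributes its
  shape statistics to exactly one bin);
* **average shape** — unweighted mean of perimeter/area, with the
  crack-length perimeter (count of 4-neighbor edges between region and
  non-region, image border included, × pitch). Crack length is exact for
  axis-aligned shapes and fixes the scale of the shape coefficient;
* bins with no regions and no overlap are flagged **empty**.

Features are stored in physical units (µm, µm⁻¹). Size-thresholded model
variants can restrict the region set to equivalent diameters < 10 µm or
≥ 10 µm before binning.

## Logistic classification

The bin classifier is p = σ(β₀ + Σβₖxₖ) over a declared subset of the three
features; a bin is called tumor when p > α strictly (α = 0.5 default).
Muscle and adipose bins are pooled as the negative class.

Fitting is unpenalized maximum likelihood by IRLS/Newton: convergence when
the largest coefficient update is below 1e-8, at most 100 iterations.
Complete separation is detected (diverging coefficient norm, or a
non-converged estimate that already classifies every observation correctly);
the last stable estimate is kept and flagged, with an optional ridge refit
for callers needing finite coefficients. Standard errors come from the
inverse Fisher information; the implementation agrees with statsmodels'
Binomial GLM to ~1e-8 in the tests. The estimator is sklearn-compatible
(`BinLogisticRegression`).

Four published coefficient sets ship as built-in models, one per variable
subset; the three-variable set is β = (2.659, 44.074, −0.962, −0.8652).
They are declared in **pixel units** (diameter in px, shape in px⁻¹ — the
regionprops convention): under µm units these coefficients cannot push any
bin past p = 0.5 at realistic nuclear densities, so the pixel convention is
the only one consistent with the reported margin behavior. Prediction
converts µm-valued features through the pitch; models fitted by the package
record the units they were trained in.

**Unscored bins.** Bins with no centroid-assigned region (which includes all
empty bins) are assigned p = 0: their diameter and shape are undefined, and
a zero-filled feature vector would otherwise score σ(β₀) ≈ 0.93 — a
spurious positive for bins containing essentially nothing.

ROC analysis varies α over midpoints between consecutive distinct scores
plus ±∞ endpoints; AUC is the trapezoid-rule area (equal to tie-corrected
Mann–Whitney concordance, cross-checked against scikit-learn); the Youden
threshold maximizes sensitivity + specificity − 1, breaking ties toward the
lower α (higher sensitivity).

## Whole-margin mosaics

Frames are placed at explicit physical offsets (µm → px with round-half-up);
registration is out of scope because the modeled acquisition moves a
micrometer stage (steps 1300 µm in x, 1800 µm in y). Overlaps resolve by
painter's order — the later tile wins — which is deterministic and
sufficient for bin-wise analysis. With the default 1376×1040 px frames the
y-step leaves a thin uncovered strip between frame rows; uncovered bins are
empty and score 0, and they stay in the denominator of the positivity
summary (the fraction of bins with p > threshold, reported per threshold).

## Synthetic phantoms

The generators are pure functions of (parameters, seed) and emulate the
qualitative appearance of the three dominant tissue classes:

| class | nuclei / 350×300 ROI | nucleus diameters | background |
| --- | --- | --- | --- |
| tumor | 420 | 6–14 µm | smooth mid-level field (75 ± 35) |
| muscle | 40 | 5–9 µm | bright 75 µm fiber bands (115–150), dark 5 px septa; nuclei on septa |
| adipose | 25 | 5–9 µm | dark field (15) with thin bright streaks on 120 µm Voronoi cell borders; nuclei on borders |

Nuclei are uniform disks (intensity ≈ 190–210 ± 15) within the biologically
expected 5–20 µm range; scenes are blurred with an isotropic Gaussian of
4.4 µm FWHM standing in for the system point-spread function, read noise of
σ = 0.5 gray levels is added, and the result is quantized to 8 bits. The
nucleus counts set the class separation that drives everything downstream
(bin area fractions ordered tumor ≫ adipose > muscle); the appearance
parameters are constrained only qualitatively and were chosen so the
phantom classes reproduce the reported behavior of their real counterparts
(negative tissue scoring below p = 0.5 under the built-in coefficients).
Two quantization-related choices matter: flat background plateaus use
integer levels (a level at a rounding boundary dithers into salt-and-pepper
noise), and streak brightness varies smoothly along adipose septa (constant
ridges would read as strings of compact nucleus-sized blobs).

Margins are rendered as one master scene at composite size — tile-class
regions in painter's order, plus an optional contiguous tumor patch spanning
full grid width from the top — and then cut into frames at the stage
offsets, so overlapping frames see identical content. The ground truth
carries per-bin true classes; the patch rasterizes to the requested bin
fraction within ±0.03.

Bead phantoms place non-touching uniform disks of a single physical
diameter. The sizing study measures each bead by its innermost matched
region (nested coarser detections are blur skirts): 10 µm beads measure
near 12 µm, 6 µm near 6.5 µm, and 1 µm beads — far below the 4.4 µm
resolution — are over-estimated to ≈ 5 µm, reproducing the known
resolution-limited bias.

**What the phantoms do not capture**: fluorophore photophysics, depth
dependence, stain variability across specimens, correlated speckle, and the
benign dense-nuclei confounders (bone marrow, nerve, lymph node) that cause
false positives on real margins. Passing tests therefore validate the
pipeline's mechanics and its behavior under the modeled class geometry, not
clinical performance.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 10 ROIs per
tissue class (1260 bins) for training-set analyses, 2×3 full-frame margins
(≈ 7.7 Mpx composite, 2992 bins) for the mosaic analyses, 50-bead fields
per diameter, and ≥ 200 random images up to 32×32 for detector/oracle
equivalence. Every stochastic step is seeded; the acceptance script derives
all of its streams from a single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The two-sided, lifetime-clamped stability score makes short-lived
  components maximally stable (see above); very noisy flat inputs
  over-segment unless pre-smoothed.
* MaxVariation 10 on an 8-bit scale is permissive; selection is in practice
  driven by the local-minimum structure, the size band and diversity
  pruning.
* The diversity pruning recompares after each removal round; for pathological
  candidate chains this is quadratic, which is irrelevant at nuclear
  densities but untested at extreme ones.
* Touching nuclei merge into single regions (no watershed splitting); the
  size band then discards sufficiently large clumps.
* Built-in coefficients assume the pixel-unit convention at 1.5 µm/px;
  applying them at a different pitch relies on the declared-units conversion
  and has no external validation.
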