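# Methods

`ivpharm` quantifies single-cell drug pharmacokinetics from two-channel
intravital fluorescence movies: a nuclear-marker channel (e.g. an H2B
fluorescent fusion) drives segmentation, and a drug channel (a
fluorophore-labeled compound) is read out inside the segmented nuclear
borders and converted to concentration through a dilution-series
calibration. This note records the models, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Image model and conventions

Images are float arrays in [0, 1], obtained by dividing integer TIFF pages
by `2^bit_depth − 1`. Coordinates are 0-based `(row, col)`; centroids are
sub-pixel floats in the same convention. Frame-to-frame drift is corrected
by integer-pixel translation maximizing the cross-correlation of each frame
with frame 0 of a reference channel; the same shift is applied to all
channels and exposed edges are zero-filled. Integer translation was chosen
deliberately: interpolation would redistribute intensity between pixels and
bias the concentration averages downstream. Registration is applied jointly
(one offset per frame, estimated on the nuclear channel) because the two
channels are acquired near-simultaneously.

## Thresholding

Three thresholding families are implemented behind one interface
(`mask == frame > surface`, foreground strictly greater, candidate levels
for the global methods being the 256 uniform quantization levels of [0, 1],
ties broken toward the smallest level):

* **Otsu** — global clustering; exhaustive scan maximizing between-class
  variance `w0 w1 (μ0 − μ1)^2`.
* **Huang** — global fuzzy object-attribute; each pixel's membership in its
  class under candidate `t` is `µ = 1 / (1 + |x − m_class| / C)` with `C`
  the intensity range, and the threshold minimizes the summed Shannon
  entropy `S(µ) = −µ ln µ − (1−µ) ln(1−µ)` (the entropy variant of the
  index of fuzziness; the Yager variant would slot in behind the same
  interface).
* **Iterative locally-adaptive ("Ray-style")** — three user inputs:
  iteration cap (default 1000), `power`, and termination tolerance
  `epsilon`, plus a window radius (default 15 px ≈ one nucleus diameter and
  its surround at 20× magnification). The published description of the
  original method specifies only this parameter interface, so the update
  rule here is this package's own formulation, chosen to be deterministic,
  convergent, and adaptive to multi-level brightness:

  1. Seed with a global two-means (isodata) level.
  2. Each iteration, estimate a background surface `B(x, y)` as the
     windowed median of currently background-classified pixels (a masked
     rank filter over a disk window).
  3. Split the residual `I − B` by power-weighted class means,
     `t = (f^p m_F + (1−f)^p m_B) / (f^p + (1−f)^p)` with `f` the current
     foreground fraction — `p` is the selectivity dial: larger `p` pulls
     the cut toward the majority class — floored at `m_B + 3 sd_B` so the
     threshold never descends into the background noise band.
  4. New surface `T = B + t`; stop when the mean absolute per-pixel change
     of `T` falls below `epsilon` (default 1e-4) or the cap is reached
     (returned flagged, not an error).

  A purely local class-mean update (weighting windowed foreground and
  background means per pixel) was prototyped first and rejected: in
  windows containing a single class the update is ill-defined — collapsing
  the threshold to the local background mean marks ~half of all noisy
  background pixels foreground, while freezing the surface makes dim
  objects below the initial threshold undiscoverable. The
  background-surface/residual decomposition keeps the locality (the
  surface follows illumination and background structure through the
  windowed class statistic) without either failure mode. In practice it
  converges in 3–10 iterations, far below the 1000-iteration cap kept for
  pathological inputs.

Gamma pre-adjustment (`frame ** gamma`) is available before any method; it
is strictly order-preserving, so for the global methods it only moves the
effective cut point.

## Segmentation pipeline

Per frame: gamma adjust → threshold → speckle filter → label → size filter.
The speckle filter is a morphological opening with a discrete disk
(`(i, j)` included iff `i² + j² ≤ r²`; radius 0 = identity); running it
*before* the area filter removes the noisiest single-pixel artifacts so the
minimum-object-size choice is simple. Labeling uses 8-connectivity with
4-adjacent border extraction (this pairing keeps borders closed);
centroids are unweighted member-pixel means; per-channel mean intensities
are taken over all member pixels ("inside the borders" read as the
enclosed area, not the border ring). Z-stacks are segmented per slice,
with an outline-count projection for visual review; a content-free slice
yields an empty region list rather than aborting the stack. Overlapping
nuclei of similar brightness are not split — that needs watershed-style
post-processing outside this package's scope.

## Segmentation quality metrics

Against one or more manual reference masks (averaged when several
reviewers are supplied):

* `ME = 1 − (|B_o ∩ B_T| + |F_o ∩ F_T|) / (|B_o| + |F_o|)` — fraction of
  disagreeing pixels.
* `TRNU = |R_T − R_o| / R_o` — relative region-count error (adopted form,
  flagged `trnu_def="abs_rel"`).
* `VNU = |σ²_T − σ²_M| / σ²_M` — relative foreground-variance error,
  variances population (÷N) over each mask's own foreground; an empty test
  foreground scores exactly 1 (adopted form, `vnu_def="rel_var"`).

Methods are ranked within each image (rank 1 = lowest, mid-ranks on ties);
Friedman's statistic is the plain closed form
`12/(nk(k+1)) Σ R_j² − 3n(k+1)` on mid-ranks (no tie correction — an
all-tied table then gives exactly 0), with the p-value from χ²(k−1).
Pairwise comparisons use the two-sample Wilcoxon rank-sum test, computed
only where Friedman p < 0.05. Rank-sum (not signed-rank) is used
deliberately even though the data are paired by image.

## Calibration and pharmacokinetics

The calibration is an ordinary least-squares line fluorescence →
concentration (µM) over a dilution series (≥ 3 points, ≥ 2 distinct
concentrations); nonlinear fluorophore response is out of scope, and
conversions outside the calibrated fluorescence range are returned but
flagged extrapolated. No background is subtracted by default; a constant
dark-level parameter is available where the detector baseline matters.

Per-cell concentration = converted mean drug fluorescence over the cell's
member pixels; per-frame summaries are the mean and population sd over
cells. The subtherapeutic fraction counts cells strictly below the
threshold (default 1.5 µM). The nuclear/cytosolic split approximates the
cytosol as a perinuclear ring (dilation by a disk, default 5 px, minus the
nucleus) and reports nuclear signal over nuclear+ring signal on
background-subtracted intensities.

The synthetic drug kinetics follow a one-compartment model: vessel bolus
`C_v(t) = peak·e^(−k_decay t)` feeding first-order exchange
`dC/dt = k_in C_v − k_out C`, solved in closed form. `fit_uptake_kinetics`
recovers `k_in`, `k_out` by nonlinear least squares given the vessel
input. Because the synthetic drug signal is confined to the exact nuclear
support, concentration averages are sensitive to border placement: a
segmentation that dilates borders by ~1 px of soft edge dilutes every
average (a pure scale error on `k_in`, ~15 % at the default geometry).
Parameter-recovery accuracy is therefore quantified over reference masks;
with correct borders the estimator is unbiased to the noise-propagation
limit `3σ_conc/√area`.

## Tracking

Detection (per-frame centroids) and linking are separate. Linking joins
consecutive frames only — no gap closing, merging or splitting (those are
delegated to dedicated LAP trackers, for which detections are exported as
CSV). Between two frames the assignment minimizes total cost where a
matched pair costs its squared Euclidean displacement, pairs beyond the
search radius (default 10 px) are inadmissible, and every unmatched
detection costs `radius²`; since any admissible pair costs at most
`radius²`, matching is always preferred to leaving both endpoints
unmatched, and the solution is the global least-squares assignment
(Hungarian algorithm). With continuous centroid coordinates cost ties have
measure zero; the solver itself is deterministic for fixed input.

## Synthetic data: what it emulates, and what it does not

The generator renders elliptical nuclei (axis ratio 0.7–1, random
orientation) with a 1-px soft edge, per-cell brightness drawn from a
configurable range, optional tight pairs and brightness heterogeneity
(the canonical hard cases: multi-level brightness, dense fields, both
combined, and high-magnification nuclei with intracellular texture),
single-pixel speckle artifacts, additive Gaussian noise, global integer
drift, a vessel strip with exponential bolus decay, and per-cell uptake
with lognormal `k_in` heterogeneity (CV 0.5 — without cell-to-cell spread
a subtherapeutic fraction is degenerately 0 or 1). Calibration defaults
(30 µM per fluorescence unit, 0.05-unit dark level) keep the brightest
plausible cell inside the detector range and background noise unclipped.
Default acquisition matches a typical intravital time-lapse: 75 s frame
interval; validation movies use 97 frames (2 h) and fields of 50–60 cells
at 224–288 px, sizes chosen so the full suite runs in well under a minute
per scenario on one core.

Not emulated: optical point-spread blurring, tissue scattering and depth-
dependent background, photobleaching, cell division, and non-rigid tissue
motion. Passing the synthetic suite therefore demonstrates the
correctness of the arithmetic and the algorithms' behavior on the
modeled complications — not robustness to every in vivo artifact; on real
data the preview-and-iterate parameter loop remains essential.

## Degenerate inputs and errors

Constant frames are rejected by all thresholders (`DegenerateInputError`);
a constant manual foreground makes VNU undefined; zero manual regions make
TRNU undefined; empty frames yield empty region lists and NaN-marked
summary rows rather than crashes; configuration problems exit the CLI with
code 1, data problems with code 2.
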