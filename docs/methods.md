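# Methods

`capop` turns raw population calcium-imaging movies into ROIs, ΔF/F0
traces, statistically significant transients, stimulus tuning maps, and
non-exclusive neuronal assemblies. This note records the models behind each
stage, the parameters that matter, the numerical choices made where the
design was genuinely open, and what the synthetic-data validation does and
does not establish.

## Conventions

Pixel coordinates are 0-based `(row, col)`, frame indices 0-based, and time
windows half-open `[t0, t1)`. All physical parameters are given in physical
units — radii in μm, decay constants in seconds — and converted internally
with `pixel_size` (μm/px) and `frame_rate` (Hz). Multi-plane volumetric
sessions are represented as one `MovieStack`/`ROIMap` per optical plane;
population analyses concatenate ROIs across planes.

## Registration and artifact flagging

Motion correction is rigid translation only. Each frame is aligned to a
template (by default the mean of the 100 frames most correlated with the
movie average — frames dominated by transients or motion correlate poorly
with the average and are excluded) by upsampled cross-correlation at
sub-pixel precision. The raw displacement series is then smoothed with a
centered moving average (default 1 s) to suppress frame-to-frame estimation
jitter; the smoothed series is what gets applied, with linear
interpolation, and pixels shifted in from outside the field are marked
invalid (NaN). Because the template is an average of displaced frames, the
estimated series carries the mean displacement as a constant offset;
relative motion is estimated accurately, absolute position is defined only
up to that offset.

Frames are flagged as motion artifacts when their aligned correlation with
the template falls below `median(quality) − 3·MAD(quality)` or when the raw
displacement jumps by more than 5 px between consecutive frames. The
flagged set is stored in `MovieStack.bad_frames`; all downstream trace
statistics mask those frames. Flagging is monotone in the quality
threshold. Axial (z) motion and non-rigid deformation are out of scope.

## Segmentation

Segmentation operates on a spatially normalized image:
`(I − local min) / (local max − local min + ε)` over a moving window of
`local_contrast` pixels, clipped to [0, 1]. The regularizer
`ε = 0.05·(global P99 − P1 range)` keeps structure-free noise regions dark;
because ε scales with the image, the output is exactly invariant to global
affine intensity changes `a·I + b` (a > 0). A constant image normalizes to
0.5 with a warning.

Two labeling regimes are supported, selected by `mode`:

* **labeled_nuclei** (nucleus-localized or uniformly loaded reporters,
  bright disks): threshold at `thr_soma`, split touching cells by a
  distance-transform watershed seeded at distance maxima separated by at
  least the expected cell radius, then exclude pixels below `thr_neuropil`.
* **unlabeled_nuclei** (cytosolic, nucleus-excluded reporters, bright
  rings): seeds are small dark connected regions (`norm ≤ thr_soma`) whose
  surrounding annulus is mostly above `thr_neuropil` — i.e. a dark nucleus
  enclosed by bright cytosol, which excludes plain dark background. Each
  seed is grown by a structuring element of the expected cell radius and
  intersected with the bright mask; contested pixels go to the first
  claiming seed, so ROIs stay disjoint.

`roi_size_opt` sets the morphological scale: expected cell radius 6 μm
(`bigger`) or 3 μm (`smaller`). Detected ROIs can be filtered by area,
mean normalized intensity, and perimeter circularity, defined as
`P²/(4πA)` (1 for a circle, larger for irregular shapes; a rasterized
disk of radius 6 px measures ≈ 1.0–1.1). Filtering is idempotent.

For datasets without single-neuron resolution a pointy-top hexagonal grid
of a given vertex-to-vertex diameter tiles the field (axial-coordinate
rounding assigns every pixel to exactly one hexagon); hexagons clipped by a
user mask or the field border are kept only if ≥ 50% of the nominal area
remains. Programmatic `modify_rois` (remove, then add, with overlap
rejection) replaces interactive curation.

## Neuropil correction and ΔF/F0

The measured somatic signal is modeled as
`F_measured = F_soma + α·F_neuropil`. The local neuropil signal of each ROI
is the mean over a perisomatic disk of radius 20 μm centered on the ROI
centroid with the pixels of *all* detected ROIs removed; masks of
neighboring ROIs may overlap. Correction subtracts `α·F_neuropil`
(default α = 0.9, configurable — the appropriate value is
preparation-dependent and debated; regression-based α estimation is out of
scope). A sanity report flags non-finite samples, >1% negative corrected
fluorescence (over-subtraction), saturation at the sensor maximum, and
zero-variance traces.

F0 is estimated either as (i) the mean fluorescence in a user window,
optionally per event (e.g. the 2 s before each stimulus), or (ii)
`F_smooth`, a slow baseline: a centered running 8th percentile over a
window (default 30 s, validated ≥ 10·τ) followed by a same-width moving
average. The p-th percentile of stationary noise sits `Φ⁻¹(p)·σ_F` below
the baseline center, so that offset is added back using a robust
noise-scale estimate (`1.4826·median|ΔF|/√2`); as a result the median
ΔF/F0 over transient-free stretches is centered at 0. Output is floored at
a small positive value so ΔF/F0 is always defined. ROI traces are plain
means over pixels (no weighting).

## Noise model and significant transients

The baseline noise scale σ of each ΔF/F0 trace is estimated per ROI:

* **gauss_fit** (default): locate the baseline mode of the ΔF/F0 histogram
  (Freedman–Diaconis bins), then alternate (a) re-centering μ on the mean
  of samples within ±σ of μ and (b) setting σ to the SD of the sub-μ
  samples reflected about μ — a one-sided Gaussian fit that positive
  calcium transients cannot inflate. The refinement matters: the raw
  histogram mode has ~0.1σ quantization error, enough to visibly distort
  the k·σ exceedance rate.
* **trimmed_sd**: SD after discarding the largest `trim_frac` (default
  10%) of samples, rescaled by the analytic truncation factor so it is
  unbiased under Gaussian noise (analogous to the 1.4826 MAD factor).

**Static threshold**: frame significant iff `ΔF/F0 − μ > k·σ` (default
k = 3). On pure Gaussian noise the exceedance rate matches Φ̄(k).

**Dynamic threshold**: exploits the indicator decay constant τ. Candidate
events are seeded at one- or two-frame rises exceeding
`Φ⁻¹(confidence)·σ√2` (differences of independent Gaussian noise samples
have scale σ√2; a real rise can be split across two frames by sub-frame
spike timing, and single-frame seeding alone misses ~10–15% of
borderline-SNR events). From each candidate the local peak A is taken; the
event is accepted when the log odds ratio of the decay template
`A·exp(−Δt/τ)` against pure noise, accumulated over ~3τ after the peak,
exceeds `ln(confidence/(1−confidence))`. Accepted events are significant
from the first elevated frame until the envelope returns within
`Φ⁻¹(confidence)·σ` of baseline, i.e. for `τ·ln(A/(zσ))`. An early design
that required every post-peak sample to stay above a per-frame envelope
was discarded: for a genuine 4σ event spanning ~13 decay frames the joint
pass probability of such an AND-test is only ~0.25 under the event's own
noise. The joint likelihood-ratio test has near-unit power there while
suppressing noise candidates by orders of magnitude (measured noise-only
significant-frame fraction ~10⁻⁴ at 60 Hz, confidence 0.95, versus
~1.3·10⁻³ for the static k = 3 rule). Raising `confidence` (or `k`) never
grows the significant set. Noise is assumed white between frames;
autocorrelated noise is out of scope, as are deconvolution and learned
detectors.

`masked_dff` is ΔF/F0 with non-significant samples set exactly to 0. Spike
association (for datasets with ground-truth electrophysiology) counts a
spike as detected when significant fluorescence occurs within 40 ms after
it; percentages are reported for all spikes and for single spikes isolated
by ≥ 1 s.

## Event-locked responses and HSV maps

Events carry a value of one experimental variable on a declared grid.
Peri-event windows (`pre`, `post`; trials crossing the recording edge are
dropped with a warning) are grouped by value; the per-trial response
statistic is the mean (optionally peak) ΔF/F0 over the post window, by
default computed on `masked_dff` so that only significant transients
contribute. A trial is significant if any significant frame falls in its
post window.

The tuning curve is the trial mean ± SEM per grid value; `v_peak` is the
grid argmax (ties → lowest value), `peak_amp` the mean there, and the
tuning width the full width at half maximum above the curve minimum with
linear interpolation, clamped to the grid span. Cells whose best value
drives significant transients in fewer than half of its trials are flagged
unresponsive and assigned the full span (zero selectivity): without this
gate a single spontaneous transient landing in one trial window turns a
silent cell's curve into a delta function with spuriously sharp "tuning".
The gate is inactive when no significance raster accompanies the trials.

The topographic map encodes, per ROI: hue = `v_peak` scaled over [0, 0.75]
of the hue wheel (the top quarter is unused so the two grid extremes are
not confusably similar; cyclic variables are unsupported), saturation =
`1 − width/span` (selectivity), value = `peak_amp` relative to the
strongest ROI. Saturation and value pass through a clip/offset rescale
`clamp((c − offset)/(clip − offset), 0, 1)` — monotone, surjective onto
[0, 1] — which is how heavily skewed response distributions are made
readable; optional transparency ties alpha to value so weak responses fade.
ROIs are composited over the grayscale mean image.

## Assemblies (PCA-promax)

Activity is z-scored per ROI (frames with artifacts or non-finite samples
dropped; zero-variance ROIs dropped with a report), using either raw ΔF/F0
or significant transients only — the latter is preferred for noisy data
because it removes the noise floor between events. PCA of the ROI×ROI
correlation matrix keeps components with eigenvalues above

    λ_max = (1 + √(N/T))² + N^(−2/3),

the Marčenko–Pastur upper edge for random data plus a finite-size
correction (both terms configurable). On i.i.d. noise (N = 200, T = 2000)
fewer than 1% of eigenvalues exceed this bound; a planted perfectly
correlated group yields exactly one retained component.

The retained loadings are varimax-rotated (Kaiser-normalized, SVD
algorithm) and then obliquely rotated by promax with power κ = 4
(conventional default): the target is the element-wise |loading|^κ with
signs kept, fitted by least squares, and component signs are flipped so
each component's dominant loading is positive. Obliqueness is the point —
a neuron belonging to two assemblies needs correlated components, which
orthogonal rotation forbids.

Membership uses z-scored loadings, standardized per component across ROIs
with a robust z-score (median / 1.4826·MAD): member loadings are exactly
the outliers being sought, and letting them inflate a mean/SD
standardization — they can be a large fraction of ROIs — compresses the
separation the threshold needs. The threshold zMax is chosen automatically
at the first local minimum of the kernel-density estimate of per-ROI
maximal z-scored loadings above its global mode, i.e. where the non-member
bulk dies away. The bandwidth is Silverman's rule on a MAD-based scale
times a user `smooth` factor, with progressive shrink retries and a
valley-depth guard (minimum ≤ half the mode density; a second cloud of at
least 5% of the mode beyond it), so strongly bimodal distributions yield
the valley and unimodal ones raise an error asking for a manual choice. A
manual zMax always overrides.

A ROI joining m assemblies splits its unit variance among them, shrinking
each of its loadings by ≈ √m. Membership therefore compensates: ROIs with
at least two loadings above `zMax/√2` are admitted to every component whose
loading exceeds `zMax/√m_c` (m_c = candidate count); all others are judged
against plain zMax. Without this correction the multi-assembly ROIs that
oblique rotation exists to find are systematically the ones dropped, since
their diluted secondary loadings fall into the very valley where zMax
sits. Raising zMax still never grows any member set.

Assemblies whose unit components have dot product > 0.6 are merged
iteratively (largest dot first, ties to the lower index pair; merged
component = renormalized mean), and only assemblies that are both
significantly correlated (mean pairwise member correlation) and
significantly synchronous (peak count of co-active members at z > 2) versus
membership-shuffled nulls are kept (p < 0.05 on each, with
`p = (1 + #{null ≥ obs})/(1 + n_shuffle)`, default 1000 shuffles;
single-member assemblies are dropped). Assembly activation is the mean
member z-score per frame. K-means (10 restarts, seeded) and
average-linkage hierarchical clustering on correlation distance serve as
exclusive baselines, optionally after projection onto the retained
components; their partitions are disjoint by construction, which is
precisely what they cannot represent about overlapping assemblies.

## Surrogate assemblies

Both null models keep every ROI's activity trace untouched and randomize
only the grouping. RSA resamples each assembly as a uniform same-size ROI
set. TSA preserves spatial structure: the member centroids are rigidly
transformed (random rotation, optional reflection, translation sampled so
the transformed cloud stays inside the centroid bounding box — otherwise
snapping pulls border points inward and distorts distances) and each point
maps to the nearest unused ROI centroid; a replicate is accepted only if
the two-sample KS distance between original and surrogate pairwise-distance
distributions is ≤ 0.1, with bounded retries and an explicit error when
the field cannot host the assembly. Pooled per-ROI or per-pair features
(mean activity, pairwise correlation, pairwise distance, or any
user-supplied per-ROI values) are compared between original and surrogate
pools with shared Freedman–Diaconis histogram bins and a two-sample KS
test. Time-shuffled (phase-randomized) activity surrogates are not
implemented.

## Synthetic ground truth

The generator produces: non-overlapping disk or ring cells by dart
throwing (ring cells have a darker nucleus interior and the labeled mask is
the cytosolic annulus); spiking as the superposition of background Poisson
activity, planted assembly events (Poisson event times, each recruiting
every member independently with `within_prob`; shared members follow all
their assemblies), and stimulus-locked Poisson responses with Gaussian
tuning around per-cell preferred values; ΔF/F0 as the spike train convolved
with a unit-peak single-exponential kernel `exp(−t/τ)` with instantaneous
rise (indicator rise times ~45 ms are below typical frame periods), plus
multiplicative linear drift and white Gaussian noise. Movies add a shared
neuropil background — a near-uniform textured field driven by the
low-pass-filtered population mean, attenuated by a factor α inside somata
so the contamination model holds exactly — integer rigid jitter, and pixel
noise. Everything is bit-reproducible from (parameters, seed).

What the generator does **not** emulate: indicator saturation and Hill
kinetics, spike-amplitude variability within a cell, autocorrelated
(photon/shot) noise, axial motion, bleaching nonlinearity beyond linear
drift, and overlapping cells. Passing the validation suite therefore
demonstrates correctness of the algorithms under the stated model, not
performance on any particular real preparation.

## Validation experiments and problem sizes

`capop.validation` runs closed-loop experiments used by both the test
suite and `scripts/acceptance.py` (all sizes chosen as realistic desk-scale
sessions): eigenvalue-null calibration at N = 200, T = 2000 over 100
replicates; assembly recovery with 500 ROIs and 8 planted assemblies
(sizes 20–40, two sharing 5 ROIs, within-assembly recruitment 0.3,
background 0.02/frame) over a 600 s session at 10 Hz, measured by planted-
vs-detected Jaccard overlap; transient inference at 60 Hz with τ = 250 ms
and 4σ peaks (sensitivity via the 40 ms spike-association rule, false
positives on noise-only traces and 10⁵ noise frames); neuropil correction
with α = 0.9 shared contamination (per-trace correlation and off-diagonal
correlation restoration); segmentation of 50 planted disks and 50 rings at
IoU ≥ 0.5; tuning recovery of a linear preferred-value gradient (7 stimulus
values × 6 trials) plus silent cells for the zero-saturation check; TSA/RSA
behavior; and bit-exact determinism plus threshold-monotonicity sweeps.

## Known limitations

Rigid, within-plane motion model; single-exponential indicator kernel with
fixed amplitude per spike; white-noise assumption in both σ estimation and
the dynamic odds test; FWHM tuning width is grid-resolution-limited and
undefined for cyclic variables; the automatic zMax rule assumes a bimodal
loading distribution and refuses otherwise; TSA construction can fail on
very sparse fields (it reports the attempt budget rather than silently
relaxing the distance criterion); no automatic choice of k for the
baseline clusterings; no GPU or cluster parallelism.
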