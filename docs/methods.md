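# Methods

## Acquisition model (simulate)

The simulator emulates a single-molecule FISH acquisition on a widefield
microscope with a 100×/1.4 objective. Conventions: continuous coordinates
in nanometres, x rightward (columns), y downward (rows); pixel (i, j) spans
[j·p, (j+1)·p) × [i·p, (i+1)·p) nm with p the pixel pitch; frames and
pixels are 0-based.

**Nuclei** are random non-overlapping ellipses (semi-axes drawn uniformly
from `nucleus_radius_px`, default 11–14 px). **FISH loci** are placed
inside an eroded nucleus mask with a minimum pairwise separation
(`min_signal_separation_nm`, default 600 nm) so that plain loci are
resolvable by both routes; each locus carries `emitters_per_signal`
fluorophores (default 8) scattered uniformly in a disc of diameter
`signal_extent_nm` (default 80 nm). A fraction of nuclei
(`cluster_fraction`) additionally receives one *cluster locus*:
`cluster_signals` (default 5, i.e. more than four) signals co-located
within `signal_extent_nm` of a common centre — unresolvable as separate
spots at diffraction-limited resolution.

**Blinking** is i.i.d. Bernoulli per frame and emitter (`p_on`, default
0.005) — the simplest kinetics consistent with autonomous stochastic
blinking; no dark-state memory. An on-frame contributes Poisson-distributed
photons with mean `mean_photons` (default 1500) through an *integrated*
2-D Gaussian PSF (sigma 130 nm ≈ a diffraction-limited spot at high NA),
i.e. the PSF is integrated over pixel areas, not sampled at centres. Pixel
counts are Poisson draws of emitters + background (the compound-Poisson
identity makes per-emitter Poisson patches equivalent to one draw of the
summed intensity), plus Gaussian read noise (`read_noise_sd`, default 3
ADU), clipped at zero and stored as 16-bit integers at unit gain.

**Autofluorescence background** is a smooth random field: white Gaussian
noise smoothed to `background_corr_len_px`, standardised and pushed through
the normal CDF, then scaled — `offset + amplitude·Φ(z)`. Each pixel's
marginal is uniform on (offset, offset + amplitude), so the per-pixel mean
is exactly offset + amplitude/2 (the closed form used by the Monte-Carlo
test). The default correlation length (48 px ≈ half the field) makes the
background vary on multi-micrometre scales, slower than the 15-px rolling
ball — the standard regime for morphological background subtraction.

**DAPI** frames image continuously fluorescent nuclei (mask × brightness,
PSF-blurred) with the same noise model; 1000 frames versus 5000 for the
probe channels, matching the acquisition protocol the simulator emulates.

**Scale.** Default fields are 96 px (9.6 µm) with 3–4 nuclei of ~2.5 µm
diameter — a deliberately desk-scale field: one field simulates and
analyses in ~20 s, so count-recovery studies over tens of fields remain
cheap. Nuclei are smaller than typical epithelial nuclei; nothing in the
pipeline depends on absolute nucleus size beyond the segmentation area
filter. Frame counts (5000/1000), exposure metadata (30 ms), PSF width and
pixel pitch are the emulated instrument's values; photon budget, blink
rate, background shape and camera noise are engineering choices — the real
instrument's gain and kinetics are not public.

## Blind-spot denoising (denoise)

The self-supervision contract: a pixel is predicted from its Chebyshev
neighbourhood of radius r *excluding itself*, so noise that is independent
across pixels cannot be reproduced. Two predictors implement it — a
masked-neighbourhood median (training-free) and a linear regressor fitted
by ordinary least squares on a random fraction of masked pixels (default
5%) — as desk-scale stand-ins for a deep blind-spot network; the interface
(train on raw frames, never see the centre pixel, apply per frame with
reflective borders) is the same, so a deep backend could be slotted in.
Training is a single closed-form least-squares solve; the recorded
`final_loss` is the training MSE. Denoising is optional in the default
localization path: the detection stage's box-sum statistic already averages
pixel noise, and the per-frame threshold model absorbs the noise level.

## Background and thresholds (background)

The rolling-ball background is grayscale opening (erosion then dilation)
with a flat disk, default radius 15 px; the image is reflect-padded so the
opening is exact on the original support (pointwise ≤ the image,
idempotent, verified against a brute-force sliding min/max oracle). A flat
disk rather than a true ball: at radius 15 on diffraction-scale spots the
ball's curvature is irrelevant.

The "optimum" threshold for an image with a known signal mask is the
intensity maximising the pixelwise F1 score of `pixel > tau`, searched over
the image's unique intensities with ties broken toward the smaller value.
Thresholds for new images come from an OLS regression of the optimum on the
image's mean *and* standard deviation (two predictors) with intercept,
floored at zero; thresholding keeps pixels strictly above tau.

**Calibration design.** 20 single frames spanning background offsets
30–300 ADU, amplitudes 5–80, read noise 1–15 (bracketing the default
acquisition), each with 135 emitters on a 192-px field, thresholded after
subtracting the clean background's opening. The larger, denser calibration
frames sharpen the F1 optimum (its sampling noise scales down with pixel
count), which is what pushes the fitted-vs-optimum correlation reliably
above 0.95. The regression predictors are the image's *background*
statistics, measured on a paired emitter-free frame of the same
background and noise: dense calibration spots would otherwise shift the
mean/SD by several ADU relative to the sparse blinking frames the model
is applied to, and the extrapolation makes the predicted threshold
unstable across calibration draws. With background statistics as
predictors the model interpolates, and the predicted per-frame threshold
sits at ~4.5 noise standard deviations under the default acquisition.

## Localization (superres)

Stacks are preprocessed by subtracting a *static* background — the rolling
ball of the temporal mean frame — rather than re-running the opening on
each of 5000 frames: autofluorescence is constant across an acquisition in
this model, and the temporal mean averages blinking spots into negligible
bumps that the opening removes. Per-frame thresholds from the regression
model zero the remaining background pixels.

Detection then finds local maxima of the 3×3 box sum of the thresholded
frame above a robust per-frame floor (median + 5·1.4826·MAD of the
unthresholded box sums): a genuine diffraction-limited spot concentrates
~55% of its photons in 3×3 pixels, while isolated suprathreshold noise
pixels do not, so the floor separates them cleanly. Maxima closer than
2 px merge to the brighter one.

Each candidate is fitted on the (unthresholded) subtracted frame with a
symmetric integrated 2-D Gaussian — parameters (flux, x, y, sigma, offset)
— by damped Gauss–Newton (Levenberg–Marquardt) least squares, vectorised
over all spots of a stack at once: per-spot 5×5 normal equations, per-spot
damping, at most 100 iterations, relative cost tolerance 1e-8. Initial
values are the border-median offset, background-subtracted centroid and the
expected PSF sigma. Fits are rejected (and counted) when they fail to
converge, the flux is non-positive, the centre leaves the window, or sigma
falls outside [0.5, 4]× the expected PSF sigma — the sigma gate is what
discards single-pixel noise spikes (sigma too small) and residual
background bumps (too large). Photons = flux/gain at unit gain;
`uncertainty_nm` is the Thompson-style sigma/√photons. No drift correction
and no multi-emitter fitting; duplicate localizations of one emitter across
consecutive frames are left to the clustering stage.

Rendering bins localizations at `render_px_nm` (default 20 nm) as a count
histogram (sum = row count exactly) or as integrated-Gaussian splats of
width `uncertainty_nm` (sum = row count up to edge losses). The
conventional-resolution image is the pixel-wise mean (or sum/max) of the
raw frames.

## Counting (quantify)

Nuclei are segmented from the DAPI projection by Gaussian smoothing
(sigma 1 px), Otsu thresholding, hole filling, a distance-transform
watershed to split touching nuclei (marker minimum distance 15 px,
comfortably above the medial-axis length of a single ellipse and below
inter-nucleus distances), and an area filter (default 50 px).

Super-resolution signals are single-linkage clusters of localizations: two
localizations link within `eps_nm` (default 150 nm ≈ the SR-resolvable
separation), components with ≥ `min_pts` (default 3) members become
signals; centroid = mean position, strength = number of localizations,
extent = RMS radius. This is deliberately the linkage rule, not DBSCAN's
core-point rule. Conventional-resolution signals are connected
suprathreshold blobs of the background-subtracted projection that contain a
local maximum; strength is the blob's integrated intensity, extent its
intensity-weighted RMS radius. The CR threshold defaults to a robust MAD
rule on the subtracted projection — the frame-level regression does not
transfer to a 5000-frame average whose noise is ~70× smaller — but a
ThresholdModel or scalar can be passed.

Signal multiplicity: est_count = round(strength / reference), floored at 1,
with the reference the median signal strength of the sample (isolated
single signals dominate the median). A signal estimated above four copies
whose extent exceeds `isolation_extent_nm` (default 100 nm — between the
sub-diffraction spread of a true cluster locus, ~60 nm RMS, and any
diffraction-limited blob, ≥ ~150 nm RMS) is reported as "more than four":
est_count 5 with the ambiguous flag. Consequently cluster loci are
countable in the SR route and ambiguous in the CR route, which is the
mechanism behind the SR > CR counting direction.

Signals are assigned to the nucleus whose mask contains their centroid
(outside-all-nuclei signals are dropped and logged); per-nucleus H and C
sum est_counts; a nucleus is CEP17-countable when C ≥ 1 with no ambiguous
CEP17 signal. The nine sample metrics tally ambiguous nuclei separately
and exclude them from signal totals and per-nucleus means (the denominator
of `her2_per_nucleus` is the count of non-ambiguous nuclei with H ≥ 1);
the ratio R sums H and C over CEP17-countable nuclei, and is null (with a
recorded reason) when none exists.

## Classification (classify)

Groups 1–5 partition (R, HER2 signals/cell): Group 1 (R ≥ 2.0, ≥ 4.0),
Group 2 (R ≥ 2.0, < 4.0; annotated "monosomy"), Group 3 (R < 2.0, ≥ 6.0),
Group 4 (R < 2.0, [4.0, 6.0)), Group 5 (R < 2.0, < 4.0). The half-open
Group 4 interval resolves the boundary overlap with Group 3 at 6.0 so the
partition is disjoint (verified exhaustively on a grid). Group 1 is ISH
positive, Group 5 negative, Groups 2–4 need IHC: 0/1+ → negative, 3+ →
positive, 2+ → the guideline's concurrent-review outcome (Group 3 positive,
Groups 2 and 4 negative) flagged `guideline_default`. The mean entering
classification is the ambiguous-exclusive `her2_per_nucleus`, with the
ambiguous tally reported alongside.

## Statistics (compare)

Wilcoxon signed-rank: zero differences dropped, midranks on |d|, statistic
W+ = positive-rank sum. For m ≤ 25 the exact null distribution of W+ is
built by shift-convolution over sign patterns (doubled ranks keep
half-integer midranks integral) — equivalent to enumerating all 2^m
patterns, which the tests do literally at small m; two-sided p =
2·min(lower, upper tail) capped at 1, observed point included in both
tails. Above m = 25, normal approximation with the tie-corrected variance,
no continuity correction. Mann–Whitney: midranks, U of the first sample;
exact p for n1+n2 ≤ 12 by enumerating all labelings and counting
|U − n1·n2/2| at least as extreme; otherwise tie-corrected normal
approximation. Chi-squared: Pearson X² with margin-derived expectations and
**no Yates correction** — with the correction the cohort tables' printed
p-values are not reproduced. Two-sided throughout; reports annotate
p < 0.05 as significant.

The cohort report emits median (min, max) per metric × route × routine
HER2 stratum, the paired Wilcoxon p per metric (None when fewer than two
complete pairs or degenerate), and the 5×5(+unevaluable) CR-vs-SR group
contingency table.

## What the simulations do and do not show

The simulator provides exact ground truth and reproduces the *structure*
of the problem: stochastic blinking, diffraction-limited blurring, smooth
autofluorescence, camera noise, nuclei, plain and clustered loci. Passing
tests therefore demonstrate algorithmic correctness (localization precision
and its √N scaling, count recovery, the CR/SR resolvability gap, the
ambiguity rule's direction). They do not demonstrate performance on real
tissue: no defocus or 3-D structure, no tiling or stage drift, no chromatic
aberration, no probe off-target binding, no sectioning artefacts
(truncated nuclei), no inter-observer variability, and emitter photophysics
far simpler than real dye kinetics. Cohort-level medians from real samples
are outside what a simulation of this kind can reproduce.

## Numerical choices and degenerate inputs

- Rounding of copy-number estimates: half away from zero, floor 1.
- Threshold comparisons are strict (> tau kept); the optimum-threshold
  search ties toward the smaller value; an image with no separating
  threshold (e.g. constant) raises a degenerate-threshold error.
- All-zero paired differences, zero contingency margins, empty samples and
  missing required IHC scores raise typed errors rather than returning
  sentinel values; an undefined ratio is carried as null with a reason so
  cohort tabulation can proceed.
- Determinism: every stochastic component takes a seed or NumPy Generator;
  identical seeds give bit-identical stacks, truth, fits and reports.
- Fit windows are 7 px (unit tests use 9 px where sub-pixel truth is
  asserted); windows must fit inside the frame, so detections within half
  a window of the border are discarded.

## Known limitations

- The linear/median blind-spot predictors cannot learn non-linear image
  priors; they bound what the denoising stage can claim.
- The intensity-ratio copy-number estimate assumes signals of one sample
  share a brightness scale; strong locus-to-locus probe variability would
  need a per-locus model.
- Single-linkage clustering can chain signals closer than eps; the
  simulator's 600-nm locus separation avoids this regime by design.
- The CR route's robust threshold assumes spots occupy a small area
  fraction of the projection.
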