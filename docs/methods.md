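# Methods

This note documents the models, conventions, and numerical choices behind
synaptrack, in the spirit of the methods documentation of simulation and
analysis packages in this field.

## Motion model and simulator

Molecules live on a rectangular patch of dendritic membrane (default
40 × 3.2 µm) decorated with circular post-synaptic domains (default 14 discs
of 0.3 µm radius, ~3% of the membrane area). Two built-in study conditions:

- **DIV8** — mobile-state diffusion coefficient `D_free = 0.30 µm²/s` with a
  20% immobile subpopulation; emulates an early-development culture in which
  most molecules diffuse freely and a minority is trapped at synapses.
- **uniform-GPI** — the same mobile pool with only a 5% immobile fraction;
  emulates a freely diffusing GPI-anchored control.

Free molecules take independent Gaussian steps of per-axis variance
`2·D_free·Δt` (default `Δt = 20 ms`) and reflect specularly at the rectangle
edges — reflection keeps the surface density uniform without absorbing or
wrapping particles. Immobile molecules are completely frozen at a uniformly
drawn anchor point inside a synapse disc; their apparent movement downstream
comes only from localization noise. This is deliberately the simplest model
consistent with the operational definition of "immobile" used in trajectory
analysis (molecules exploring less than the pointing accuracy, D < 0.01
µm²/s). An alternative kinetic mode (`p_trap > 0`, escape rate `k_off`)
implements reversible trapping inside discs for users who want exchange
dynamics; no quantitative exchange rates are claimed for it, and its
defaults are free parameters.

Track lifetimes are geometric with mean `track_length_mean = 50` frames
(minimum 1), emulating probe photobleaching/unbinding and producing the
characteristic broad track-length distribution of sparse live labeling;
birth frames are uniform over the movie. With the default 500–1,300
molecules over 4,000 frames this keeps the instantaneous density near
0.1 molecules/µm², the sparse regime in which frame-to-frame linking is
essentially unambiguous.

All randomness flows from a single master seed; each molecule gets a
deterministic child stream (`numpy` `SeedSequence.spawn`), so results are
bit-reproducible and independent of iteration order.

Coordinates: x rightward, y downward, origin at the top-left corner of pixel
(0, 0); pixel (i, j) covers the half-open square `[j·p, (j+1)·p) × [i·p,
(i+1)·p)` µm. All positions are stored in µm; time is `frame · Δt`.

## Camera model

The renderer integrates an isotropic Gaussian PSF (`psf_sigma = 0.10 µm`)
over each pixel (erf differences per axis), adds a constant background, and
draws counts with EM-register excess noise: for gain factor g, counts are
`g · Poisson(mean/g)`, which preserves the mean and inflates the variance by
g (the standard EMCCD excess-noise model, g ≈ 2). Defaults —
250 photons/molecule/frame, 50 background photons/px, g = 2 — were chosen so
the refined localization error is ~25–30 nm s.d. (≈60 nm FWHM), matching
both the stated pointing accuracy of this kind of instrument and the 30 nm
`sigma_loc` used by the rendering-free degradation path; this keeps the two
ways of producing localization tables statistically interchangeable.
Fiducial markers are rendered every frame; a constant drift velocity
displaces everything in the image. Molecules outside the field are clipped
silently.

`degrade_to_localizations` bypasses rendering entirely: truth positions get
isotropic Gaussian noise of s.d. `sigma_loc` and per-frame Bernoulli
thinning. It retains the molecule identity per row, which is what makes
linking and estimator recovery testable against ground truth.

## Spot detection

Detection uses the à-trous (undecimated) wavelet transform with the
separable B3-spline kernel `[1,4,6,4,1]/16` and dyadic hole insertion,
mirrored boundaries. The decomposition is exactly additive: detail planes
plus the final smooth residual reconstruct the input to float precision,
and the test suite verifies each plane against a brute-force 2-D convolution
oracle.

The second detail plane (the band containing diffraction-limited spots at
0.16 µm sampling) is thresholded at `k_sigma` times the plane's noise s.d.
The noise s.d. is not measured on the detection plane itself but estimated
robustly (MAD/0.6745) on the first plane — which is noise-dominated — and
rescaled by the ratio of the planes' white-noise gains (the l2 norms of
their equivalent filters, computed once from an impulse response). This
keeps the threshold anchored to the pixel noise even when real spots occupy
a noticeable fraction of the detection plane.

Defaults `k_sigma = 3.5` and `min_spot_px = 3` were calibrated once against
two requirements that a per-frame detector for sparse single-molecule data
must meet simultaneously: a false-positive rate well below one spurious spot
per background-only frame (measured ~0.1 per 64×64 frame; at `k_sigma = 3`
the correlated plane-2 noise yields ~2 per frame) and recall ≈ 1 for
emitters at the default optics. Both parameters are exposed in config.

Connected components (8-connectivity) at or above the size cut become
coarse detections at their intensity-weighted centroids; an isotropic 2-D
Gaussian least-squares fit (amplitude, x, y, width, offset; 7×7 window,
bounded trust-region solver) refines each to subpixel precision. The
per-spot precision estimate follows the standard localization-error formula
`var = (s² + a²/12)/N + 8π·s⁴·b²/(a²·N²)` with fitted photon count N, PSF
width s, pixel size a and background noise b; Monte-Carlo scatter matches
it within 25% in the tests. Non-converged or out-of-window fits fall back
to the centroid and carry a `fallback` flag. Detections are strictly
per-frame; no temporal merging is performed (one detection per frame per
emitter).

## Trajectory linking

Consecutive-frame linking solves the assignment problem on the squared
displacement cost matrix (scipy's Hungarian implementation) under a gating
radius `r_max = 0.5 µm` per frame interval — about 3.2 standard deviations
of the expected free step at D = 0.30 µm²/s and Δt = 20 ms, so >99.9% of
true steps pass the gate. Infeasible pairs get a cost large enough that the
solver first maximizes the number of gated links, then minimizes their total
cost; on small instances this provably equals exhaustive enumeration, which
the tests check directly. A deterministic, annealing-free solver was chosen
because it minimizes the same objective that stochastic annealing trackers
target while being reproducible and oracle-testable.

Unassigned detections open new tracks; unmatched heads terminate, or
persist up to `allow_gaps` frames (default 0 — sparse labeling does not
require gap closing) with the gate widened proportionally. Input rows are
canonicalized (sorted within frame, duplicates dropped with a warning) so
the track set is invariant to row order. Tracks shorter than `L_min = 10`
localizations are discarded before diffusion analysis.

## Diffusion estimation

The time-averaged MSD uses all overlapping ordered pairs,
`MSD(nΔt) = mean_i |r(i+n) − r(i)|²`, the standard practice for short
single-particle tracks. D comes from an ordinary least-squares line through
the first `n_fit = 4` MSD points with a free intercept, `D = slope/4`. The
free intercept matters: static localization noise offsets the whole MSD
curve by `4σ²` and would otherwise bias D upward by `σ²/Δt` (≈ 0.045 µm²/s
at the defaults, a 15% error at D = 0.30); with the intercept fitted, the
median estimate is unbiased within sampling error and the mean intercept
converges to `4σ²` — both verified in the tests over D ∈ {0.03, 0.1, 0.3}.

Non-positive slopes (including exactly zero) floor D at `1e-5 µm²/s` with a
`floored` flag. Floored estimates are included in fractions, medians, and
histograms — the low-D spike they form is a real feature of this kind of
distribution, and excluding them would bias the immobile fraction; the flag
allows sensitivity analyses that drop them. Classification is strict:
immobile iff `D < 0.01 µm²/s`. A "cell" is one input dataset (one movie);
the per-cell summary reports fractions and the median D over its tracks.

The semi-log distribution uses 0.15-decade bins of log₁₀ D spanning
[−5, 1]; mass is normalized to 1 and floored estimates land in the lowest
bin. With the DIV-8 condition the modal bin contains the ground-truth
mobile D, and the recovered immobile percentage matches the simulated
mixture within binomial error — the two quantities `scripts/acceptance.py`
recomputes (at 1,300 molecules, giving ≥1,000 filtered tracks, a size that
runs in seconds while leaving the binomial error on a 20% fraction near one
percentage point).

## Density maps, drift, enrichment, coverage

Density maps bin localizations at `source_pixel / zoom` pitch (0.16 µm / 5 =
32 nm) under the half-open pixel convention; each detection contributes one
count, so the map total equals the in-field localization count exactly.

Drift correction estimates per-frame displacement as the mean over fiducials
of their displacement from first-frame position, interpolated over missing
frames and smoothed with a 100-frame moving average (long enough to average
out fiducial localization noise, short relative to thermal drift
timescales). The smoothed drift is subtracted from all localizations and the
residual fiducial scatter is reported; with no fiducials the table passes
through unchanged with a warning.

Synaptic enrichment divides the detection density inside the synapse mask by
the density in the remainder of the *cell* mask — the dendritic shaft, not
empty coverslip, is the extrasynaptic reference — with no peri-synaptic
exclusion ring. Zero extrasynaptic detections yield an infinite, flagged
value rather than an error. Camera-space masks are transferred to map space
by nearest-neighbor upscaling (×zoom), which preserves area fractions
exactly.

Synaptic coverage segments the "occupied" region as map pixels with ≥1
detection, regularized by a binary closing with a radius-1 disc (radius 0
disables it). The closing is a declared convention — the operator behind
"segmented areas containing detections" is not uniquely determined — chosen
as the mildest regularization that bridges single-pixel gaps in an
otherwise contiguous occupied region without inflating isolated detections;
compact blobs gain no area under it, which the tests pin down. Coverage is
computed per connected synapse and averaged.

Track-level compartment sorting labels each localization by mask membership
of its map pixel; a track is synaptic iff ≥50% of its localizations are
inside (majority rule, ties counting synaptic). Per-localization labels are
always retained for density work.

## Puncta quantification

Segmentation thresholds the image (fixed value, intensity percentile —
default 99th — or a wavelet plane-2 threshold for parity with the
reference-channel pipeline), labels 8-connected components, and keeps those
strictly bigger than `min_area_px = 4` pixels; at the default 0.185 µm
pixel this equals the 0.137 µm² morphometric cut (the pixel size is
back-derived from that equivalence and exposed in config). Linear density is
punctum count divided by the polyline arc length. Colocalization is
object-level and intentionally asymmetric: a reference punctum counts as
colocalized when its intersection with the target foreground reaches
`min_overlap_px` (default 1 px — the criterion for "containing" a cluster
is a convention); the mean area overlap normalizes the intersection by the
*reference* punctum area, and swapping the arguments selects the other
normalization.

## What the simulator does and does not establish

Passing the recovery suites shows the analysis chain is internally
consistent and unbiased under the simulator's assumptions: pure 2-D Brownian
or fully immobile states, isotropic Gaussian localization noise, geometric
lifetimes, no motion blur within a frame, no z-dimension, no triplet-state
photophysics or spectral crosstalk, disc-shaped synapses, and ideal
(Poisson + EM-excess) camera noise. Real recordings violate several of
these (anomalous subdiffusion, confinement short of immobility,
frame-integrated motion blur, structured background, non-disc synapse
morphologies), so quantitative agreement on real data is not implied — the
simulator validates the estimator, not the biology. The mobility statistics
inherit the usual small-sample caveats of 4-point MSD fits on short tracks
(broad log-normal-like spread of D̂), which is why medians and fractions,
not means, are the summary statistics of choice.

## Problem sizes used in the shipped benchmarks

The recovery benchmarks simulate 1,300 molecules over 4,000 frames
(≥1,000 filtered trajectories), the detection-quality benchmark renders 300
frames at ~0.1 molecules/µm², and the identity suites use constructed
fixtures of a few hundred to a few thousand points — sizes chosen so that
sampling error is comfortably below each test's tolerance while the whole
suite stays interactive (tens of seconds).
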