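# Methods

This note records the models, parameter choices and numerical conventions of
the package, including every place where a design was genuinely open.

## Firing-rate features

The instantaneous rate is a Gaussian kernel-density estimate: a unit-mass
Gaussian of SD `kernel_sd_ms` (default 500 ms) is centered at every spike and
summed on a regular 10 ms grid. "Kernel size" conventions vary (SD, FWHM,
full support); we read it as the SD, the most common convention, and expose
it as a parameter. Implementation bins spikes at the grid step and convolves
with a sampled kernel truncated at ±5σ normalized to unit discrete mass, so
the rate integral equals the spike count exactly on any grid that extends
past the train; the approximation error relative to exact per-spike
evaluation is O((Δt/σ)²) ≈ 4·10⁻⁴ at the defaults.

Episode warping rescales each episode of a behavior onto `n` phase bins with
`n = round(mean duration / warp_bin)` at `warp_bin` = 10 ms. Bin values are
exact means of the piecewise-linear rate interpolant over each sub-interval
(via the cumulative trapezoidal integral), then averaged across episodes.
Episodes are half-open `[start, end)` intervals; all times are seconds,
0-based per session.

Joint clustering of cells from many sessions requires equal-length vectors,
so the mean episode duration per behavior is pooled across sessions (one
shared bin count per behavior) and every session's episodes are warped onto
it. An alternative — per-session bin counts resampled to a common length —
would add an interpolation stage without changing what the features measure.

Concatenated feeding|social|object vectors are z-scored per cell. PCA
(column-centered, full SVD) retains the smallest `m` with cumulative
explained variance ≥ `variance_target` (default 0.90). On real recordings
`m` lands in the hundreds; on the synthetic templates a handful of
components suffice — `m` is an outcome, not a constant. Cells missing any
behavior in their session, or with zero-variance vectors, are excluded with
a logged warning.

## Spectral clustering and stability selection

The affinity is a binary k-NN graph under the cosine metric, OR-symmetrized,
zero diagonal. Clustering embeds the graph by the bottom-k eigenvectors of
the symmetric normalized Laplacian (computed as top-k of D^{-1/2} A D^{-1/2}),
row-normalizes the embedding, and applies k-means with 10 restarts and a
deterministically derived seed. A disconnected graph (more components than
clusters) receives a uniform 10⁻⁸ regularization edge weight instead of
failing; the condition is logged.

The stability scan draws `n_boot` = 100 subsamples of 90 % of the cells
without replacement. Each subsample is re-clustered and compared with the
full-data reference clustering restricted to the subsample, by ARI and AMI.
Replicate-vs-reference (rather than all-pairs replicate-vs-replicate) keeps
the cost linear in `n_boot` and anchors all comparisons to one partition;
an all-pairs mode would scale quadratically without changing the ranking of
grid cells in our experiments. Selection reports two criteria: the maximal
mean of {ARI mean, AMI mean}, and the maximal variance-adjusted mean
(mean/SD averaged over the two metrics). Ties break toward the smallest `k`,
then smallest `knn`. A grid cell whose bootstrap agreement is perfectly
reproducible (positive mean, zero SD) is treated as maximally stable
(ratio +∞): on strongly separated data the best cell routinely achieves
ARI ≡ 1 across all bootstraps, and a score meant to reward low variance must
not discard the zero-variance optimum. Zero SD with non-positive mean is
skipped with a warning.

The default scan grid is k ∈ 2…10, knn ∈ {10, 20, 30}: the k range brackets
plausible population counts, and the knn values span sparse to dense graphs
below n/10 for the ~350-cell study size.

Note on null stability: with the fixed-data bootstrap design, isotropic
noise does not give near-zero ARI — a noise k-NN graph keeps much of its
community structure under 90 % subsampling (ARI ≈ 0.4–0.7). Noise is
distinguished from planted structure by its *markedly lower* stability, not
by stability near zero; the tests assert the paired comparison.

Silhouette filtering re-runs k-means 100 times at the selected `(k, knn)`
varying only the k-means seed (the embedding is deterministic given the
data), computes per-cell silhouettes with the cosine metric (matching the
affinity metric), and retains cells with s > 0 in ≥ 95 runs. Cluster quality
is summarized by mean within- vs between-cluster Pearson correlations of the
first five principal components.

## Population naming

Per cluster and behavior, the peak rate of each cell's warped vector is
averaged across cells; the preferred behavior is the argmax. Peak phases
(bin centers of the vector maximum, in [0, 1]) of the preferred behavior
feed a one-sample KS test against Uniform(0, 1) at the Bonferroni-adjusted
α = alpha_family / (n_clusters × n_behaviors); 0.05/21 = 0.002380…, printed
as 0.0023 (truncated at 4 decimals).

Naming rule (the separation of the homogeneous feeding population from the
four phase populations was a genuinely open design point): non-feeding
clusters are Sol/Exp by preferred behavior. Among feeding clusters, with
five or more the one closest to uniform peak times (smallest KS D) is Fd and
the remaining four take FOn/EF/LF/FOff in order of median peak phase (ties
broken by mean phase, logged); with four or fewer, clusters that fail to
reject uniformity are Fd and the rejecting ones take phase names in order.
The smallest-D rule handles the realistic case in which even a homogeneous
feeding population rejects uniformity at large n.

Anatomical enrichment maps are raw (unsmoothed) unit-mass 2D histograms on a
10×10 grid of 70 µm ML × 38.8 µm DV bins, minus the all-cell histogram, so
every map sums to 0; map similarity is the Pearson correlation of flattened
maps. Spike width is measured at 25 % of the peak-to-baseline amplitude with
linear interpolation of the two flank crossings; the baseline is the mean of
the first and last waveform samples.

## LFP events

Wide-band signals are low-passed (zero-phase Butterworth order 8 at
0.4·fs_out) and resampled to 1,250 Hz. Band envelopes are zero-phase
band-pass (Butterworth order 4), rectification, and Gaussian smoothing
(SD 10 ms, ≈ half a slow-gamma cycle; the smoothing width was an open
choice). The *noise statistics* — the mean and SD that define thresholds —
are taken from the rectified band-passed signal before smoothing, over the
whole session in a single pass (an option excludes detected events and
iterates once). Thresholding the smoothed trace against the rectified-signal
scale keeps the threshold's meaning independent of the smoothing width; the
smoothing only stabilizes the run structure of crossings. Computing the SD
on the smoothed envelope itself would make "2 SD above the mean" a ~2 %
exceedance level that pure 1/f background crosses for ≥ 25 ms about every
other second, leaving threshold events dominated by noise runs.

Detection: candidate events exceed mean + 2 SD for ≥ 25 ms; edges extend
outward to the mean + 1 SD crossings; overlapping extended events merge
(no additional merge gap — unstated upstream, chosen minimal). Slow
(30–60 Hz) and fast (61–90 Hz) gamma are detected independently and may
overlap. Nonrhythmic epochs are runs of ≥ 100 ms (a floor chosen to avoid
sub-cycle fragments; no minimum was prescribed) in which every exclusion
band's envelope stays below mean + 0.5 SD. The exclusion list splits the
gamma range into the two event bands plus 90–120 Hz — alongside delta 2–4,
theta 5–10, beta 15–30 and 120–200 Hz — so that the 0.5 SD < 1 SD nesting
argument holds per band and nonrhythmic epochs can never overlap detected
events, exactly.

The multitaper PSD uses 2·NW−1 = 5 Slepian (DPSS) tapers of length 1024 at
NW = 3, averaging tapered periodograms over half-overlapping windows;
one-sided density per Hz (validated against line recovery, spectral
flatness, and Parseval).

## Cofiring ratio

CCGs use 1 ms bins over ±50 ms (the window was an open choice; it
comfortably contains the ±15 ms cofiring window). Lag bins are half-open;
the vectorized counting path, the fast cofire path, and the brute-force test
oracle share this convention bit-for-bit. Only trigger spikes are
epoch-restricted — response spikes may fall at any time, the literal reading
of the trigger/response asymmetry; an option restricts both. Pairs are
formed across different shanks within a session. A CCG with zero triggers or
zero coincidences is undefined and the pair is excluded (logged).

The cofiring probability is the mean normalized bin value over the 31 bins
with centers within ±15 ms. CFR divides the nonrhythmic-triggered by the
gamma-triggered cofiring probability; pairs with zero gamma cofiring are
excluded. The shuffle null shifts every epoch-selected trigger spike
independently by Uniform(−25, 25) s wrapped modulo the session span and
recomputes both cofiring probabilities; 1,000 shuffles per pair by default.
Per-spike independent shifts (rather than one whole-train shift) were chosen
because a single rigid shift preserves within-train structure that the null
is meant to destroy. Group tests per ordered population pair compare
original vs per-pair mean control CFR with a paired t test when the paired
differences pass Shapiro at α = 0.05, else Wilcoxon signed-rank; groups
below 2 valid pairs are reported missing. No correction is applied across
population-pair groups (each is tested at α = 0.05).

## Synthetic data

The generators emulate the study conditions the analysis assumes and provide
exact ground truth. Ethograms: behaviors interleave in shuffled triplets
separated by 8–20 s unscored gaps; feeding durations are lognormal (median
22 s, σ_log 0.5) truncated at the 4.8 s scoring minimum; social and object
durations lognormal (median 4 s) — feeding bouts ≈ 6× longer than other
episodes, matching the recorded regime. Spike trains: inhomogeneous Poisson
by thinning (exact for piecewise-defined rates); each cell fires at its
template baseline (1.7–3.5 Hz depending on population, guided by the
reported per-population averages) multiplied by the template tuning inside
episodes. Phase-bump templates are Gaussians in episode phase at centers
0.05/0.30/0.70/0.95 (FOn/EF/LF/FOff), width 0.1; homogeneous templates
(Fd/Sol/Exp) elevate uniformly during their behavior. The modulation depth
(3× baseline at peak) is a free simulation choice — no quantitative depth
was reported. Cells distribute round-robin over sessions and ≥ 2 shanks.

LFP: pink (1/f-amplitude) Gaussian noise with Tukey-windowed sinusoidal
bursts at the band center; burst amplitude is specified on the detector's
own scale, as SDs above the noise mean of the band's rectified signal (a
"4 SD burst" sits 4 noise-SDs above the noise mean, hence clearly above the
2 SD detection rule — an amplitude defined as an absolute envelope of 4 SD
would sit only ~1.6 SD above the mean and be undetectable by construction).
Pair coupling injects Poisson-rate synchronous spike pairs (second spike
jittered by ±jitter_ms) inside chosen epochs only, preserving all original
spikes.

What the generators do *not* emulate: refractoriness and bursting,
rate nonstationarities across a session, theta/gamma phase coupling of
spikes, volume-conducted artifacts, correlated noise across cells, or
imperfect spike sorting. Passing tests therefore demonstrate correctness of
the pipeline's statistics under its own model assumptions, not robustness to
every pathology of real recordings.

## Problem sizes and runtime

Validation runs use desk-scale versions of the study conditions, chosen to
exercise every stage at full parameter settings while keeping the suite and
the acceptance script at a few minutes on one CPU:

- planted-population recovery: 7 templates × 50 cells, 10 sessions × 1,200 s,
  full scan (k 2–10 × knn {10, 20, 30}, 100 bootstraps), 100 silhouette
  iterations;
- phase-order recovery: 20 independent runs of 7 × 20 cells, 4 × 600 s,
  clustered at (k = 7, knn = 10);
- event detection: 20 planted 4 SD, 100 ms bursts per gamma band in 120 s of
  pink noise (≈ one event per 6 s, a realistic gamma event density at which
  whole-session noise statistics include genuine events, as on real data);
- CFR null calibration: 100 independent 5 Hz Poisson pairs, 30 min, 300
  shuffles per pair; assembly sign recovery and type-I: 15 coupled pairs and
  200 all-null replicate groups of 10 pairs (10 min sessions, 30 shuffles
  per pair for the per-pair control mean);
- oracles: 1,000 fuzz instances each for the agreement metrics (n ≤ 30) and
  the epoch-conditioned CCG (trains ≤ 100 spikes); KS calibration: 10,000
  uniform samples of n = 60.

## Known limitations

- The stability scan is O(grid × n_boot) spectral clusterings; for thousands
  of cells the dense eigendecomposition should be replaced by a sparse
  solver.
- Bonferroni across the population × behavior family is the only multiplicity
  control; the population-pair CFR tables are uncorrected by design.
- Warping assumes behavior unfolds proportionally to episode duration;
  landmark-based or dynamic time warping are out of scope.
- The flat-binary LFP reader covers single- and multi-channel interleaved
  int16 only; proprietary acquisition formats are not supported.
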