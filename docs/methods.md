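# Methods

`hierflux` analyzes hierarchical dynamics of low-frequency brain
fluctuations: how strongly spontaneous activity concentrates at the
transmodal versus unimodal end of the cortical hierarchy, how that
concentration evolves in time, and which discrete global states,
propagating events and electrophysiological signatures accompany it.
This note documents the models, the conventions that fix absolute
scales, the synthetic-data generator, and the design choices that were
genuinely open.

## Fluctuation-amplitude maps

Low-frequency signal variability is measured per region either in the
time domain — the sample standard deviation of the 0.01–0.08 Hz
band-limited signal — or in the frequency domain as ALFF, the summed
Fourier amplitude inside the band. With the demeaned signal written as
`x(t) = Σ_k [a_k cos(2π f_k t) + b_k sin(2π f_k t)]`,

```
ALFF = Σ_{k: f_k ∈ [0.01, 0.08]} sqrt((a_k² + b_k²) / N)
```

Conventions (they change absolute scales, never rankings, and the
downstream statistic is rank-based):

* **Filter.** 4th-order Butterworth bandpass applied forward–backward
  (`sosfiltfilt`), i.e. zero phase. The same filter is used for BOLD-like
  signals, for band-limited power (BLP) time courses, and inside the
  synthetic generator, so generator and analyzer agree on spectral
  content.
* **Fourier convention.** `a_k = (2/N) Σ x cos`, `b_k = (2/N) Σ x sin`
  for `0 < f_k <` Nyquist; DC removed by demeaning; the Nyquist bin is
  excluded so every retained bin follows the same scaling. A single
  in-band sinusoid of amplitude A on an exact bin yields `A/√N`.
* **Denominators.** Sample (N−1) SD everywhere, including the spatial
  z-normalization that turns a map into a heterogeneity pattern.
* **Windows.** 0-based, half-open, starting at frame 0; remainder frames
  at the run end are dropped (a 1200-frame run at length 50 gives exactly
  24 windows). An optional stride below the window length produces the
  overlapping variant.

SD and ALFF are "Parseval-analogous": SD² sums squared bin amplitudes
while ALFF sums the amplitudes themselves, so the two rank regions
identically exactly when regions share one spectral magnitude profile.
The test fixture `band_limited_regions` constructs precisely that case
(fixed in-band magnitudes, independent random phases); on generic
band-limited noise the agreement is near-perfect but not exact, which is
a property of the estimators, not an implementation artifact.

## Principal gradient (diffusion-map embedding)

The hierarchy reference is the principal diffusion-embedding component
of the functional connectome: Pearson FC → per-row top-10% retention
(sparsity 0.9; kept entries per row are the top `(1−sparsity)` fraction,
then `(S+Sᵀ)/2` symmetrization) → cosine-similarity affinity with
negatives clipped to 0 → density normalization `W = D^−α A D^−α` with
α = 0.5 → random-walk matrix `M = D_W^−1 W` → eigendecomposition.
Components are the nontrivial right eigenvectors of `M` (the constant
eigenvector at eigenvalue 1 is dropped), unit-norm with a deterministic
sign (largest-magnitude entry positive), each scaled by its eigenvalue
(diffusion time t = 0). The spectrum is computed through the symmetric
conjugate `D_W^−1/2 W D_W^−1/2`, which is numerically robust and agrees
with a direct nonsymmetric eigendecomposition to ~1e−15 on the test
fixtures. Eigenvector sign remains arbitrary in principle; `align_sign`
flips components against a reference map. An externally supplied
gradient file is treated identically to a computed one.

## Hierarchical index and its dynamics

The hierarchical index is the Spearman correlation (average ranks for
ties; two-sided p-values) between a spatial amplitude map and the
gradient. Windowed trajectories filter the full run once and take
per-window SDs of the filtered signal — filtering once avoids per-window
transients; the choice of ordering is a convention. Degenerate windows
(constant maps) yield NaN rather than raising, so runs with dead regions
complete.

Consciousness-related contrast maps come in three forms: a paired-t map
between two conditions (A−B per region), a Spearman map of per-window
amplitude against a state code (e.g. sleep stages 0/−1/−2/−3), and the
interval variant where all `n(n−1)/2` window pairs (276 for 24 windows)
are correlated against their time interval (1–23).

The trend test is an unadjusted Pearson correlation of the trajectory
against window index. A caveat established by simulation: at TR = 0.72 s
a 50-frame window spans 36 s while the slowest passband components have
100 s periods, so window variances are weakly positively correlated
across neighboring windows and the nominal 5% test empirically rejects
at ≈6–8% on stationary synthetic data. The trajectory machinery itself
is calibrated (5.5% on window-independent maps through the identical
code path); the excess is a property of windowed variance estimates at
these acquisition parameters, and it disappears as windows lengthen
relative to the band.

## Spin tests

Map-versus-map correlations are tested against rotation nulls that
preserve spatial autocorrelation. Rotations are Haar-uniform (sampled
via uniform unit quaternions); a rotated map takes at each vertex the
value of the nearest original vertex (great-circle metric; KD-tree ties
break to the lowest index). Masked vertices keep their mask; rotated
positions landing on masked donors take the nearest unmasked donor. The
parcel variant projects parcel values to vertices, rotates, and
re-averages within the original parcels. Only `map_x` is rotated — the
standard asymmetric design for comparing an empirical map against a
fixed reference. The p-value is two-sided by absolute value with the
add-one convention, so it is never zero. Test geometry is a Fibonacci
lattice; calibration uses pairs of independent white-noise maps smoothed
with a great-circle Gaussian (FWHM 40°), where the spin test rejects at
≈4–5% and a spatially blind shuffle rejects at >30% — the anticipated
anticonservative contrast.

## Brain states and entropies

The global signal (GS) is the unweighted region mean; a window's GS
topography is the per-region Pearson correlation with that window's GS.
K-means (Euclidean, 50 seeded restarts) clusters window topographies;
silhouette coefficients over k = 2..10 guide the choice of k (argmax by
default, overridable to a fixed k). The clustering runs on raw
topography vectors; the window-by-window similarity matrix is a
diagnostic output, not the clustering space. The two-state centroid
contrast is oriented by hierarchical similarity: state 1 is the centroid
with the higher Spearman correlation with the gradient.

Connectivity entropy of a node is the normalized Shannon entropy of its
FC value distribution: `n = 10` equal-width bins spanning the node's
observed min–max (self-connection excluded), `H = −Σ pᵢ log pᵢ / log n`
with `0·log 0 = 0`, hence `H ∈ [0, 1]` and invariance to affine
rescaling of the row. The binning range convention is stated explicitly
because it changes H; a constant row returns 0 by convention.

Sample entropy is `−log(A/B)` with B (A) the number of length-m
(length-m+1) template pairs within Chebyshev distance `r = 0.5·SD`;
overlapping templates allowed, self-matches excluded (the standard
Richman–Moorman convention), defaults m = 2. `B = 0` flags NaN and
`A = 0` flags +inf rather than raising. H decreases monotonically in r
and orders white noise above a same-variance sinusoid.

## Quasiperiodic patterns

A QPP template is a region × L matrix (L = 30 frames at TR 0.72 s, ≈
21.6 s; 50 frames at 0.4 s for ECoG-like data). Matching slides the
template one frame at a time and correlates the flattened
(region-major) template with each flattened segment — computed via FFT
cross-correlation plus sliding sums, verified against the direct
formula. Events are strict local maxima at or above r = 0.4 (plateaus
count at their leftmost frame); maxima closer than `min_sep = L` keep
the higher correlation, so events never overlap. Lags are never
wrapped.

Template building is recursive match-and-average from 20 random
starting segments: detect super-threshold events, average their
segments, repeat until the event set repeats (convergence) or 20
iterations; the candidate with the highest summed event correlation
wins. The returned template reproduces its own event set exactly (fixed
point). Cross-template comparison uses a circular phase alignment over
a bounded shift range (ties: smaller |shift|, then negative).

Event summaries: the gradient projection of a frame (plain dot
product); bottom/top 20% gradient-ranked mean traces per event (a
propagating wave shows the high-order trace lagging); a
typical/atypical split at r = 0.5 against the template's high-order
trace (boundary counts as typical; constant traces are atypical); and
within-event network FC with an optional edgewise two-sample t contrast
between two event groups.

## Band-limited power (ECoG path)

Multitaper spectrogram: 1 s windows, 0.2 s step, 5 DPSS tapers. The
time–bandwidth product is NW = 3 — the smallest giving five
well-concentrated tapers — so a pure tone spreads over ±3 Hz; power is
averaged over tapers and binned to 1 Hz bins centered on the integers
1–100 Hz. Normalization is `10·log10(power + 1e−12)` followed by
per-channel, per-frequency temporal mean removal, making the pipeline
invariant to global gain. BLP is the mean of the normalized spectrogram
over inclusive integer bands (delta 1–4, alpha–beta 5–30, gamma
40–100 Hz), then 0.01–0.08 Hz zero-phase filtered. Band averaging
happens on the dB-scale normalized spectrogram (dB first, then
average). A 50 Hz notch is available but off by default for synthetic
inputs. The BLP hierarchical index applies the fMRI-side machinery to
per-channel SD maps over 150 s fragments (750 frames at the 0.2 s
step). The gamma "peak difference" between top/bottom 20% gradient
channels within the first 12 s of an event is the difference of the
per-trace maxima by default; the max-of-difference reading of the same
quantity is available via a mode switch, since either is defensible.

## Synthetic-data generator

No real recordings ship with the package; the generator plants known
structure so every stage is tested against ground truth. The
resting-state model is

```
x_i(t) = [σ₀ + β·rank(g_i)·s(t)]·η_i(t) + w_i(t)·G(t) + ε_i(t)
```

with `η_i` independent band-limited (0.01–0.08 Hz) unit-variance noise,
`G` a shared band-limited global component with loading
`w_i(t) = w_lo + (w_hi − w_lo)·rank(g_i)·s(t)`, `ε_i` white measurement
noise, `g` the planted gradient, `rank(·)` the normalized rank in
[0, 1] (coupling in rank space makes the planted effect exactly what a
rank correlation should recover), and `s(t) ∈ [0, 1]` a slow state.
Defaults encode an HCP-like run: 200 regions, 1200 frames at
dt = 0.72 s, σ₀ = 1, β = 1 (β/σ₀ = 1), w_lo = 0.2, w_hi = 0.5,
ε SD 0.1, linear ramp state. All randomness flows through one
explicitly passed seeded generator; identical spec + seed reproduces
outputs bit for bit.

Band-limited noise is white noise passed through the same zero-phase
Butterworth as the analyzers and scaled by the filter's deterministic
gain (the mean of |H|⁴ over the DFT grid). Normalizing by each
realization's sample SD instead would pin every region's total run
energy and induce long-range anticorrelation between window variances —
a subtle artifact that manifests as spurious trajectory trends; the
deterministic gain avoids it while keeping the process at unit
variance.

Other fixtures: one-cycle sinusoid QPP templates whose phase lags
linearly with gradient rank (a gradient-ordered propagating wave,
analytically checkable); piecewise-constant Markov stage walks with a
minimum dwell time (sleep-stage-like label sequences); ECoG-like
channels — a unit-variance 55–65 Hz narrowband carrier whose envelope
is `1 + coupling·rank(g_i)·mod(t)`, plus a 2 Hz oscillation and white
noise; a distance-decay connectome `C_ij = exp(−decay·|p_i − p_j|)` on
a latent 1-D axis whose principal embedding component is provably
monotone in `p`; strictly band-limited regions with a shared magnitude
profile and random phases (Parseval fixture); and two-family GS
topography sets for clustering recovery.

What the generator does **not** emulate: hemodynamics, anatomical
geometry, physiological confounds (cardiac/respiratory), head motion,
scanner drift, spatial autocorrelation between regions (regions are
conditionally independent given the planted components). Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to the full nuisance structure of real
recordings.

## Problem sizes and numerical choices

Simulation-based checks use 200 regions × 2000 frames (40 windows of
50 frames), 1000 replicates for the trend-test calibration, 500 map
pairs × 500 rotations on a 1000-vertex sphere for spin calibration,
20 injected events in 200 × 2000 noise at gain/noise = 2 for QPP
recovery, and a single-channel 300 s recording at 1 kHz for the BLP
envelope check — sizes at which every planted effect is comfortably
identifiable while the full suite runs in minutes.

Degenerate inputs are flagged, not raised, wherever a partial result is
scientifically meaningful (dead regions → NaN map entries; constant
trajectories → NaN trend; degenerate entropies → 0/NaN/inf by stated
convention); they raise only where no meaningful output exists (empty
bands, disconnected graphs, constant state vectors, overlapping event
injections). Ties break deterministically everywhere (average ranks in
correlations; lowest index in nearest-vertex lookup; leftmost frame on
match plateaus; smaller |shift| then negative in phase alignment).

## Known limitations

* The trend test is nominal-level only when windows are long relative
  to the slowest passband period (see above).
* Parcel-level spins on coarse parcellations inherit the discreteness
  of vertex re-assignment; p-values are exact only under the add-one
  permutation convention.
* `build_template` is a greedy fixed-point iteration; with few events
  or heavy noise different starting segments can converge to phase-
  shifted variants of the same cycle, which is why cross-template
  comparisons go through `phase_align`.
* The ECoG generator's carrier is narrowband noise, not a biophysical
  gamma model; BLP results on it validate the spectral pipeline, not
  neural claims.
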