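# Methods

This note documents the models, estimators and numerical choices behind
`nucleoflow`, what the synthetic benchmark does and does not emulate, and the
known limitations of the measurement chain.

## Physical model

A cell in a confluent monolayer is treated as two elastic elements in
series — nucleus (modulus `E_n`) and cytoplasm (`E_cy`) — subjected to a
common in-plane stress.  The projected cell-area strain decomposes as
`a_c = beta * a_n + (1 - beta) * a_cy` with `beta = <A_n>/<A_c>` the nuclear
area fraction.  Under the continuity approximation (weakly inhomogeneous
cell number density) the divergence of the tissue velocity field equals the
cell-area strain rate, so the slope `m` of nuclear strain rate versus local
divergence measures the ratio of nuclear to cellular deformation rates.
Its reciprocal `e_n = 1/m` is a purely kinematic "relative stiffness", and
eliminating the (unknown, common) stress from the series model gives

    E_n / E_cy = (e_n - beta) / (1 - beta).

The model assumes an instantaneous elastic response at the 2–10 min frame
intervals of these experiments (viscoelastic relaxation happens on tens of
seconds).  Consistently, the strain-rate/divergence cross-correlation must
peak at zero delay — this is checked, not assumed.  Only the modulus *ratio*
is identifiable; the stress proportionality constant cancels.

## Estimators

**Strain rates.**  The instantaneous single-nucleus area strain rate is the
symmetric difference `adot = (2/dt) (A2 - A1)/(A2 + A1)` (units 1/h),
antisymmetric under frame exchange.  Because the mean projected area is not
stationary over hours, deformation *amplitudes* are quantified through
increments: the mean square strain
`MSS(tau) = <<[ (A(t+tau)-A(t)) / <A>_window ]^2 >_t>_j`, computed for all
integer multiples of the frame interval up to a third of the analysis
window, and fitted by weighted least squares with
`MSS(tau) = sigma_w + adot0 * tau_c * (1 - exp(-tau/tau_c))`: linear
(diffusive-like) at short delays with characteristic strain rate `adot0`,
saturating beyond the correlation time `tau_c`; the offset `sigma_w`
absorbs delta-correlated area measurement noise (an i.i.d. relative area
error of variance `s^2` contributes `2 s^2`).  The fit is verified against
an exactly discretized Ornstein–Uhlenbeck area process, for which the
increment variance is known in closed form (`tau_c = 1/theta`,
`adot0 = sigma_OU^2 / <A>^2`).

**Coupling fit.**  Strain-rate/divergence pairs are summarized in 25
equal-width divergence bins spanning ±3 standard deviations (bins with
fewer than 50 pairs are dropped).  The slope `m` is a zero-intercept fit
restricted to `|div| <= 1 sigma_div` — real data saturate at large
strain rates, so only the near-origin linear regime is fitted; the range is
configurable.  The fit is computed on the raw pairs inside the range rather
than on the bin means: bin means share frames and nuclei, their errors are
strongly correlated, and SEM-weighting them proved unstable (slope
excursions of several percent).  The slope standard error is
heteroscedasticity-robust; a free-intercept fit is reported as a
diagnostic.  `beta` is estimated per analysis window as
`<A_n> * N / FOV-area` per frame (border-truncated nuclei are excluded from
the mean area but counted in `N`), with its standard error from five
contiguous time sub-blocks.  Analysis windows default to five
half-overlapping intervals covering the record (0–8, 4–12, … h on a 24 h
record).

## Pipeline stages and numerical choices

**Background.**  Iterative masked interpolation (ten iterations by
default): cubic interpolation from randomly sampled points (one per
~500 px²), then exclusion of pixels above the masked median + 2 robust
standard deviations, repeated; averaged over ten frames equally spaced in
time.  Interpolation is evaluated on a 4× coarse grid (the background
varies slowly).

**Registration.**  Consecutive-frame translations by phase correlation
(subpixel via Fourier upsampling).  The cumulative trajectory is split into
a smooth migration component (degree-20 polynomial in a scaled basis,
capped at `n_frames/4`) plus stage jitter, which is removed by bilinear
shifting.  A degree-`d` polynomial over `T` frames inevitably absorbs a
fraction `(d+1)/T` of white jitter variance, so jitter recovery to
< 0.5 px RMS needs records of ~200 frames at jitter sigma ~1 px.

**Segmentation.**  Wiener-type adaptive denoising (5×5); LoG filtering with
`sigma = 0.27 ×` expected nucleus diameter (interiors become wells, edges
ridges); division by a surface interpolated through the significant
regional minima (h-minima at 10% of the global well depth) to level
inter-nucleus brightness differences; binarization at the threshold
maximizing the 8-connected domain count (100 levels between the 1st and
99th percentile, with a full-range retry for sparse fields).  Domains are
then *grown*, identity-preserving, by a marker watershed of the corrected
LoG map up to just below its zero-crossing — the count-maximizing threshold
separates nuclei reliably but keeps only the deepest part of each well, and
tiny domains misplace both the centroid seeds and the equidistance lines.
Merged-nucleus candidates (aspect ratio > 3, or area > 1.6× the median
domain area) are replaced by two 2 px disks at the two deepest
scale-smoothed LoG minima.  Internal watershed seeds are the domain
centroids with the eroded (3 px) grown domains as marker support; external
seeds are the ridge lines of the watershed of the Euclidean distance
transform plus the image border.  The final watershed runs on the Sobel
gradient magnitude with the gradient forced to zero at all seeds.
Boundaries are refined to subpixel accuracy by parabolic localization of
the gradient-magnitude peak along the local gradient direction; areas and
centroids come from the refined polygon (shoelace), the aspect ratio from
the pixel-coordinate covariance eigenvalues, `J` is the summed intensity.
Regions under 5 px are discarded; border-touching regions are flagged and
excluded from strain statistics.

**Tracking.**  Globally optimal frame-to-frame assignment
(squared-displacement cost, Hungarian algorithm) with birth/death costs at
the gate; the gate defaults to 0.4× the mean inter-nucleus spacing and
scales with the gap length; gaps up to one frame are bridged.  The quality
filter invalidates frames whose total intensity deviates more than 10% from
the median over the previous ten validated frames (frames without a full
history are exempt) and drops trajectories losing more than 20% of their
frames.  The deviation is two-sided: merges raise `J`, truncations lower
it.  The ensemble MSD in the center-of-mass frame is fitted with the
persistent-random-walk form
`MSD(tau) = sigma_MSD + 2 u^2 tau_p^2 (tau/tau_p - 1 + exp(-tau/tau_p))`
to verify that the persistence time exceeds the frame interval (the
instantaneous-velocity assumption).

**PIV.**  Single-pass cross-correlation of square interrogation windows
sized *slightly larger than the mean inter-nuclear distance* (the window
must contain whole-nucleus structure; with windows below the nucleus
diameter the aperture problem dominates).  For the data the method was
designed around that rule gives ~14 µm; the pipeline default is 1.2× the
measured spacing.  Correlations are computed zero-padded (linear) and
normalized by the per-lag overlap — the raw estimator is biased toward zero
displacement ("loss of pairs") — with a mild Gaussian lag prior to keep the
variance-amplified rim from producing spurious far peaks, and a three-point
Gaussian/parabolic subpixel peak fit.  Windows whose contrast is below 10%
of the frame's are flagged invalid (nucleus-free regions); outliers beyond
4 robust standard deviations per component are replaced by the median of
their valid 8-neighbours, iterating until the field is filled.  The
divergence uses central differences (one-sided at borders) followed by a
0.70-grid-cell Gaussian smoothing: on the synthetic benchmark this setting
balances the low-pass attenuation of the window/grid/smoothing chain
against noise-induced regression dilution so that the divergence
interpolated at nucleus centers (bicubic) regresses on the true divergence
with unit slope to within ~1% (the residual wanders ±3% between
realizations).

## The synthetic benchmark

The generator emulates a 10× fluorescence recording of a confluent
MCF10A-like monolayer: 0.65 µm/px, 512×512 px (333 µm) FOV, 5 min frames,
200 nuclei (mean spacing 23.5 µm), nuclear area fraction `beta = 0.4`,
aspect ratios with median 1.4 and spread 0.5, per-nucleus brightness spread
of 25%.  Nuclei are anti-aliased ellipses (logistic edge, half-maximum
exactly on the true boundary) modulated by chromatin-like granules defined
in material coordinates, so texture advects and rescales with the nucleus;
total per-nucleus fluorescence is conserved (intensity ∝ 1/area).  Areas
follow `A <- A (1 + m * div * dt)` with `m = 0.5` by default, centers
advect by explicit Euler steps.  The default flow is a pair of sinusoidal
compression waves (wavelength = FOV width, amplitude 20 µm/h, divergence
amplitude ~0.4 1/h) whose phase drifts with a 2 h period so that
peak-to-peak nucleus displacements (~13 µm) stay below the inter-nuclear
distance — cells oscillate around their cage, as in a monolayer near
dynamic arrest, rather than streaming out of the FOV.  Imperfections:
tilted additive background (level 120, ±30% gradient), Poisson shot noise,
and i.i.d. Gaussian stage jitter (sigma 1 px).

Two deliberate departures from the real data regime: the divergence
amplitude is ~10× the experimental values so that 200 nuclei × 100 frames
resolve the coupling above segmentation noise (real analyses use thousands
of nuclei over 24 h), and photobleaching, cell division, out-of-focus
drift and optical vignetting are not modelled.  Passing the benchmark
therefore demonstrates correctness of the estimators and their couplings,
not robustness to every real-world artefact.

## Known limitations

* **Small-signal area response under crowding.**  Frame-to-frame nuclear
  area changes of ~1% move boundaries by ~0.1 px.  Where two nuclei are
  close, the watershed boundary sits on the mid-gap ridge and partially
  tracks the gap — which, by continuity, closes faster than the nuclei
  shrink — so measured strain rates over-respond to the divergence by
  ~5–8% (realization-dependent).  End-to-end this biases `e_n` low by a
  similar amount; with imaging noise included the recovery stays well
  within 15%, but the noise-free recovery is typically 5–10% rather than
  <5%.  A boundary estimator anchored to each nucleus's own edge profile
  would remove this; the inward-searching refinement tried here traded the
  bias for texture-induced noise.
* The domain-count-maximizing threshold needs a non-degenerate count curve;
  on sparse fields the percentile grid can miss the maximum (a full-range
  retry is built in), and images without any interior count maximum are
  rejected explicitly.
* Detection recall is insensitive to photon noise until SNR ~2 (texture,
  not noise, is the difficulty on these images) and then collapses; the
  recall-versus-noise curve is flat within ±1 nucleus over a wide SNR
  range.
* `v_CM` comparisons between PIV and tracking on flows with zero spatial
  mean are limited by the PIV grid covering slightly less than the full
  FOV; collective-drift agreement is the meaningful cross-check.
* Linking assumes no divisions or merges; a dividing nucleus appears as a
  trajectory break plus a birth.
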