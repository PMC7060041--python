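# Methods

This note documents the models behind `mvrmap`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices that affect results.

## Imaging model

Acquisition follows stimulus-locked pHluorin imaging of hippocampal
boutons: a 120-stimulus train at 1 Hz, one 40 ms frame captured 45 ms
before each stimulus and one coincident with it, 65 nm effective pixels,
and a PSF modeled as an isotropic Gaussian of sigma ≈ 130 nm. A fusion
event contributes a pixel-integrated Gaussian to the stimulus-locked
frame; its expected photon count is the event's quantal content scaled by
the remaining-frame fraction (frame − delay)/frame — a fusion delayed by
*d* ms after the stimulus is integrated only for the rest of the frame.
Both frames carry constant background, Poisson photon noise and Gaussian
read noise; photobleaching decays quantal content as a single exponential
in experiment time.

Coordinates are continuous nanometres with the origin at the field corner;
pixel (i, j) spans rows [i·65, (i+1)·65) nm in y and columns likewise in x
(0-based, half-open). Bouton-local coordinates put the AZ center at the
origin; the renderer shifts them to the field center.

### Photon budget

The recordings this pipeline targets resolve single-vesicle events with
~27 nm localization precision, which we read as the overall (2-D radial)
localization error. Neither photon counts nor SNR are fixed by that
statement, so defaults were chosen once to land in that regime:
300 expected photons per quantum, 15 background photons/pixel/frame,
2 photons read-noise SD. Under these conditions the measured repeated-fit
spread is ≈ 20 nm per axis (≈ 28 nm radial) and the parameter-covariance
precision estimate agrees with the empirical spread within 25%.
Photobleaching defaults to τ = 300 s (a ~33% amplitude loss over the
120 s train — large enough to require correction, small enough to keep
late events detectable). Calibration beads default to 10× the quantal
brightness, reflecting that bead calibration is photon-rich.

## Synthetic experiment

A bouton is a disc-shaped AZ (default radius 180 nm, matching a ~0.10 µm²
hull) holding `n_sites` = 8 release sites placed uniformly with a 60 nm
minimum spacing, so truth sites are resolvable under the 50 nm clustering
criterion. Site release probability interpolates linearly in radius from
`pr_center` = 0.04 to `pr_edge` = 0.008 — the observed P_r-site range over
a 120-stimulus train — giving the center-to-periphery release-probability
gradient the analysis is designed to detect.

Per stimulus each site fires independently with its P_r; when several fire
the generator keeps one fusion (uniform among firers), so spontaneous
activity yields at most one event per stimulus and multi-vesicular events
arise only by explicit promotion: a firing stimulus becomes an MVR pair
with probability `mvr_fraction` = 0.05, which makes ~9–10% of all fusion
events members of MVR pairs. The second fusion is placed at another site
with weight ∝ site P_r (both MVR sites tend to be high-P_r sites), damped
exponentially with distance from the first site (scale 250 nm) and biased
2:1 toward sites more peripheral than the first; its delay is
|Normal(0, 2 ms)| truncated to the frame, in line with the 1–5 ms
desynchronization reported for MVR. Quantal amplitudes carry Gaussian
variability with CV 0.2 (two clearly separable histogram peaks at q and
2q, as observed).

Condition modes: `egta` shrinks the second-site distance scale to 120 nm
(tightened MVR spread under calcium buffering); `strontium` draws *all*
delays Uniform(0, frame) (asynchronous release), producing the left-shifted,
non-Gaussian amplitude distribution used as a control.

**What the generator does not emulate:** vectorial/defocused PSFs, focal
drift, camera gain maps, axial structure, overlapping neighboring boutons,
vesicle-size or cleft-pH gradients, and activity-dependent changes in site
properties during the train. Passing tests therefore certify the analysis
chain against this idealized forward model, not against every instrumental
artifact of real recordings.

## Localization

Candidates are local maxima of the Gaussian-smoothed difference image
(post − pre) above `snr_threshold` × noise SD. The noise SD is estimated
from the raw difference pixels by MAD (uncorrelated, robust to the small
bright event area) and propagated through the smoothing kernel
(‖k‖₂ = 1/√(4π σ_px²)). Because smoothing correlates noise over the PSF
scale, blank-field maxima routinely reach 4–4.8 SD; the default threshold
is 5, which measured 0 false positives in 200 blank frames while detecting
~93% of full-amplitude events. Maxima within 2 σ_px of the border are
discarded (edge smoothing inflates noise there and edge spots cannot be
fit). Detection windows are 4·⌈σ/px⌉ + 1 pixels on a side; nearby
candidates are merged into a joint window so that partially overlapping
fusions are fitted together rather than as two biased single fits.

All fits are unweighted least squares on pixel-integrated models with
deterministic moment-based initialization (identical input ⇒ identical
output):

- **Single fit**: symmetric Gaussian, width fixed to the calibrated PSF
  sigma; free position, total-photon amplitude, constant offset. Per-axis
  precision is read off the parameter covariance (J'J)⁻¹·RSS/dof.
- **Mixture fit**: one vs two fixed-width components, compared by a nested
  F-test at α = 0.05 (3 extra parameters). Two components are accepted
  only if the F-test is significant, the separation is at least one pixel,
  and *both* amplitudes are significantly positive (one-sided t at α from
  the fit covariance). The significance gate matters: under Poisson noise
  the unweighted F-test alone splits 10–15% of genuine single events.
  The second component is seeded at the brightest residual pixel, the
  first at the brightest window pixel (for a true pair the single fit
  lands between the blobs). On noiseless images the selection is exact:
  200/200 singles select one component, 200/200 well-separated pairs
  select two with sub-nanometre position errors.
- **Asymmetric fit**: rotated elliptical Gaussian (free widths δ₁ ≥ δ₂,
  orientation free, reported modulo π), pixel-integrated by 3×3 midpoint
  oversampling. The asymmetry score δ₁/δ₂ − 1 is ~0 for symmetric spots
  and strictly increasing in the separation of two unresolved events.

PSF calibration fits a free-sigma symmetric Gaussian to every detected
bead in a stack and averages; with the default bead brightness the
estimate is within ~1% of truth on 50 noisy frames.

## Quantal analysis

Boutons with fewer than 5 events are excluded from all analyses.
Photobleaching is corrected first (single exponential fitted to amplitude
vs time; fitted τ above 10⁴ s is treated as "no bleaching", factor 1), and
quantal statistics are computed on the corrected amplitudes — the ordering
(correct, then estimate) is a documented choice where the alternative is
equally defensible. Resolved MVR members are excluded from the quantal
sample, and one round of 3-SD trimming removes stray multi-quantal events
before the final mean/SD so they do not inflate the quantal SD. The MVR
threshold is exactly mean + 2 SD per bouton. With quantal CV 0.5 the
threshold rule captures ~50% of two-quanta events (matching the closed
form Φ((2μ − thr)/(σ√2))); the two-peak histogram fit (scikit-learn
Gaussian mixture, declared two-peaked only when the fitted density is
actually bimodal) recovers a 91%/9% q vs 2q composition within ±3%.

The frame-integration delay estimate is the exact inverse of the
rendering law: delay = (1 − amplitude ratio) × frame. The optional
measurement-uncertainty deduction subtracts u/2 from the amplitude deficit
(the expected inflation of a folded deficit under symmetric ±u noise);
with the ~10% amplitude uncertainty this shrinks the 4 ms bound at ratio
0.9 to 2 ms. It is off by default, so reported delays are upper bounds.

## Release-site analyses

"Cluster diameter 50 nm" is read as the maximal within-cluster pairwise
distance, i.e. complete linkage cut at 50 nm (boundary inclusive); the
partition is identical to exhaustive greedy agglomeration for all tested
configurations. P_r-site divides event count by the number of stimuli
(120 at 1 Hz, where counts per second and per stimulus coincide), so
values are quantized at 1/120 multiples. The AZ center is the mean of all
fusion positions (MVR members included) and AZ area the convex hull in
µm²; degenerate (collinear) configurations return area 0 with a flag.
Overlap of an MVR pair with UVR activity is classified full/partial/none
either site-based or by ≤ 25 nm proximity (boundary inclusive);
equidistant-band comparisons use a ±25 nm annulus around the target
site's distance to center and flag the result undefined when no
comparator exists. Proximal/distal within a pair follows distance to the
AZ center, exact ties broken toward the larger-amplitude member with a
tie flag; unresolved MVR events are positioned at their asymmetric-fit
peak.

## Pair statistics

Amplitude difference is expressed as a percentage of the larger member
(configurable; the scale is consistent with treating the reference
regression coefficients — slope 0.021 %/nm control, 0.006 %/nm under
EGTA — as unit-compatible). Separation-threshold fractions use strict
"<". Condition slope contrasts use the group × covariate interaction term
of a pooled OLS model (two-sided); all tests are two-sided at α = 0.05
with raw p-values (no multiplicity correction). The stimulus-train
control regresses per-stimulus double-event probability on stimulus index;
the asynchronous control compares synchronous vs strontium-mode amplitude
distributions by two-sample KS (uniform intra-frame delays halve the
median collected amplitude).

## Problem sizes and determinism

Simulation-backed tests use 40–60 boutons per property, 100-seed repeats
for coverage-style claims (e.g. bleaching-corrected series show no time
trend in ≥95/100 boutons; the stationary train control covers zero slope
in ≥93/100 runs of 16 boutons), and 150–200 replicates for fit-recovery
suites — sizes at which the checked effects are statistically
unambiguous. All randomness flows through explicit integer seeds; the
pipeline is bit-reproducible for a fixed config and seed, and the report
embeds a hash of all analysis-relevant parameters.

## Known limitations

- The imaging path under the default photon budget detects ~60% of all
  simulated fusions (dim delayed/bleached events fall below threshold), so
  imaging-mode site maps and pair counts are conservative relative to
  ground-truth passthrough; with ~20 nm per-axis error against a 50 nm
  cluster diameter, noisy event clouds of a single true site can split,
  and the imaging-mode site partition reproduces the truth partition for
  roughly three quarters of matched events (chance level ~15%).
- The mixture fit is limited to two components; triple fusions in one
  frame are not modeled (they are rare at the simulated MVR rate).
- The amplitude classifier is censored by construction (~half of true
  two-quanta events at CV 0.5 stay below mean + 2 SD); no attempt is made
  to extrapolate the true MVR prevalence from the censored counts.
- The F-test model selection assumes iid Gaussian residuals; under
  photon-limited noise it is used jointly with the amplitude-significance
  gate, which restores parsimony empirically but is not an exact
  likelihood-ratio procedure.
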