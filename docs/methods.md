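# Methods

This note documents the models, numerical choices and design decisions
behind `gammabeam`, and what its synthetic-data experiments do and do not
establish about real recordings.

## Forward model

The head is a homogeneous conducting sphere (default center at MNI
(0, −20, 10) mm so occipital and fusiform coordinates fall inside, radius
85 mm). The field of a current dipole in a sphere has the Sarvas closed
form, which is exact for MEG regardless of the conductivity profile, and
in which the radial source component is magnetically silent. Each source
location therefore carries an N_ch × 2 lead field over an orthonormal
tangential basis; a 3-column (vector) beamformer would add a null
direction and destabilize the weights.

Sensors are point magnetometers on a Fibonacci spiral covering the upper
hemisphere of a 0.12 m shell, coil normals pointing radially inward — a
stand-in for a 248-channel whole-head magnetometer array; the count is
configurable and tests use 24–64 channels for speed.

Grid points within 20 mm of the sphere center are excluded
(`CENTER_EXCLUSION_MM`): lead fields vanish toward the center, where every
direction is radial, and the unit-gain constraint would blow up the weight
norms. Points a subject warp pushes outside the valid region keep their
slot with a zero lead field and are masked as degenerate, so every
subject's grid has identical point count and ordering — the requirement
for voxel-wise group statistics.

## Synthetic cohorts

The generator emulates the statistical structure of a two-cohort
face-viewing study; it is a model of *effects*, not of faces:

- **Epoch geometry.** 2000 ms epochs (−1000…+1000 ms) at 678.17 Hz, six
  emotion condition labels cycling over epochs; full-scale default 600
  epochs and 13 + 12 subjects, with a scaled-down preset (8 + 8 subjects,
  60 epochs) for fast runs.
- **Evoked transient:** a Gabor atom at 10 Hz centered 100 ms
  post-stimulus in right lateral occipital cortex, identical phase every
  epoch. Its `phase_jitter` parameter is the experimental dial for
  phase-locking tests.
- **Induced gamma:** narrowband bursts (carrier drawn uniformly in
  60 ± 10 Hz per epoch, fresh uniform phase per epoch) whose amplitude is
  the baseline level outside 150–650 ms and `gain ×` baseline inside it.
  The TD-like group gain centers on 2.5, the ASD-like group on 0.6 — so
  one cohort's induced gamma increases from baseline and the other's
  *decreases*, with a lognormal subject-level spread (σ = 0.15 in log
  space). Planted at right lateral occipital cortex (36, −86, 2), left
  occipital pole (−20, −92, 16) and right fusiform gyrus (32, −57, −3).
- **Beta desynchronization:** an ongoing 20 Hz component whose amplitude
  halves after 150 ms in both groups, producing the lower-band (3–30 Hz)
  power decreases both cohorts should show.
- **Background:** 1/f-shaped dipole noise at three non-visual sites plus
  white sensor noise (default 100 fT per sample). Source amplitudes
  (20–40 nAm) were chosen once so that the TD-like cohort's occipital
  gamma reaches significance at the pipeline's own permutation thresholds
  at the scaled-down cohort size; they are config-exposed.
- **Covariates.** AQ is Gaussian per group (ASD-like 38.62 ± 6.16,
  TD-like 12.33 ± 6.47, truncated to 0–50); a Gaussian copula couples the
  AQ draw to the subject's gamma-gain deviation at r = −0.5 within group.
  Age and full-scale IQ are group-matched Gaussians with no planted
  relation to gamma. Affines are identity plus a small random rigid
  perturbation (2° / 2 mm SD).

What passing tests on these cohorts shows: the pipeline recovers planted
spatial, spectral, temporal and between-group structure at realistic
amplitudes, and its permutation inference is calibrated on nulls. What it
does not show: robustness to real artifacts (eye movements, environmental
noise), realistic anatomy (BEM head models, cortical orientation
constraints), or inter-subject anatomical variability beyond rigid
perturbations.

## Preprocessing

DC offset removal is per epoch and channel. Band filtering is a
4th-order Butterworth applied forward–backward (`sosfiltfilt`, reflection
padding), chosen over FIR because zero-phase IIR keeps edge transients
short on 2 s epochs. The acquisition-chain filters (3 Hz high-pass,
200 Hz anti-aliasing low-pass) are considered part of the recording being
emulated, not re-applied in analysis. Artifact rejection is an automated
surrogate for manual inspection: an epoch is dropped when its worst
channel peak-to-peak amplitude exceeds a threshold (default 6× the median
per-epoch amplitude); survivors are never modified or reordered.

## Beamforming and volumetric statistics

- **Covariance**: band-filtered data pooled over the passive window and
  all three active windows, sample covariance plus 5% diagonal loading.
  The loading fraction trades spatial resolution against robustness at
  low epoch counts; 5% is a common default and the tests pass at 60
  epochs with 24–64 channels.
- **Windows**: passive −300…−100 ms; active 50–250, 250–450, 450–650 ms
  (200 ms each, long enough to resolve <10 Hz changes).
- **Depth normalization** (neural activity index) is omitted: the paired
  active-vs-passive contrast at a fixed voxel cancels the weight-norm
  scaling that depth bias would otherwise inject.
- **t→z conversion** per subject uses the probit of the t CDF, computed
  through the upper tail for numerical symmetry and clamped at |z| = 8
  (flagged). At synthetic SNRs many voxels saturate identically across
  subjects, which would make the group one-sample t 0/0; zero-variance
  nonzero-mean voxels instead receive a saturated statistic
  (±`T_SATURATION`), which preserves the ordering the permutation test
  needs. Under sign-flip nulls the all-same-sign patterns that reproduce
  saturation are rare (2 of 2ⁿ), so thresholds stay finite.
- **Group inference**: one-sample t across subject z-maps; null from
  whole-subject sign flips; threshold = (1−α) linear-interpolation
  quantile of the permutation maxima of |t| (two-sided). When all sign
  patterns fit in the permutation budget they are enumerated exactly.
- **Between groups**: unpaired t on subject-level mean band power per
  voxel (raw power, not z; the subject summary is config-switchable),
  separately for the active and the passive window, each thresholded by
  its own 300-permutation label-exchange maximum-statistic cutoff at
  p < .001; the reported map is t_active − t_passive masked at the higher
  cutoff. With 300 permutations the .999 quantile sits at the top of the
  sampled null — the conservative behavior this dual-cutoff procedure
  intends.
- **Degenerate voxels** (source-space matrix condition number > 1e8, or
  zero lead fields after warping) are masked, never silently zeroed.
  A zero statistic is never reported significant even when a degenerate
  null collapses the threshold to zero.

## Virtual electrodes and time-frequency analysis

VE weights are computed from the analytically evaluated lead field at the
affine-mapped coordinate (not the nearest grid point). The Stockwell
transform is implemented in the frequency domain: for analysis frequency
bin k, the voice is the inverse DFT of the spectrum shifted by k and
windowed by exp(−2π²m²/k²); the f = 0 voice is the signal mean. This
form satisfies the time-marginal identity (the time average of each voice
equals the DFT coefficient), which the tests verify to 1e-10.

"Induced" power is the average of per-epoch Stockwell power — i.e. total
power, the operational definition used here throughout; a variant that
subtracts the evoked average first exists behind a flag
(`subtract_evoked=True`) but is off by default, and the two differ.
"Evoked" power transforms the epoch-average trace. By Jensen's
inequality evoked ≤ induced bin-wise, which is a tested invariant.

First-level TF t-maps pair each (time, frequency) bin's per-epoch power
with the same epoch's mean power over the passive window at that
frequency (the baseline convention; bin-to-bin pairing within the
baseline is not meaningful because baseline bins are exchangeable).
Defaults: 1–2 Hz frequency steps over a configurable range (up to
100 Hz, well under Nyquist at 678.17 Hz), time axis decimated ×4 for
tractability. Group TF inference reuses the sign-flip engine over all
bins.

VE site selection supports three modes: the between-groups peak, the
coordinate-wise mean of significant within-group maxima snapped to the
grid (all significant gamma-band maxima across the analysis windows
contribute by default), and theory-driven coordinates passed through
unchanged; the default sites are the three canonical MNI coordinates
above.

## Statistics

Pooled and Welch t-tests accept raw samples or printed summaries (n,
mean, SD), so published group comparisons can be recomputed exactly.
Response-time trimming removes values beyond 2 SD of their cell mean in a
single pass, with group × emotion cells as the conservative reading of
"group mean" (per-group is a switch); RTs are log10-transformed before
testing. Backward elimination regresses the standardized response on
standardized predictors (statsmodels OLS), repeatedly dropping the
predictor with the largest p-value above 0.10 — a lenient removal rule
consistent with retaining marginal predictors around p ≈ .05–.10 —
and reports standardized betas, R² and F. Two-sided p-values throughout.

## Validation experiments and problem sizes

The experiments in `gammabeam.validation` (run by `scripts/acceptance.py`
and the acceptance tests) use deliberately desk-scale sizes:

- localization: 50 repeats, one planted induced source, 32 sensors, 30
  epochs, full 5 mm grid (~17k voxels);
- evoked/induced dissociation: 300 epochs at one VE, locked versus
  uniform per-epoch phase;
- permutation calibration: 200 null runs of 10 subject-maps × 50
  elements at 200 permutations (the family-wise error target band
  0.025–0.085 reflects binomial noise at 200 runs), plus exact
  equivalence of both engines with exhaustive enumeration at n = 8 and
  4 + 4;
- group-effect recovery: 8 + 8 subjects, 60 epochs, 64 sensors, gamma
  band, 250–450 ms window;
- regression recovery: 100 covariate-level cohorts (13 + 12 subjects),
  response = the simulator's ground-truth induced-gamma gain. With the
  lenient p > 0.10 removal rule, each nuisance predictor survives in
  ~10% of null fits, so the expected rate of "AQ only" final models is
  ≈ 0.9² ≈ 0.81 — the ≥ 0.80 requirement is met by construction but
  without margin, which is a property of the removal rule, not of the
  planted signal.

## Known limitations

- Spherical single-shell conductor and point magnetometers only; no BEM,
  gradiometers or sensor-noise covariance from empty-room data.
- No reference-channel environmental denoising or ocular ICA; artifact
  rejection is amplitude-based.
- Between-group inference on raw band power assumes comparable sensor
  noise across subjects (true by construction in simulation; real data
  may need the z-based switch).
- Anatomical labels are out of scope: peak tables report MNI coordinates
  with an empty region column.
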