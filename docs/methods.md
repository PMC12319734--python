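# Methods

`megfingerprint` implements, on synthetic data, a complete source-level
analysis for asking whether two MEG platforms — a wearable triaxial
optically-pumped-magnetometer (OPM) array and a cryogenic SQUID axial
gradiometer system — measure the same subject-specific brain responses
during a bilateral braille somatosensory task. This note documents the
generative model, the analysis chain, every numerical choice that was
genuinely open, and what the synthetic results do and do not show.

## Paradigm model

A trial begins (t = 0) at the end of an auditory attentional cue ("attend
left"/"attend right"). Five braille patterns are presented bilaterally at
t = 1.17 + k·1.37 s (k = 0..4), each lasting 0.37 s, followed by a 7 s
rest, giving a trial length of 14.02 s. Target patterns occupy exactly 20%
of stimulus slots, drawn without replacement so the default 80-trial run
always contains 80 targets and 320 non-targets. Cue sides are balanced
40/40 in seeded random order (the balance is a package choice; symmetric
attentional contrasts need it). The cue's duration is not part of the
timing model; a 2 s lead-in before each run's first trial stands in for it
so that pre-cue baselines exist. Button responses are bookkept but generate
no neural signal.

## Forward model

Both sensor arrays are laid out quasi-uniformly (Fibonacci lattice) on a
spherical cap around a 9 cm head sphere:

* **OPM**: 64 triaxial sites (192 channels) 6.5 mm off the scalp, sampled
  at 375 Hz, white sensor noise at 15 fT/√Hz;
* **SQUID**: 275 radial axial gradiometers (5 cm baseline) with the inner
  coil 20 mm off the scalp plus 29 distal reference magnetometers 0.4 m
  above the helmet, sampled at 600 Hz, 5 fT/√Hz.

The stand-off distances are package defaults (configurable); they are not
claimed as instrument values. The conductor is a homogeneous sphere with
the Sarvas closed-form dipole field. This preserves the property that
matters for the analysis — radial dipole moments are externally silent —
while remaining analytic and fast. Gradiometer gains are the difference of
the radial field projection at the two coils; a spatially uniform field
therefore produces exactly zero gradiometer output. The source space is a
cubic voxel grid (default 5 mm) inside an 8 cm sphere, shared by the whole
cohort (per-subject anatomy is out of scope).

## Subject model (the planted fingerprint)

Each subject draws, once, a parameter vector that all four of their
sessions share:

| parameter | default distribution | role |
|---|---|---|
| source positions (L/R) | (∓42, 10, 60) mm + N(0, 5 mm) per axis | pseudo-T image shape |
| patch extent σs | 8 ± 3–5 mm (3-dipole cluster) | image spread |
| moment orientation | tangential, ±0.6 rad | field pattern |
| beta peak | 22 ± 6 Hz (clipped to 13–30) | TFS position |
| beta bandwidth | 4 ± 1 Hz | TFS width |
| baseline beta amplitude | 8 nAm × lognormal(0.2) | SNR |
| ERD depth | 0.55 ± 0.2 | stimulus-locked dip |
| rebound profile (5 values) | 0.4 ± 0.25 with per-stimulus trend | post-stimulus peaks |
| evoked amplitude/latency/width | 15 nAm, 50 ± 8 ms, 12 ms | evoked responses |
| attentional depth | 0.2 ± 0.1 | cue-locked contralateral drop |

All spreads are multiplied by a single `between_subject_scale`; setting it
to 0 produces a cohort of statistically identical subjects, under which
identification must fall to the chance distribution. Session-to-session
variation is a 5% (default) multiplicative lognormal jitter on amplitudes
and depths; positions, peak frequency and orientation are treated as
stable anatomy. These effect sizes are package calibrations — the study
this emulates reports no quantitative between-subject effect sizes — and
were fixed once from physiological ranges.

Per hemisphere the dipole moment is
`m(t) = A·env(t)·carrier(t) + evoked(t)` where `carrier` is 4 Hz-wide
Gaussian noise at the subject's beta peak normalised to unit mean Hilbert
envelope, `env` multiplies in: an ERD plateau of depth d over
0.2–0.5 s after each stimulus onset (50 ms cosine ramps), a Gaussian
rebound bump (σ = 0.12 s) centred 0.9 s after onset with the per-stimulus
profile amplitude, and a tonic (1 − attentional depth) factor over
−0.8…1.0 s around the cue end in the hemisphere contralateral to the cued
hand. `evoked` is a biphasic difference-of-Gaussians pulse at each
stimulus onset plus a 0.6-scaled copy at stimulus offset. Sensor data are
the lead-field projection of the two 3-dipole clusters plus white noise at
the platform floor; optional injections (a spatially uniform interference
field; a reference-correlated drift) exist solely to exercise the
interference-suppression steps.

## Analysis chain

Order: channel screening → interference suppression → band-pass →
epoching → rejection → beamforming → spectral dynamics → statistics.

* **Channel screening** (OPM): Welch amplitude spectral density (2 s Hann
  segments, 50% overlap — unstated upstream, chosen for ≥1 Hz resolution),
  channels with a 60–80 Hz floor < 5 (not operational) or > 20 fT/√Hz
  (noisy) removed. The high cut is automated at exactly 20 where the
  original procedure was visual. SQUID screening sits behind a flag.
* **HFC** (OPM): least-squares projection of every time sample out of the
  3-dimensional space spanned by the channel orientation unit vectors; an
  exact projector, hence idempotent.
* **Reference gradiometry** (SQUID): each scalp channel minus its full
  record least-squares fit on the 29 references. This is a zeroth-order
  stand-in for synthetic third-order gradiometry; the vendor's balancing
  coefficients are proprietary and out of scope.
* **Filtering**: zero-phase Hamming-window FIR; transition width
  min(max(edge/4, 2 Hz), edge) per side, length 6.6 / (shortest
  transition) − 1 samples. Bands: 1–100 Hz (broadband), 13–30 Hz (beta),
  5–40 Hz (evoked).
* **Epoching**: 1.2 s stimulus-locked windows; trials where any channel
  exceeds 4 pT peak-to-peak are rejected. The rule is applied to the
  stimulus windows only: over a 15 s × 192-channel cue-locked window it
  would reject clean trials on noise extremes alone. Cue-locked epochs
  (−1…14 s) feed the spectral dynamics.
* **LCMV beamformer**: data covariance = average of the "early"
  (0.2–0.5 s) and "late" (0.75–1.05 s) window covariances, regularised by
  5% of its maximum singular value. Per voxel the orientation maximises
  unit-gain projected power; because the radial lead-field column of a
  spherical conductor is exactly silent, the search is restricted to the
  two dominant right-singular vectors of the voxel lead field (the
  standard rank-2 reduction) before minimising lᵀC⁻¹l. Voxels with a
  numerically silent lead field (the sphere centre) get zero weights.
* **Pseudo-T image**: (P_late − P_early) / (P_late + P_early) per voxel.
  The upstream description names a pseudo-T contrast without printing a
  formula; the symmetric normalisation bounds values in [−1, 1] and keeps
  images comparable across platforms with different absolute power — a
  requirement for cross-platform correlation. Zero-power voxels map to 0.
* **Minimum-norm evoked imaging**: Ĵ = Lᵀ(LLᵀ + λ²·tr(LLᵀ)/N·I)⁻¹m on the
  trial-averaged 5–40 Hz data, λ² = 1/9 (SNR = 3 convention), identity
  noise covariance, no depth weighting (all three unstated upstream).
  Per-voxel power is the quadrature sum over orientations, making it
  invariant to the orientation basis. The beamformer is deliberately not
  used here: bilateral simultaneous stimulation drives correlated evoked
  sources, which an LCMV filter suppresses (verified as a property test).
* **Virtual electrodes & TFS**: broadband (for TFS) and beta-band (for
  envelopes) weights from continuous-data covariance, same regularisation.
  TFS: overlapping 1 Hz-wide bands, 1.5–99.5 Hz in 0.5 Hz steps (the
  overlap step is a package choice), per-band per-trial Hilbert envelope
  with 0.5 s reflection padding, trial-averaged to A(t, f); baseline
  B(f) = mean of A over 12–13.5 s (rest period);
  R = (A − B)/B. Envelopes are averaged before baseline division.
* **Peak-voxel policy**: the virtual-electrode site per hemisphere is the
  pseudo-T argmax within the hemisphere (x-sign mask). By default the peak
  from a subject's first run on a platform is reused for the second run:
  at realistic noise the argmax can hop between neighbouring plateau
  voxels, and that selection jitter injects variance into within-subject
  comparisons that has nothing to do with the subject. The policy uses no
  cross-subject information; `peak_per_run=True` restores fully
  independent per-dataset peaks.
* **Cross-rate comparisons**: all compared timecourses and TFS matrices
  are resampled onto a shared 1 ms grid (linear interpolation) before
  correlation, since the platforms sample at 375 vs 600 Hz.

## Fingerprinting statistics

Dataset similarity = mean of Pearson r between pseudo-T images and Pearson
r between flattened TFS matrices (an evoked variant substitutes the
minimum-norm image and evoked power timecourse). Three N×N matrices:
within-OPM and within-SQUID compare run 1 of the row subject against run 2
of the column subject (one comparison per cell, so diagonal and
off-diagonal cells are statistically equivalent); cross-platform averages
the four OPM-run × SQUID-run comparisons. Identification is the row
maximum landing on the diagonal; ties count as misses. The permutation
test on mean(diag) − mean(offdiag) relabels the column-axis identities
(100,000 permutations at full scale), one-tailed with the +1 correction.
The chance-identifiability model simulates i.i.d. matrices; because row
maxima are independent with hit probability 1/N, the count is exactly
Binomial(N, 1/N), which serves as the analytic cross-check. The
group-level platform comparison correlates the two platforms'
group-average beta envelopes against a sham-mixing null (random 15/15
splits of the pooled 30 subject-average timecourses, 10,000 permutations,
two-tailed percentile). The attentional contrast is Δ = mean envelope
(attend-left) − (attend-right) over −0.8…1 s per subject and hemisphere,
with a two-sided Wilcoxon signed-rank test of left- against
right-hemisphere Δs (complete-case).

## Problem sizes

Defaults on `RunConfig` are the full study conditions: 15 subjects × 2
platforms × 2 runs, 80 trials/run, 5 mm grid, 0.5 Hz TFS band step,
10,000/100,000 permutations. The test-suite and examples use
`RunConfig.desk_scale()` — 20 trials/run, 12 mm grid, 1 Hz-step bands over
3.5–40.5 Hz, 10,000 matrix permutations — which runs the full 60-session
cohort in a few minutes on one CPU. Localisation-accuracy tests use the 5 mm grid with
single planted sources. The chance-identifiability computation always runs
at the full 100,000 simulations (~seconds).

## What the synthetic results show — and what they cannot

Passing tests demonstrate that the pipeline recovers planted structure:
source positions to within one voxel, ERD depths and rebound profiles from
the TFS, attentional contrasts of the planted sign, identification success
when subjects differ and chance-level identification when they do not, and
correctly calibrated permutation nulls. They cannot certify performance on
real recordings: the generator omits 1/f and line noise (available behind
flags but off by default), physiological artefacts, head movement,
per-subject anatomy, coregistration error, and any model mismatch between
a real head and a conducting sphere. Claims about real OPM/SQUID
equivalence rest on the original study's data, not on this package.

## Known limitations

* The spherical conductor makes deep and midline sources poorly
  constrained (radial silence removes one orientation dimension).
* Reference gradiometry is zeroth-order; it under-suppresses gradients of
  interference fields.
* The sham-mixing group null is sensitive to platform SNR asymmetry: with
  very low envelope noise, small systematic platform differences (e.g.
  envelope-floor compression at the noisier platform) can push the
  observed correlation into the null's tail even when the underlying
  neural signal is identical.
* Desk-scale trial counts make the TFS feature noisier than at full scale;
  the identification margin there is smaller than the study-scale model
  would give.
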