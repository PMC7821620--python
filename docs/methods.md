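# Methods

`genrefmri` implements a voxel-wise encoding/decoding analysis of music
genre representation and exercises it end to end on synthetic stimuli and
simulated voxel responses with known ground truth.  This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic studies do and do not show about real data.

## The analysis

**Encoding.** Cortical responses are modeled per voxel as a linear
function of stimulus features carrying hemodynamic delays,

    R̂ = F_E · W_E,      F_E : T × 5N,   W_E : 5N × V,

where `F_E` concatenates five delayed copies of the T × N feature matrix
at lags of 1.5, 3, 4.5, 6 and 7.5 s (TR = 1.5 s, so TR lags 1–5; lags are
zero-padded at run starts and never cross run boundaries).  `W_E` is
estimated by ridge regression, `W = (FᵀF + λI)⁻¹FᵀR`, computed through
an SVD so that a whole λ grid and per-voxel λ values are cheap.  λ is
selected by random resampling: 10 draws of an 80/20 split, fitting on the
80 %, scoring by Pearson r on the 20 %, choosing per voxel the λ with the
best mean validation r.  Splits draw contiguous chunks (clip-length
blocks by default) rather than single TRs, to respect temporal
autocorrelation.  Prediction accuracy on the repetition-averaged test set
is Pearson r per voxel; p-values come from the one-sided t-transform of r
(df = T_test − 2; accuracy is a positive-tail claim) with
Benjamini–Hochberg FDR control across voxels.  A permutation-free,
closed-form p is adequate here because the test rows are
repetition-averaged and modeled as exchangeable.

**ROI.** The genre-representing region of interest repeats fit/evaluate
over 50 resampled 80/20 splits (at the λ already selected for the
genre-label model) and keeps voxels significant in more than 80 % of
splits.

**Voice nuisance.** The genre-label model can be refitted on the
column-concatenated [genre | voice] delayed features; at test the voice
columns and their weights are dropped, regressing the voice confound out
of the genre prediction.  Voice feature column order is fixed as
[voice, no-voice].

**Genre maps.** Genre-label weights are averaged over the five delay
blocks to a 10 × V map per subject; maps are concatenated across subjects
along the voxel axis and decomposed by PCA over the 10-dimensional genre
axis (voxels as observations, centered, unscaled since weights share
units).  Loadings place genres in the representational space (PC1/PC2
give the 2-D embedding; min-max-normalized PC1–3 give RGB colors),
scores place voxels in the same space (normalized per subject).
Component signs are fixed by making each loading column's
largest-magnitude entry positive, so plots are deterministic.

**Feature–brain similarity (FBS).** For an acoustic model with an
interpretable D-dimensional feature space, a voxel's tuning profile is
its delay-averaged weight vector, back-projected through the stored PCA
basis (`W_D = basis · W_K`) when the model was fitted on reduced
features.  The reference profile of genre g is the mean feature vector
over that genre's training TRs (equivalently clip means, since all clips
have equal TR counts).  FBS(v, g) is the Pearson correlation between the
two profiles — computed on the full D-dimensional profiles; collapsing to
the 10 × 10 (Ω × ω) matrix by averaging the 20 frequency ranges is for
visualization only.  The FBS map is compared with the categorical
genre-weight map by per-genre correlation across ROI voxels, and models
are compared on those 10 paired values with an exact Wilcoxon signed-rank
test (all 2ⁿ sign assignments enumerated, so the p-value stays exact
under rank ties; two-sided by default).

**Decoding.** Genre labels are decoded by ridge regression of the one-hot
label matrix on delay-embedded ROI responses — deliberately a linear
regression, not a categorical classifier, to mirror the encoding
analysis.  Because hemodynamics delay the measurement, the response
embedding uses *future* lags: G(t) is predicted from R(t+1) … R(t+5).
(The mirror-image past-lag embedding decodes at chance on simulated
data; the future-lag reading recovers it, and is the only physically
sensible one.)  Each test TR gets the argmax genre of the decoded label
matrix; each clip gets the modal label over its TRs (majority voting).
Ties in both argmax and voting break toward the lowest genre index, for
reproducibility.  Confusion matrices are column-normalized percentages
(columns = correct genre, rows = classified genre) and are compared
across sessions by Spearman correlation over all 100 cells (off-diagonal
option available).

## Acoustic feature models

All extractors work at TR resolution from 22,050-Hz mono waveforms and
are restricted to 100–8,000 Hz.

* **Cochlear (128 features).** Power spectrogram with 25-ms Hann windows
  and 10-ms hop, weighted by 4th-order gammatone magnitude responses on
  128 channels, TR-averaged.  Channel spacing defaults to *logarithmic*
  rather than ERB: the MTF scale axis Ω is in cycles/octave, which is
  exact only on a log-frequency grid (ERB spacing is available as an
  option).
* **MTF (2000 raw features).** The cochleogram is convolved with
  quadrature pairs of 2-D Gabor filters at 10 scales
  Ω ∈ {0.35 … 8.0} cyc/oct and 10 rates ω ∈ {2.8 … 64.0} Hz, for upward
  and downward sweeps.  Filter geometry: Gaussian envelopes with
  σ_t = 0.5/ω s and σ_x = 2/Ω octaves (the sharper spectral Q is what
  makes the half-octave-spaced scale grid resolvable through
  cochlear-channel smearing), truncation at 2.5 σ, impulse response
  capped at 1 s, kernels L2-normalized.  The kernels are rank-1
  separable, so the implementation convolves once along frequency per
  scale and reuses it across rates (FFT-based); it matches a direct 2-D
  quadrature convolution to 1e-8.  Local energies (sum of squared
  quadrature outputs) are log-compressed with a floor of 1e-8 × the
  per-clip maximum energy (silence safety), averaged within TRs, within
  20 non-overlapping log-spaced frequency ranges, and across the two
  sweep directions: 20 × 10 × 10 features ordered (frequency, Ω, ω).
  Note the physical limits at this resolution: the 10-ms hop puts the
  45.3/64-Hz rate filters at/above the frame Nyquist, and the 25-ms
  window smears ripple densities much above ~1 cyc/oct.
* **MTF reduction.** PCA fitted on training stimuli only, keeping the
  smallest K reaching 99 % variance; the basis and column means are
  frozen for projecting test stimuli and for back-projecting weights
  (leakage prevention).  On real stimulus sets K lands near a few
  hundred; K is data-dependent and not asserted.
* **MFCC (12 features).** Own mel filterbank (40 triangles, 100–8,000 Hz)
  on the 25-ms/10-ms power spectrogram, log, orthonormal DCT-II,
  coefficients 1–12 (the 0th energy term is dropped), TR-averaged.
* **MIRT-style descriptors (24 features).** Standard closed-form
  definitions: RMS loudness; zero-crossing rate, high/low energy ratio
  (split at 1.5 kHz), spectral centroid, 85 % roll-off, normalized
  spectral Shannon entropy, flatness, Plomp–Levelt roughness over the 12
  strongest spectral peaks, spread, flux, and sub-band flux on 9
  log-spaced bands (25-ms frames, 50 % overlap); pulse clarity (max
  normalized onset-envelope autocorrelation in the 40–200 bpm lag range),
  fluctuation centroid and entropy (spectrum of band-envelope
  fluctuations ≤ 10 Hz), mode and key clarity (Krumhansl–Schmuckler
  chroma-profile correlations: clarity = best correlation, mode =
  best-major − best-minor) on 3-s frames with 33 % overlap.  These are
  frozen definitions in the spirit of the usual MIR toolboxes; bit-exact
  equivalence with any particular toolbox is a non-goal, and the tests
  check qualitative properties (silence, noise-vs-tone flatness, shapes).

## Synthetic data

The generator's job is controllable ground truth, not perceptual realism.

* **Archetypes.** A synthetic "genre" is a modulation archetype: carrier
  weights over the 128 cochlear channels (smoothed log-normal), a rate
  profile and a scale profile (Gaussian bumps with floor over the 10
  filter tunings, mutually distinct modes, pairwise cosine similarity of
  concatenated profiles < 0.95), and a voice probability (default
  pattern: even genre ids ≈ 0.9, odd ≈ 0.1, emulating a voice/genre
  confound).  Default profile modes are restricted to rates ≤ 22.6 Hz
  and scales ≤ 0.71 cyc/oct — the region the analysis chain can resolve
  at the 10-ms/25-ms cochleogram resolution (see above); outside it no
  generator could satisfy the fidelity requirement.
* **Clips.** Seeded moving-ripple tone clouds: 48 tones on a log-spaced
  carrier grid weighted by the carrier profile, each amplitude-modulated
  by a drifting ripple `1 + sin(2π(±ωt + Ωx))` whose dominant component
  sits exactly at the archetype's profile modes (a weaker second
  component is drawn from the profiles); a formant-like harmonic stack
  with 5-Hz vibrato is added to voiced clips.  Clips get 2-s raised-
  cosine fades and exact RMS normalization (target 0.1).  Fidelity: over
  seeded clips, the dominant extracted (Ω, ω) filter — the max-marginal
  argmax of the collapsed 10 × 10 matrix, which is robust to the
  broadband low-Ω background gradient — matches the archetype modes in
  ≥ 90 % of clips.
* **Scanner noise.** A seeded pink-noise generator stands in for a
  recorded scanner-noise file; mixing scales the noise to a requested RMS
  relative to the clip (0.2 / 0.5 / 1.0 are the conventional levels) with
  no re-normalization afterward.
* **Brains.** Tuned voxels get unit-norm tuning rows that are smooth
  bumps in (frequency range, Ω, ω) space centered near their assigned
  archetype's modes (or 1-D index bumps for non-MTF spaces); untuned
  voxels are exactly zero.  Responses are
  `R = F_delayed · W_true + ε`, with `W_true` stacking tuning × a 5-tap
  delay kernel (default [0.1, 0.25, 0.3, 0.25, 0.1]) and ε i.i.d.
  Gaussian per voxel (AR(1) optional).  `noise_sd` is calibrated as
  ‖tuning‖·‖kernel‖/√SNR, which equals the requested SNR when feature
  columns are standardized and weakly correlated — the pipeline z-scores
  features before simulating, so the assumption holds approximately.

## Study conditions and problem sizes

The full design — 540 clips (54/genre), 18 runs (12 train / 6 test), 40
clips/run, 15-s clips, 15-s dummy (excluded from analysis rows), 4 test
repetitions, TR 1.5 s — is reproduced exactly at the schedule level
(480/60 train/test clips, 4,800 training rows, 600 averaged test rows,
410 volumes/run) and used as-is wherever audio is not needed (structural
checks, label-space decoding studies).  Audio-dependent studies run at a
reduced scale chosen to keep a single-CPU session comfortable: 10
archetypes, 2–3 training + 1 test clip per genre, 6-s clips, 40–100
simulated voxels, SNR 3–5, a 4-point λ grid with 3–5 resamples, and
10–20 ROI resamples.  The model-recovery study (responses generated from
raw-MTF tuning; cochlear vs MTF vs MFCC compared by mean FBS/genre-map
correspondence) uses 20 seeded repetitions of that reduced pipeline.

What passing shows — and does not.  The synthetic studies demonstrate
internal consistency: the estimator recovers planted weights, FDR holds
under the null, the feature space that generated the responses wins the
FBS comparison, and decoding recovers planted genre codes.  They do not
demonstrate that real cortical responses are MTF-tuned, and reported
real-data quantities that depend on measured brains (mean ROI accuracies,
the ~0.73 FBS correspondence, per-genre classification rates) are outside
what synthetic data can certify.

## Numerical choices and degenerate inputs

* Ridge via thin SVD; λ = 0 allowed only for full-rank designs, otherwise
  a LinAlgError is raised.  Per-voxel λ vectors are applied by rescaling
  singular values per target.
* Detrending: running median with a 240-s window, edge-truncated (the
  window shrinks at run edges); per run and per voxel, followed by
  z-scoring.  Zero-variance voxels are left all-zero and flagged rather
  than producing NaNs.
* Pearson r with a zero-variance operand is defined as 0 with p = 1
  (never significant); FBS rows with zero variance are NaN ("missing").
* λ-selection ties choose the smallest λ; argmax/vote ties choose the
  lowest index.
* Exact Wilcoxon enumeration is limited to n ≤ 20 pairs (here n = 10).
* All randomness flows through `numpy.random.default_rng` seeds; every
  operation is bit-reproducible for a fixed seed.

## Known limitations

* No spatial voxel structure, head motion, or physiological noise; the
  noise model is Gaussian (optionally AR(1)), matching the Pearson-r
  evaluation but not real fMRI noise spectra.
* MIRT descriptors are frozen textbook definitions, not a toolbox
  re-implementation; only qualitative behavior is guaranteed.
* The high-rate (≥ 45 Hz) modulation filters are constructed faithfully
  but are unreliable at the 10-ms frame rate; analyses of real audio at
  these rates would need a finer cochleogram hop.
* Cross-subject aggregation is implemented (map concatenation), but the
  synthetic studies use single simulated sessions.
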