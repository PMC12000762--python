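# Methods

## The call model

The unit of analysis is one territorial syllable: four tonal notes
("ge-ga-ga-ge") separated by three short gaps, total duration 1.09–1.50 s.
Each note is synthesised as a harmonic stack of up to three partials — the
fundamental F0 (amplitude 1), the second partial at 2·F0 (relative
amplitude `harmonic_weights`), and a third partial at 3·F0
(`harmonic3_weights`) — with raised-cosine onset/offset ramps (15 ms) and a
linear pitch contour f(t) = F0·(1 + slope·(t/d − ½)). Fundamentals are
constrained to the observed 600–1110 Hz band.

Individuality enters as a two-level hierarchy. An individual's parameter
means are drawn once from the population distribution; each call then
perturbs them by a within-individual coefficient of variation (CV). The
individual-level dimensions are:

| dimension | among-individual spread | within-individual CV |
|---|---|---|
| note durations (s) | CV 0.20–0.30 per note | 0.035–0.06 |
| note gaps (s) | CV 0.30–0.40 | 0.08–0.10 |
| shared pitch factor | CV 0.18 (all notes jointly) | — |
| per-note F0 offsets | CV 0.08 | 0.018 |
| pitch contour slope | SD 0.28 (fraction of F0) | SD 0.015 |
| note emphasis (rel. amplitude) | CV 0.30 | 0.06 |
| 2nd-partial weight (mean 1.2) | CV 0.30 | **0.45** |
| 3rd-partial weight (mean 0.45) | CV 0.50 | 0.15 |

The large *within*-individual CV of the second-partial weight is
deliberate: it scrambles which partial is strongest from call to call
(emulating distance-dependent high-frequency attenuation in the field), so
the measured peak frequency (Fpeak) is a poor individual marker — its PIC
sits at or below 1 and the selection stage drops it, while durations, gaps
and the fundamental/harmonic frequencies remain strongly individual
(PIC ≫ 1). The shared pitch factor plus independent per-note offsets mean
that two individuals collide acoustically only if they match in overall
pitch *and* in all four notes' offsets *and* in contour/emphasis/timbre —
keeping the between-individual similarity distribution light-tailed, as
observed in real corpora.

Rejection sampling enforces physical plausibility: totals inside
[1.09, 1.50] s, fundamentals inside [600, 1110] Hz, gaps above 30 ms
(shorter silences cannot be resolved at the 11.6 ms analysis window), and
band visibility — every note must have a usable partial near the 850–1650
Hz detection band, as every measured real call does (that is how the band
was chosen). More than 1000 consecutive rejections raises an error instead
of silently biasing the population.

Soundscapes place calls at Poisson onsets (with a 3 s refractory interval,
since a bird cannot overlap its own calls), attenuate amplitude as
`reference_distance/d` with a hard detection radius (150 m default), and
log complete ground truth. Survey scenarios add a recorder grid (150 m
spacing), uniform home centres, per-recorder assignments (deliberately
producing pseudo-replication when the detection radius exceeds the
spacing), and a strip transect.

### What the generator does not emulate

Reverberation and frequency-dependent atmospheric absorption; overlapping
heterospecific choruses (confounders are simple tones/chirps); amplitude
modulation and noisy/broadband call components; bird movement during a
bout; recorder clock drift or gain differences. Passing tests therefore
show that the *analysis chain* is correct and well-calibrated under the
stated acoustic model, not that the detector or SPCC would reach the same
rates on arbitrary field recordings.

## Analysis resolution

All stages share one spectrogram configuration: 22,050 Hz mono audio,
256-sample Hamming window with no zero-padding, 75% overlap. The 64-sample
hop gives exactly 64/22050 ≈ 2.9025 ms per column and 22050/256 ≈ 86.13 Hz
per row. Columns are labelled by frame-centre time (the 128-sample offset
matters when comparing measured note boundaries with ground truth). Linear
magnitude is used throughout; dB conversion exists only for display.

## Detection

In-band (850–1650 Hz) column energy is thresholded at
max(median + 3·MAD, median + 0.02·(max − median)). The MAD term adapts to
the noise floor; the dynamic-range term keeps noise flicker from chaining
into overlong candidates (via the 0.2 s gap-merge rule) on recordings
dominated by loud calls. Above-threshold runs separated by gaps ≤ 0.2 s
merge into one candidate; candidates must be 1.0–2.0 s long. Matching
against truth is greedy one-to-one with interval IoU ≥ 0.5 (manual
verification has no numeric criterion; 0.5 is the conventional choice).
Detection triage mirrors a recogniser workflow: the band-limited patch is
resampled to a fixed 12×32 grid, unit-normalised, 2-D DCT-II transformed,
and the first 24 zig-zag coefficients are clustered (k-centroid, Lloyd);
scores are range-normalised reciprocals of the distance to the cluster
centre, with ε = 10⁻⁹ × median distance guarding division by zero.

## Measurement

Within a detection, notes are segmented on the in-band *amplitude*
envelope (square root of band energy — robust to the ~10× level range
between emphasised and quiet notes) at 10% of its maximum; more than four
segments are merged at the shortest gaps, fewer than four raise
`MeasurementFailure` and the call is excluded rather than imputed, mirroring
the manual use of only clean spectrograms. Per-note spectra are the mean
magnitude over the note's columns. Ffoun is the lowest spectral peak
≥ 400 Hz above 10% of the spectrum maximum; Fhar the strongest peak within
2·Ffoun ± 1.5·df; Fpeak the global maximum. All peak frequencies are
refined to sub-bin precision by parabolic interpolation — without it the
86 Hz grid quantises away most of the among-individual pitch variance.
Note that Ttotal is by construction the exact sum of the seven other
temporal variables, so the 16-variable set is collinear and the DFA's
ridge term is always active (a warning says so).

## PIC and DFA

CVw is the mean of per-individual CVs (sample SD, n−1, over mean); CVa is
the CV of the per-individual means — the standard convention, under which
the no-individuality null sits near 1/√(calls per individual), not at 1.
PIC = CVa/CVw; variables with PIC > 1 are retained, minus a configurable
exclusion set defaulting to Fpeak1–4 (threshold-only selection cannot
reproduce the practice of dropping peak frequency even at PIC ≈ 1). The
DFA uses equal priors (training is balanced by design), class mean
vectors, and a pooled within-class covariance regularised by
ridge·trace(S)/p with ridge = 10⁻⁶; classification is minimum Mahalanobis
distance, with posteriors softmax(−d²/2).

## SPCC

The similarity of two calls is the maximum zero-mean normalised 2-D
correlation coefficient between their magnitude spectrograms over all time
lags, computed on the 400–3600 Hz rows (the band below 400 Hz is removed as
noise; rows are zeroed, not dropped, elsewhere so indices stay aligned).
Frequency-row shifts are searched within a 50 Hz deviation — which at the
86 Hz row spacing admits only the zero shift; the generic bounded search
activates at finer resolutions. A lag is admissible only if at least 95%
of the shorter call overlaps: SPCC compares whole syllables, and smaller
minimum overlaps let a single coincidentally matching note dominate a
short overlap window and inflate between-individual similarity. The
all-pairs matrix computes each of the n(n−1)/2 pairs once via a batch FFT
path (per-call transforms are reused across pairings; cross-terms by
frequency-domain products, normalisation terms by cumulative sums).

## Hopkins and affinity propagation

For clusterability, each call is embedded as its row of similarities;
m = max(5, ⌈0.1·n⌉) sampled calls and m uniform points in the
per-dimension bounding box are compared through nearest-neighbour
distances, H = Σu/(Σu + Σw); H ≈ 0.5 indicates no structure, H → 1 strong
clustering. (A 1−s dissimilarity embedding is available via the raw
matrix; the row embedding is the default.)

Affinity propagation follows the standard message-passing updates:
r(i,k) ← s(i,k) − max_{k′≠k}[a(i,k′) + s(i,k′)] and
a(i,k) ← min(0, r(k,k) + Σ_{i′∉{i,k}} max(0, r(i′,k))), damped at 0.9,
preference defaulting to the median off-diagonal similarity (the common
default; the cluster count is sensitive to it, so it is exposed). A tiny
seeded symmetric noise (10⁻¹² of the similarity range) breaks exact ties.
Convergence is a stable exemplar set for 100 iterations (cap 1000); if no
exemplar emerges the result degrades to a single cluster at the point of
maximum total similarity, flagged not-converged. Clustering accuracy maps
each cluster to its majority true label. Wild-cluster validation samples
calls and requires both higher mean similarity inside than outside the
cluster and all same-cluster recording locations within one home-range
diameter, 2·√(11 ha/π) ≈ 374 m; singleton clusters pass vacuously and are
flagged.

## Survey arithmetic

The strip-transect estimate is N = n_observed × total_area/survey_area
(linear in both count and area); repeated daily counts keep the maximum;
group sizes are summarised as mean ± SE with range. Estimate comparison
reports the percent difference under both denominators, since with a
clustering count of 205 and a transect extrapolation of 233.5 the two
conventions give +13.9% and −12.2% and practice varies on which is quoted.
Population estimates are rounded to the nearest integer with the raw value
retained.

## Calibration of the study conditions

The generator's defaults are calibrated so that a curated pasture-style
corpus (34 individuals × 5 clear calls at 20 dB SNR — "clear" meaning the
call is detected as exactly one candidate and segments into four notes,
mirroring manual curation) shows strong and realistic separability:
same-individual SPCC ≈ 0.79 ± 0.10, different-individual ≈ 0.17 ± 0.14,
K–S D ≈ 0.98, Hopkins ≈ 0.90. A three-partial harmonic stack at a fixed
86 Hz resolution cannot simultaneously centre the between-individual
similarity at the mid-0.3s with light tails — between-pairs split into a
pitch-disjoint mass near 0.1 and a pitch-colliding tail — so calibration
prioritised the features that carry the method's behaviour: the
within/between ordering, the near-disjoint similarity distributions
(D ≥ 0.9), and a collision tail small enough that the number of
individuals is recoverable. Under these frozen conditions affinity
propagation with the median-preference rule recovers the true count of 34
in the large majority of seeded replicates, and the DFA identifies
held-out calls at ≥ 90%.

## Problem sizes and determinism

The test suite and acceptance script use 34-individual corpora with 5
calls (clustering) or 15 calls (PIC/DFA) per individual, 20 replicates for
the cluster-count study, 50 replicates for Hopkins-null and
AP-versus-brute-force checks, and 200 replicates for the transect-bias
check — sizes at which every stage's statistical claim is testable in
minutes on one CPU. All randomness flows through explicitly passed
`numpy.random.Generator` objects seeded from a single root seed; a config
plus seed reproduces every report byte for byte.

## Known limitations

- The synthetic call is far cleaner than field audio; absolute precision/
  recall/accuracy values are properties of the simulation, not predictions
  for any field deployment.
- SPCC at the fixed resolution is insensitive to pitch differences well
  below one 86 Hz row unless they are carried by contours or harmonics.
- The detector's length gate rejects overlapping same-band calls merged
  across the 0.2 s gap rule; dense choruses need source separation that is
  out of scope.
- The transect estimator assumes uniform density and complete detection
  inside the strip; the simulation satisfies both by construction.
- Affinity propagation's cluster count depends on the preference rule;
  the median default is a convention, not an optimum.
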