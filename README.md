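# callcensus

Acoustic individual identification and population estimation from
territorial calls.

Passive acoustic monitoring can census a bird population only if calls can
be attributed to individuals: the same male is recorded by several nearby
autonomous recorders, so raw detection counts are inflated by
pseudo-replication. `callcensus` implements a complete, testable version of
the workflow that solves this for a loud, stereotyped territorial call — a
four-note "ge-ga-ga-ge" syllable of ~1.1–1.5 s with fundamentals around
600–1100 Hz, as given by male red junglefowl (*Gallus gallus*):

1. **Detection** — band-limited energy detection on a fixed-resolution
   magnitude spectrogram (Hamming window, 75% overlap, 2.9025 ms columns):
   in-band (850–1650 Hz) energy above an adaptive threshold, syllable runs
   merged across gaps ≤ 0.2 s, candidates kept if 1.0–2.0 s long; DCT
   features, k-centroid clustering and reciprocal-distance scores for
   triage; precision = TP/(TP+FP) and recall = TP/(TP+FN) against ground
   truth.
2. **Measurement** — 20 variables per call: note durations (Tdur1–4), gap
   lengths (Tint1–3), total duration (Ttotal), and per-note peak,
   fundamental and first-harmonic frequencies (Fpeak, Ffoun, Fhar 1–4).
3. **Individuality** — coefficients of variation within (CVw) and among
   (CVa) individuals; the potential individual coding PIC = CVa/CVw
   selects variables (PIC > 1); discriminant function analysis (class
   means under a pooled within-class covariance) classifies calls to known
   individuals.
4. **Similarity & clustering** — spectrogram cross-correlation (SPCC):
   the maximum zero-mean normalised 2-D correlation over time lags and
   bounded frequency shifts, after removing the band below 400 Hz; the
   Hopkins statistic for clusterability; affinity propagation (Frey–Dueck
   message passing: responsibilities r(i,k) and availabilities a(i,k)) on
   the similarity matrix — the number of exemplars is the estimated number
   of calling individuals; spatial validation against a ~11 ha home range.
5. **Survey arithmetic** — strip-transect extrapolation
   N = n_observed × total_area / survey_area, group statistics, and
   side-by-side comparison of the transect and clustering estimates.

Because field recordings cannot ship with a library, the package includes a
first-class synthetic-data generator (`callcensus.synth`) producing
junglefowl-like calls, soundscapes and survey scenarios with known ground
truth, so every stage is testable end to end.

## Worked example

`examples/04_count_individuals.py` synthesises 12 individuals with 5 clear
calls each, builds the SPCC matrix and counts individuals without using
the labels:

```text
60 calls, 1770 SPCC pairs
same-individual similarity  0.78 +/- 0.11
diff-individual similarity  0.25 +/- 0.10
K-S test: D = 0.97, p = 2.7e-174
Hopkins statistic = 0.84 (clusterable)
affinity propagation: 12 clusters (true 12), converged=True
majority-label accuracy: 59/60 = 98.3%
```

Same-individual call pairs correlate far above different-individual pairs
(the K–S statistic D near 1 says the two similarity distributions barely
overlap), the Hopkins statistic above 0.5 confirms real cluster structure,
and affinity propagation recovers the true number of calling individuals —
the quantity a survey needs when birds are unmarked. The other examples
cover call synthesis, detection/measurement, PIC + DFA, the transect
arithmetic, and the one-config end-to-end pipeline (`run_pipeline`).

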