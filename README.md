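# hrvstress

Nonlinear heart-rate-variability analysis and stress detection for paired
5-minute RR-interval recordings (one rest and one stress record per
subject).

The package implements:

* **RR ingestion and preprocessing** (`hrvstress.rr_io`) — plain-text RR
  readers (two-column CSV with beat labels, or single-column), filtering to
  normal-to-normal (NN) intervals, and the 90% NN/RR reliability criterion.
* **13 nonlinear features** (`hrvstress.features`) — Poincaré SD1/SD2;
  approximate entropy at three tolerances (0.2·SDNN, the entropy-maximising
  tolerance on a grid over (0.1·SDNN, 0.9·SDNN), and Chon's data-driven
  coefficient); correlation dimension (m = 10); detrended fluctuation
  slopes α1 (boxes 4–16) and α2 (16–64); recurrence-plot REC, DET, ShEn,
  mean and maximal diagonal line length (m = 10, τ = 1).
* **Paired statistics** (`hrvstress.stats`) — per-session descriptives,
  stress-minus-rest differences, and a Wilcoxon signed-rank test (exact
  sign enumeration up to n = 12, tie/continuity-corrected normal
  approximation above).
* **Classification** (`hrvstress.classify`) — two-class LDA (equal priors,
  midpoint boundary, `score > 0 ⇒ stress`), ACC/SEN/SPE/PPV/NPV, subject-wise
  k-fold cross-validation, exhaustive search over all 2¹³ = 8192 feature
  subsets (8191 evaluated; the empty subset is enumerated only), and
  human-readable final rules (single-feature thresholds or a linear form).
* **Synthetic cohorts** (`hrvstress.synth`) — a deterministic, seedable
  generator of paired rest/stress records (two oscillatory components plus
  AR(1) noise, per-subject jitter, optional ectopic beats) calibrated so the
  stress session shows reduced long-term variability, reduced
  complexity/entropy and increased recurrence relative to rest.
* **Pipeline** (`hrvstress.pipeline` / CLI) — end-to-end study runs
  producing per-record features, statistics tables and classification
  tables with full provenance.

## Command-line usage

Run the whole study on a synthetic cohort (42 subjects):

```sh
hrvstress run --synthetic --subjects 42 --seed 1 --out study_out/
```

or on a directory of `<subject>_<session>.csv` RR files (seconds by
default, `--ms` for milliseconds):

```sh
hrvstress run --input-dir cohort_dir/ --out study_out/
```

The output bundle contains `features.csv` (13 features per record),
`session_stats.csv` (per-session descriptives), `differences.csv`
(stress−rest descriptives + Wilcoxon p), `classification.csv`
(single-feature and best-subset cross-validated performance with rule
text), `rules.json`, and a provenance log.

Generate a cohort as files:

```sh
hrvsynth --subjects 42 --seed 1 --out cohort_dir/
```

Classify from an existing feature table:

```sh
stressclf eval features.csv --subset SD1,SD2,En02 --folds 10 --seed 17
stressclf search features.csv --folds 10 --seed 17 --out ranking.csv
```

## Conventions worth knowing

* All internal units are seconds; standard deviations feeding tolerance
  thresholds (SDNN, SDDS, SD1, SD2) use the population (divide-by-N)
  convention.
* The recurrence-plot radius defaults to √m·SDNN (`rp_radius_mode=sqrt_m`);
  the literal m·SDNN variant is available as `rp_radius_mode=literal` and
  the mode used is recorded in all outputs.
* Chon's tolerance formula yields a coefficient that multiplies SDNN, like
  the fixed 0.2 coefficient.
* REC and DET are reported as fractions in [0, 1]; ShEn uses natural
  logarithm of diagonal line-length fractions, negated.
* A cross-validation score of exactly 0 classifies as rest (strict `>`).
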