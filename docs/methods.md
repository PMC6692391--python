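# Methods

This note documents the models and procedures implemented in `somnotypes`,
the defaults chosen where the upstream descriptions left the design open, and
what the synthetic-data generators do and do not emulate.

## Accelerometer sleep detection (`somnotypes.actigraphy`)

The detector operates on uniformly sampled epoch series (default 5-s epochs)
of the wrist z-angle — the dorsal–ventral tilt, computed from raw triaxial
acceleration as `atan2(az, sqrt(ax² + ay²))` in degrees when native z-angle
input is not supplied — plus a nonnegative activity magnitude.

Per noon-to-noon analysis day:

1. **Change metric.** The per-epoch absolute z-angle change |Δz| (leading
   value repeated) is smoothed with a centered rolling median over 5 minutes.
   The window is forced to an odd epoch count so it is exactly symmetric;
   edge windows are truncated to the available epochs. Because only angle
   *changes* enter, the detector is invariant to constant z-angle offsets.
2. **Movement threshold.** Per analysis day (a per-recording option exists),
   the threshold is the 10th percentile of the rolled series — linear
   interpolation between order statistics — multiplied by 15. The bare
   percentile (`threshold_multiplier=1`) is selectable, but it cannot work
   when a third of the day is sleep: the 10th percentile of the daily rolled
   distribution then falls *inside* the sleep portion, so the non-movement
   mask can never contain a contiguous 30-minute run. The ×15 scaling follows
   the open-source heuristic this detector descends from and is what makes
   the planted-window recovery guarantee (below) attainable. The mask marks
   an epoch non-movement when the rolled value is ≤ the threshold
   (non-strict, so the degenerate noise-free day with threshold exactly 0
   still detects).
3. **Bouts, blocks, SPT-window.** Maximal non-movement runs of ≥ 30 min are
   inactivity bouts; bouts separated by gaps strictly under 60 min merge
   transitively into blocks; the longest block (ties → earliest onset) is the
   sleep-period-time (SPT) window, onset to wake. A day with no block has no
   SPT and is excluded from summaries.
4. **Sleep episodes.** Inside the SPT-window, epochs with the rolled change
   metric < 5° are posture-stable; maximal stable runs of ≥ 5 min are sleep
   episodes. "Separated by wakefulness" is operationalised as ≥ 1 non-stable
   epoch (5 s at the default epoch length). The same rolled metric serves
   both stages; this is an interpretive choice — the text defines episode
   stability and movement thresholding in nearly identical terms.
5. **Metrics.** Sleep duration = Σ episode lengths; efficiency = sleep
   duration / SPT duration; number of sleep bouts = episode count; sleep
   midpoint = (onset + wake)/2 in minutes from the day start (noon); L5/M10 =
   midpoints of the least-active 5-h / most-active 10-h moving-sum windows
   (exhaustive over all starts, ties → earliest), L5 reported in hours since
   the previous midnight and M10 since the previous midday; diurnal
   inactivity = total bout time outside the SPT-window within the day.
   Person-level summaries use the sample SD (n−1) of sleep duration across
   days; a single valid day reports the SD as missing.

All intervals are half-open `[start, end)` with 0-based epochs. The analysis
day runs noon-to-noon so a nocturnal window is never split.

## Phenotypes, orientation, GRS, meta (`somnotypes.association`)

Sleepiness is coded 1–4 from "never/rarely" through "all of the time";
"do not know"/"prefer not to answer" become missing; unknown categories
raise. Frequent-insomnia cases are the "usually" responders. Short sleep is
< 7 h and long sleep > 8 h, each contrasted against the inclusive 7–8 h
control band; the opposite extreme is set missing rather than counted as a
control, so the two case groups share one control set.

Risk-allele orientation flips every locus so the sleepiness effect is
positive, negating companion-trait effects and complementing allele
frequencies in tandem; it is an involution and preserves |z|. The z-matrix
is z = β/SE per locus × trait in the fixed order (efficiency, duration,
bouts, insomnia).

The GRS is the weighted allele count Σⱼ wⱼ·dosageᵢⱼ. Missing dosages are
mean-imputed per variant (≡ 2·EAF under Hardy–Weinberg) with the count
logged. Association tests are OLS (two-sided t) and IRLS logistic (GLM
binomial, tol 1e-8, max 50 iterations, normal-approximation p, OR with
exp(β ± 1.96·SE) CI). Fisher's method combines the cohorts' two-sided
p-values as reported (X = −2Σ ln p ~ χ²₂ₖ); direction consistency is the
caller's concern, and zero p-values are rejected rather than silently
floored. Bonferroni flags use p < 0.05/m.

## Subtype clustering (`somnotypes.clustering`)

Loci are clustered on pairwise Euclidean distances between raw (not
column-standardised) 4-trait z-score rows. Agglomeration uses complete
linkage by default — the linkage criterion is not pinned upstream, so it is
a package default with average/single/Ward selectable — cut at k = 2.
Silhouettes are computed from the same distance matrix,
s = (b − a)/max(a, b), with singleton clusters scoring 0. Each iteration
removes *all* loci with negative silhouettes (matching the reported
three-at-once removal) and reclusters, until no silhouette is negative or
`max_iter` is reached; fewer than k+1 remaining loci aborts with a partial
result. The full per-iteration audit trail (retained loci, labels,
silhouettes, averages, removals) is retained on the fitted estimator.

The two final clusters are named by centroid sign agreement with the
propensity template (+efficiency, +duration, −bouts, −insomnia): ≥ 3 of 4
matching signs → sleep propensity, the counterpart → sleep fragmentation;
ambiguous cases fall back to total agreement with a tie flag.

## Two-sample MR (`somnotypes.mr`)

Harmonization aligns outcome effects to the exposure's effect allele,
including strand-complement matches; palindromic (A/T, C/G) variants with
exposure EAF in [0.42, 0.58] (configurable) are dropped, as are unresolvable
pairs. Wald ratios use first-order weights wⱼ = γ̂ⱼ²/σ_Γⱼ² (the exposure SE
does not enter the weight), consistent with a radial plot whose x-axis is
the inverse outcome SE scaled by the exposure effect.

IVW is fixed-effect: β̂ = Σwβ̂ⱼ/Σw, SE = (Σw)^(−1/2); Cochran's Q = Σw(β̂ⱼ −
β̂)² on J−1 df. Radial MR-Egger regresses β̂ⱼ√wⱼ on √wⱼ with a free
intercept; the slope is the pleiotropy-adjusted estimate, the intercept the
directional-pleiotropy term, Rucker's Q the residual sum of squares on J−2
df, and both SEs carry the multiplicative overdispersion factor
max(1, √(Q_R/(J−2))). Rucker's Q never exceeds Cochran's Q (nested models).
Instrument strength: mean F = mean(γ̂ⱼ²/σ_γⱼ²) and I²_GX = max(0, (Q_GX −
(J−1))/Q_GX) from the precision-weighted heterogeneity of the exposure
effects. `mr_analyze` runs IVW first and adds the radial-Egger sensitivity
analysis when Cochran's Q has p < 0.05; the reverse direction swaps the
tables.

A caveat the test suite encodes: first-order weights neglect the β²σ_γ²
term in the ratio variance, so Cochran's Q is only nominally calibrated when
the causal slope is small relative to the instrument scale (as it is here);
at much larger slopes Q over-rejects by construction.

## Synthetic data (`somnotypes.simulate`)

All generators are pure functions of config + seed.

- **Traces** are z-angle level processes: waking time is piecewise-constant
  posture (new level every ~10 min) plus per-epoch wrist jitter (sd 20°);
  the planted nocturnal window (default 23:00–07:00) holds a constant
  posture with optional discrete posture changes and Gaussian measurement
  noise (default 1°); the epoch before onset already carries the sleep
  posture so the noise-free case is recoverable exactly. Naps are optional
  still windows. Not emulated: sub-second waveforms, non-wear, device
  calibration error, daylight-saving shifts — so passing recovery tests
  speak to the algorithm, not to field robustness.
- **Cohorts** draw Binomial(2, MAF) dosages per variant (no LD, no
  relatedness); quantitative traits are grs_effect·GRS + Gaussian noise and
  binary traits use a logistic link whose intercept is solved numerically to
  hit the target prevalence exactly, keeping the OR interpretation clean.
- **Z-matrices** default to the two-subtype study geometry: 10 propensity +
  27 fragmentation template loci (mean |z| = 3, noise sd 1) plus 5 loci with
  random off-template sign patterns, 42 in total.
- **MR instrument sets** satisfy InSIDE by default (pleiotropy α independent
  of γ; a violation switch exists but the Egger recovery guarantees apply
  only under InSIDE). Defaults are calibrated to the reported
  instrument-strength regime of the motivating analysis — J = 77,
  mean F ≈ 33, I²_GX ≈ 0.89, and outcome SEs giving an IVW SE near 0.005 —
  around a small positive causal slope (0.018).

## Problem sizes used in tests and the acceptance script

Monte-Carlo suites use 500 replicates for IVW coverage and Q calibration,
200 for pleiotropy detection, 100 clustering seeds for ARI recovery, and 50
two-day traces for the ±10-min window-recovery rate; these sizes give
binomial standard errors of ~1–3 percentage points on the reported rates.

## Known limitations

- The published 42-locus z-score table is not redistributable here; the
  reproduction test of the printed silhouettes/cluster sizes runs only when
  a user supplies `data/supplementary_locus_z_scores.tsv`, and otherwise
  reports the missing input as a failure rather than silently skipping.
- Cohort-scale effect magnitudes (GRS regression betas on biobank traits)
  are not reproducible without the source individual-level data; only the
  procedures are implemented and validated on synthetic cohorts.
- The clustering is hierarchical with a fixed k = 2 by default; model-based
  clustering and bootstrap stability are out of scope.
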