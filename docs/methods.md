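# Methods

This note documents the models and procedures implemented in
`methpanel`, the assumptions they make, the defaults and why they were
chosen, and what the synthetic-data generators do and do not establish.

## 1. Marker discovery

### Probe harmonisation

Two methylation array platforms are reconciled by genomic proximity: a
probe pair is matched when the design intervals overlap, or the
end-to-start distance on the same chromosome is at most 150 bp
(inclusive — a gap of exactly 150 bp matches). Coordinates are 0-based
half-open throughout; 1-based inputs must be converted at the reader
boundary. A probe may enter several pairs and the pair set is symmetric
in the two inputs.

### DMR screen

Per region, tumor vs adjacent-normal methylation levels are compared
with a two-sided Wilcoxon rank-sum test (default) and adjusted across
regions by Benjamini–Hochberg. A region passes when

* adjusted P < 1 × 10⁻²,
* mean(tumor) − mean(adjacent) > 0.1, and
* mean WBC level < 0.1.

The rank test is the default because beta values are bounded and often
skewed, making rank procedures robust; Welch's t-test and Bonferroni
adjustment are available as configuration options since the original
analysis does not state its choices. Missing values are excluded
pairwise, never imputed; a region needs ≥ 2 non-missing values per
tissue group to be tested, and all-missing regions are flagged and kept
out of the adjustment denominator. Results sort by adjusted P, ties by
larger |Δ|.

### One-hot plasma transform

cfDNA is dominated by leukocyte DNA, so raw plasma levels carry a
strong background. Per region, the detection threshold is the 95th
percentile of plasma levels in cancer-free controls, computed with
linear interpolation between order statistics (numpy's default
`quantile` method; configurable). Detection is **strict** — a level
exactly at the threshold is "not detected" — so per region at most
5% + 1/n_controls of controls light up, and a detected signal carries
the input level verbatim (signal = level if level > threshold else 0).
Fewer than 20 controls triggers a warning because the empirical 95th
percentile becomes unstable.

### Marker selection

One multivariate L2-regularised logistic fit (C = 1) on the one-hot
signals ranks regions by |coefficient| × feature SD (the standardised
effect), ties broken by lower screening adjusted-P, then
lexicographically by region key for full determinism. The top-k regions
are refit to give the final model. Regularisation absorbs perfect
separation, which is common since one-hot signals are mostly zero in
controls. No ranking rule was published; the standardised-coefficient
rule was chosen because it is scale-free across regions whose signal
magnitudes differ.

## 2. qMSP interpretation

* **QC gate.** A sample is analyzable iff its ACTB reference Ct is
  present and ≤ 34.8 (inclusive) and, when a plasma cfDNA concentration
  was recorded, ≥ 0.9 ng/mL. Both thresholds are the kit-validation
  values; the gate's reason string names the first failing rule.
  QC-failing samples are excluded from performance denominators and
  tallied separately (the trial's denominators equal its cohort sizes,
  implying negligible QC failure).
* **Marker call.** Positive iff a Ct is present and ≤ the marker's
  cutoff — inclusive, mirroring the ACTB rule. A well that never
  amplified is negative (no methylated template); a well not run is
  invalid. Undetected is an explicit sentinel (`None`), never an
  in-range Ct; where a numeric stand-in is unavoidable (risk scores,
  logistic features, ROC) the 45-cycle ceiling is used, shared through
  one configuration constant.
* **Panel combination.** The parallel (OR) rule: positive iff any valid
  marker call is positive; no_call only when no marker produced a valid
  call. Parallel testing maximises sensitivity at a specificity cost
  bounded by the union bound; 2-of-3 voting was not implemented because
  "parallel" in diagnostic-test combination conventionally means OR. A
  logistic combination over reference-adjusted Ct features
  (Ct_marker − Ct_ACTB, undetected at ceiling) is provided as the
  alternative mode.
* **Risk score.** Per marker, 45 − (Ct_marker − Ct_ACTB); the panel
  score is the maximum over markers, so more methylation gives a higher
  score, and a fully-undetected sample floors at its ACTB Ct. The
  published description pins only "45 − ΔCt"; scoring the marker Ct
  alone (45 − Ct_marker) is available behind `risk_score_mode` since
  the reference adjustment is not spelled out.
* **Cutoff calibration.** The trial's per-marker Ct cutoffs are not
  published, so they are recovered from training controls: the cutoff
  is the largest Ct at which marker-level specificity stays at or above
  the target (default 0.95). With silent controls the cutoff is the
  ceiling (any amplification is positive); excluding a control at Ct c
  requires a cutoff infinitesimally below c (`nextafter`), making the
  procedure deterministic with no arbitrary offsets.

## 3. Evaluation statistics

Point metrics are the standard 2×2 ratios; empty denominators yield NaN
with an explicit `undefined` flag, never 0. Youden's J =
sensitivity + specificity − 1. Cohen's κ uses marginal chance
agreement; its CI uses the asymptotic Fleiss–Cohen–Everitt standard
error (the source promises κ CIs but prints none, so no tighter
verification target exists). Three binomial CI constructions are
first-class — Wilson score (default), Wald (clamped to [0, 1], logged)
and Clopper–Pearson — because the published intervals demonstrably mix
all three across sections; every report labels its method. ROC curves
are empirical with ties grouped (scikit-learn points, all thresholds
kept) and AUC is the trapezoidal integral, which equals Mann–Whitney
concordance; tests verify this against exhaustive pair enumeration.
Paired pre/post score comparisons use the two-sided Wilcoxon
signed-rank test with zero differences dropped and ties mid-ranked;
independent-group comparisons route to the rank-sum test. Percentages
are printed with half-up rounding at 2 dp to match clinical convention
(e.g. 96/111 → 86.49).

## 4. Synthetic data

### What the generators emulate

`DiscoverySpec` defaults state the discovery-phase world: 108 tumor,
107 adjacent-normal and 249 WBC samples; 56 case and 107 control plasma
samples; 500 regions with 10 planted markers at Δ = 0.4 over a 0.10
background and 0.05 WBC mean. Values are Beta-distributed around each
compartment mean with concentration 20 (SD ≈ 0.065 at mean 0.1, a
realistic region-level spread). Case plasma carries a tumor-derived
elevation at a planted region with probability 0.8
(`plasma_signal_rate`); this is a stand-in for an undescribed noise
process, not a claim about the study's data.

`CohortSpec` defaults state the clinical cohort: the published group
sizes (1,429 participants) and per-marker detection probabilities
solved from each stratum's published panel positivity under the OR rule
with exchangeable markers, p = 1 − (1 − s)^(1/3). Detected Ct values
are Normal(33, 2.5) truncated at 45 cycles — late-amplification
territory typical of plasma qMSP; ACTB runs at Normal(29, 1.5), and
cfDNA concentration is log-normal around 5 ng/mL. These Ct parameters
are package choices (the source prints no Ct distributions); they fix
the scale of risk scores but not panel positivity, which is governed by
the detection probabilities alone. One top-level seed feeds
deterministically spawned per-group substreams, so identical specs give
byte-identical cohorts.

### What green tests do not establish

The simulator draws markers independently within a sample; real
methylation markers are correlated, so the OR-rule calibration
identity is exact here but only approximate in tissue. Plasma noise,
batch and center effects, age structure, and histology mixtures are not
modelled. A green calibration test therefore establishes that the
pipeline's arithmetic and calling logic reproduce a stated operating
regime — not that the panel would achieve it on new clinical material.

### Reconstructed count tables

Every printed percentage with a known denominator is inverted to the
unique integer numerator that rounds back to it; ambiguity or
impossibility fails the build. The model-verification 2×2 table is
recovered by exhaustive search over tables with the phase's margins
(92 cases / 205 controls) matching the printed accuracy (95.29%) and κ
(0.89); rounding admits 14 such tables, and the symmetric-error one
(fp = fn = 7) is selected — uniqueness under that tie-break is asserted
by an independent search in the tests. Two printed stage figures
conflict internally (stage II 86.69 vs 86.49; stage III 89.70 vs
89.71); the values consistent with the stage sizes and the overall 548
true positives (96/111, 183/204) are used. The treatment-monitoring
pre/post pairs are a deterministic synthetic stand-in reproducing the
published outcome frequencies (29 of 32 post-operative negatives, 3
non-declining scores, one of them pre-operatively low); the pair values
themselves are not published data.

## 5. Numerical choices and degenerate inputs

* Percentile: linear interpolation (configurable); the boundary example
  0.01…0.10 × 100 controls gives threshold 0.0955.
* Beta noise means are clipped to [10⁻³, 1 − 10⁻³] to keep the
  distribution proper at extreme compartment means.
* Wilson bounds are set to exactly 0/1 at x = 0/x = n rather than
  trusting float round-off.
* Empty confusion tables, all-no_call cohorts, all-zero paired
  differences and degenerate κ marginals are flagged (warning or NaN),
  never silently coerced.
* Ties in marker ranking and in ROC thresholds are broken
  deterministically; no randomized tie-breaks anywhere.

## 6. Known limitations

* The logistic and parallel combinations are compared only on synthetic
  cohorts; the published AUCs (0.947/0.948 model verification, 0.904
  clinical) depend on the unavailable raw Ct data and are not
  reproduction targets.
* Cutoff calibration assumes training controls are exchangeable with
  deployment controls; center effects would break this.
* The screen treats regions independently; no spatial smoothing or
  per-CpG modelling (inputs are region-level by design).
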