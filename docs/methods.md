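# Methods

## The problem and the statistical model

The pipeline targets experiments where biological replication is
impossible: a single microgravity (µg) sample, three 1 g control samples
grown on an on-board centrifuge, and one 1 g ground sample, each split into
five sequential extraction fractions and measured as separate LC-MS runs.
Two assumptions make a significance test possible without replicates:

1. the measurement-error distribution of log abundances is the same for
   every protein, and
2. it is the same in every condition.

Under these assumptions the log-ratios of protein abundances between the
three 1 g control samples — which differ only by technical noise — are
draws from the null distribution of any condition log-ratio. Empirically
this pooled distribution is heavy-tailed; a Laplace law fits its quantiles
better than a Normal (the `qq_diagnostic` operation reports quantile
correlations for both laws at plotting positions (i − 0.5)/n). The Laplace
maximum-likelihood fit is closed-form: location μ̂ = sample median, scale
b̂ = mean |x − μ̂|. The two-sided tail probability is likewise closed-form,
p(x) = exp(−|x − μ̂|/b̂), because P(|X − μ| ≥ t) = e^{−t/b} for
X ~ Laplace(μ, b).

Condition profiles are computed log-first: the natural log of each
quantified protein×run abundance is averaged over the fractions where the
protein was quantified (and over the three control samples for the 1 g
space condition). Three comparisons are tested per protein
(µg/1 g space, µg/1 g ground, 1 g space/1 g ground); BH correction is
applied separately within each comparison family over the proteins
quantified in all three conditions. The selection rule is deliberately
two-keyed: a protein is called over-represented only when both µg
comparisons are significant (BH < α) with positive log-ratios *and* the
1 g/1 g comparison is non-significant (BH > α) — the latter filter removes
proteins whose apparent effect is a space-vs-ground artifact rather than a
gravity effect. Under-representation is symmetric. Natural logarithms are
used throughout (ranks of p-values are base-invariant; natural log gives
the closed forms above directly).

## Quantification chain

* **MS2 event selection.** When several MS2 events match a peptide ion,
  the retained retention time is the survey-scan time of the event with
  the highest precursor intensity; ties break to the earliest scan for
  determinism.
* **Comparable groups.** Alignment, cross-assignment and normalization
  operate within one fraction across the five samples. Fractions are
  chemically distinct extracts, so cross-fraction ion ratios would mix
  extraction chemistry with abundance.
* **Alignment.** Ions identified in every run of a group form the
  retention-time matrix; the reference run is the one with the most
  identified ions (ties: lexicographically smallest run id). Duplicate
  reference RTs are collapsed by averaging. Prediction is piecewise-linear
  interpolation with linear extrapolation outside the anchor range — exact
  for affine drift, which is what the generator and typical LC gradients
  produce.
* **Cross-assignment.** An ion unidentified in a run is looked up by
  (sequence, charge) at the predicted RT; a match within ±1 min (default;
  ~1 % of a 110-min gradient) transfers the feature's XIC area with
  `identified=False`. Misses stay missing — no zero-filling anywhere.
  A ±10 ppm m/z window option exists for real-data feature tables where
  sequence identity is not a reliable join key.
* **Normalization.** Median of (reference area / run area) over shared
  quantified ions, applied at ion level before protein summation; the
  reference run's factor is 1, and even-count medians are the mean of the
  two central order statistics (fixed for bit-reproducibility).
* **Protein abundance.** Sum of quantified (identified + cross-assigned)
  peptide-ion areas; peptides mapping to more than one protein are excluded
  from all sums; cells with fewer than two distinct quantified peptide
  sequences are reported missing.

## Validation

The score-threshold sweep considers every distinct observed score in
descending order, computes FDR = 100·D/(T+D) over PSMs at or above each
threshold, and keeps the threshold that validates the most targets while
staying strictly below the FDR limit (ties resolve to the higher threshold,
which admits fewer decoys). PSMs shorter than the minimum peptide length
are removed first; decoys and targets face identical criteria. Validation
runs per LC-MS run by default (each run is a separately searched sample); a
pooled call is available by passing the concatenated table. Reported
proteins need ≥ 2 distinct validated peptide sequences, counted at the
sequence level (charge states collapse).

## Synthetic data: what it emulates and what it does not

Per protein: a baseline log abundance ~ Normal(10, 1.5²); a fraction
profile (1–5 of the 5 extracts, weighted toward fewer fractions, identical
across samples); 2 + Poisson(3) peptides with log-normal (σ = 0.5)
ionization factors. Per protein × run: log abundance = baseline +
condition effect + Laplace(0, b = 0.06) noise, with the condition effect
ln(2.3) (over) or ln(1/2.1) (under) applied only in µg, identically across
fractions. Spike-in proportions default to 80/1484 and 69/1484. Peptide
areas are the protein's linear abundance times the ionization factor, so
ion-level ratios between runs carry pure protein-level noise. Retention
times drift affinely per run (slope within ±5 %, intercept within ±2 min,
Gaussian jitter 0.1 min); identifications drop at 15 % per ion per run
(rescued if an ion would vanish from an entire fraction group — probability
≈ 7.6·10⁻⁵ per group at the default rate); decoy PSM scores are
stochastically below target scores and decoy peptide lengths include values
below 8 residues.

Defaults were chosen once to represent the study conditions: b = 0.06 makes
fold changes near the smallest published significant ratios (~1.5)
borderline-detectable at ~1500 BH-corrected tests, and the spike fold
changes match the published average fold changes (2.3 over, ~2.1 under).

Not emulated: peptide-level interference and co-elution, intensity-dependent
(heteroscedastic) noise, nonlinear RT drift, shared peptides between
proteins, protein inference ambiguity, and condition-dependent extraction
(fraction profiles are gravity-invariant). Passing tests therefore
demonstrate correctness of the computational chain under the stated noise
model, not robustness to those real-data pathologies.

Because proteins present in fewer fractions contribute noisier control
pair ratios (a pair ratio is a difference of two means over k fraction
runs), the pooled null scale is *not* 2b·0.75/√k for any single k; the
package provides `effective_pairwise_scale`, a Monte-Carlo evaluation of
the pooled mixture given the per-protein fraction counts, as the recovery
oracle (≈ 0.068 at b = 0.06 under the default fraction-profile weights).

## Numerical choices and degenerate inputs

* Even-count medians: mean of the two central order statistics.
* FDR with zero validated hits raises an explicit undefined-input error;
  an infeasible FDR limit returns an empty validation with a warning
  status rather than silently validating nothing.
* Laplace fitting requires ≥ 10 ratios and rejects degenerate (all-equal)
  input; p-values at the null location are exactly 1.
* BH: step-up with cumulative minimum from the largest p, capped at 1;
  ties and equal p-values handled by stable sorting.
* Venn and category percentages round half-up to one decimal, matching the
  conventional printed style; counts are exact integers.
* Under-direction fold changes are reported as reciprocals of the µg/1 g
  ratio so both directions read as values ≥ 1; the mean-of-reciprocals
  convention is one of several defensible averages and is not asserted to
  reproduce any published point value exactly.
* All intermediates serialize as TSV with floats at six significant
  digits; downstream stages consume the serialized tables so re-running a
  stage on saved intermediates is byte-for-byte reproducible.
* A single pipeline seed expands into independent per-stage substreams
  (numpy `SeedSequence.spawn`), recorded in the manifest via the config
  hash; the hash excludes the output directory.

## Problem sizes

Default runs simulate 1500 proteins (~89 000 feature rows, ~80 000 PSMs,
25 runs) and complete in a few seconds; the no-effect calibration study in
the test suite uses 20 seeds at 300 proteins, and the acceptance script
uses 5 seeds at 300 proteins plus one full-scale run. These sizes were
chosen so the statistical properties (power, calibration, scale recovery)
are measured with comfortable margins while the whole suite stays fast.

## Known limitations

* The untestable/unchanged distinction depends on the ≥ 2-peptide rule per
  cell; proteins hovering at two peptides can drop out of single fractions
  and change their fraction-mean variance slightly between conditions.
* The null is pooled across proteins; strong abundance-dependent variance
  in real data would violate assumption 1 and miscalibrate tail p-values.
* Cross-assignment joins on (sequence, charge) in the synthetic world; the
  m/z-window mode for real feature tables is provided but not exercised by
  the simulator.
* With a single µg sample the µg condition mean averages 5 runs while the
  1 g space mean averages 15, so the two µg comparisons are slightly
  conservative relative to the control-pair null (which differences two
  5-run means).
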