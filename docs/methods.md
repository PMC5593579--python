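# Methods

## Scope and model

`mirpipe` implements a two-group differential-expression analysis for
single-channel spotted miRNA arrays.  The biological contrast is between
samples with high ALK expression (ALK+) and low/absent ALK expression
(ALK−); the statistical machinery is generic for any two-group spotted-array
design.  The working model is multiplicative intensity noise: a probe's
spot-level fluorescence is log-normal, so all inference happens on log2
intensities where group effects are additive.

## QC cascade

**Detection policy.**  A spot counts as *detected* when it is a non-control
feature (`ControlType == 0`) and passes a set of boolean flag conditions.
The flag set of the original study's array scans is not fully specified in
public form, so the policy is an injectable object; the default —
`well_above_background ∧ ¬saturated ∧ ¬nonuniform_outlier ∧
¬population_outlier ∧ ¬manual_flag` — is standard Feature-Extraction
detection semantics.  Any policy must be a pure predicate; referencing a
flag a file does not carry is a configuration error, never a silent pass.

**Stage order.**  Prefix restriction → detection calls → probe filter →
array exclusion → replicate averaging, with no iteration: the probe filter
uses all arrays' detection counts and is *not* recomputed after an array is
excluded.  This mirrors the workflow being reproduced, which lists the
steps once in this order.

**Probe filter.**  A probe's per-group count is the number of detected
replicate spots summed over every array of the group; the probe is removed
when the count is strictly below `min_detected` (default 5) in *either*
group, the plain reading of "fewer than five in one of the two groups" —
and the one that leaves both groups measurable for the t-test.

**Array exclusion.**  Threshold = mean − k·SD of the per-array detected-spot
counts (default k = 2), computed once over all arrays.  SD is the sample
standard deviation (n−1), the small-n convention; the population variant is
auditable via the QC report, which records every parameter in force.

**Averaging.**  All replicate spots of a probe enter the arithmetic mean of
background-subtracted signals, detected or not, so the expression matrix is
complete (no missing values) and the downstream t-test is well defined on
full columns.  Whether undetected replicates should instead be dropped is
genuinely undecidable from the public description; detection counts are
therefore carried alongside every averaged value so either convention can
be audited.  Background-subtracted signals can be ≤ 0; they are floored at
1.0 fluorescence unit (configurable) immediately before log2.

## Normalization

Two between-array methods, selected per dataset preset:

* **Quantile** (`cell_lines` preset) — classic rank-mean algorithm: sort
  each array, average across arrays at each rank, assign by rank.  Ties
  within an array receive the mean of the quantile values their tied ranks
  span (the common deterministic convention).  With ties present, exact
  equality of column distributions and idempotence hold only approximately;
  for tie-free data both are exact and are property-tested.
* **Scale** (`tumors` preset) — each array is multiplied by
  (geometric mean of all array medians)/(its own median), so all medians
  land exactly on the geometric mean of the input medians.  The scaling is
  multiplicative on the matrix as given (matching median-ratio scale
  normalization in the array-analysis ecosystem); an additive
  median-centering variant in log2 space is available by option.

There is no data-driven rule choosing between the two; the preset encodes
the per-dataset choice of the study design being emulated.

## Differential expression

Per probe, Welch's unpaired two-tailed unequal-variance t-test with
Welch–Satterthwaite degrees of freedom (df not rounded, p from the
continuous central t distribution).  Selection is on raw p < α (default
0.05, strict inequality).  Benjamini–Hochberg q-values are computed and
reported per record for multiplicity transparency but never drive
selection, reproducing the original selection surface while flagging its
cost.  Fold change is 2^|Δ(log2 means)| with a direction call
(`down_in_alk_pos` when the ALK− mean is higher).  Degenerate probes with
zero variance in both groups get p = 1 (equal means) or p = 0 (unequal) in
the vectorized matrix path; the scalar `welch_t` raises on the unequal-means
case instead.

## Clustering

Agglomerative clustering of the significant-probe log2 matrix, rows and
columns, using Euclidean distance and Ward's criterion.  "Ward" is
ambiguous across ecosystems; the default is the criterion-faithful Ward.D2
(Lance–Williams update on squared distances, heights reported on the
distance scale), with the legacy variant (same update on unsquared
distances) behind an option.  Ties are broken deterministically by the
smallest active cluster-position pair.  No row scaling is applied before
clustering by default.  Dendrograms export to Newick with branch length =
parent height − child height.

## Candidate prioritization

Significant down-in-ALK+ miRNAs are candidates when at least one of:
(i) predicted ALK 3′-UTR targeting — an input boolean, optionally derivable
from the bundled seed scanner; (ii) fold change > 2; (iii) literature
support (input boolean).  The seed scanner finds exact reverse-complement
matches of miRNA seed positions 2–7 (6mer), 2–8 (7mer) and 2–8-plus-A
(8mer) in a DNA UTR, reporting overlapping matches once at the strongest
type; it is a minimal canonical site finder, not a reimplementation of
thermodynamic/conservation-scored target prediction, which is out of scope.

## Quantification arithmetic

* **ΔCt** — ΔCt = Ct(target) − geometric mean of the reference genes' Ct
  (taken over Ct values directly); relative level = E^(−ΔCt) with
  amplification efficiency E = 2 by default (overridable); samples rescaled
  so the least-expressed sits at fold 1.
* **Dual luciferase** — per-well firefly/renilla ratio (replicates averaged
  after ratioing, since the two readings are physically paired per well),
  divided by the empty-vector mean ratio, expressed as percent of the
  negative-control condition (≡ 100 %).
* **MTT** — per-well A595 − A655, condition means, percent of the negative
  control.

All three are invariant under uniform rescaling of the raw readings and
under replicate reordering (property-tested).

## Synthetic data

The generator emulates the study conditions: two groups of arrays
(default 10 vs 6, the cell-line screen layout), 866 human probes (the human
miRNA catalogue size of the emulated array) spotted in duplicate plus 20
non-hsa control features, per-spot log2 intensity = probe baseline
(N(7, 2²), spanning the low-to-high expression range seen in the candidate
tables) + group effect for planted probes + spot noise (sd 0.5 by default).
Thirty probes are planted down-regulated in ALK+ at 1.5 log2 units
(≈ 2.8-fold, mid-range of the reported candidates).  Detection flags fail
independently per spot at a 5 % miss rate, optionally inflated on
deliberately degraded arrays to exercise the MEAN−2SD exclusion.  After
exponentiation, a small additive residual (sd 0.5 fluorescence units)
models imperfect background subtraction, so signals can dip below zero and
exercise the log2 floor.  One integer seed drives a single generator for
all draws; identical configs produce byte-identical files.

What the simulation does **not** model: spatial artifacts, dye chemistry,
probe cross-hybridization, correlated detection failures and array-level
intensity biases.  Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and decision rules under the assumed noise model, not
robustness to real-scanner systematics — in particular, between-array
normalization is close to a no-op on simulated data because all arrays
share one generative distribution.

## Verification set-up and problem sizes

The statistical acceptance checks run at 1000 probes, 8 vs 8 arrays, spot
noise sd 0.3, over 20 seeds: (a) with no planted effect the mean fraction
of raw p < 0.05 must sit in the binomial 95 % band around 0.05; (b) with 10
probes planted at 2.0 log2 units, every planted probe must be significant
with the correct direction and the mean estimated |log2 FC| within 3
standard errors of 2.0 in ≥ 19/20 seeds.  Parameter recovery is measured on
the log2 averaged matrix, before between-array normalization: quantile
normalization maps values through rank-based reference quantiles, which in
the sparse distribution tails (baseline sd 2) can shift an individual
extreme-ranked probe's estimate by several tenths of a log2 unit — a known
edge property of the method, visible in the package's own experiments, and
a measurement-stage distortion rather than a property of the estimator
under test.  Individual planted probes with very low baselines can also be
compressed by the log2 floor; the recovery criterion therefore targets the
mean over planted probes.

Welch's test is verified against an independent reference implementation to
1e-10 on a thousand random small-sample pairs, and the Ward agglomeration
against a reference linkage implementation (same merge sets, heights to
1e-9) on random instances; the references serve only as oracles, never as
the implementation.

## Known limitations

* The public description of the original workflow leaves the spot-quality
  constraint table, the replicate-averaging treatment of undetected spots
  and the exact Ward variant unspecified; all three are configurable, and
  full-scale reproduction of the published probe counts would require the
  deposited raw arrays plus the supplementary constraint table.
* The probe filter is intentionally not recomputed after array exclusion;
  on datasets where the excluded array carried many unique detections the
  kept-probe set can include probes a stricter re-run would drop.
* The seed scanner ignores non-canonical sites, 3′-supplementary pairing,
  site context and conservation.
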