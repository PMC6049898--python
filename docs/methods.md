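# Methods

## Model

A doubly bound region contributes an intensity pair (x, y): the target TF's
peak intensity x and the partner TF's peak intensity y, read from the
narrowPeak `signalValue` column (0-indexed column 6; configurable, since
some pipelines train on the BED score column instead). The joint density is
a two-component mixture

p(x, y) = w f_c(x) g_c(y) + (1 − w) f_n(x) g_n(y),

with two assumptions:

1. **Conditional independence.** Within a component, x and y are
   independent, so each component is a product of one-dimensional
   marginals. The `mutual_information` diagnostic (plug-in estimator on
   equal-frequency quantile bins, base-2 logs, default 4 bins) exists to
   check this on data; quantile bins are used because peak intensities are
   heavy-tailed.
2. **Weak cooperative target.** The cooperative component has the lower
   target-axis mean. This is an identification convention applied *after*
   fitting (lower location for lognormal/gaussian, lower k·θ for gamma;
   ties broken on the partner axis), not a constraint during EM.

Marginals are Log-normal by default; Gamma and Gaussian are implemented for
the family comparison. On lognormal-generated data the lognormal fit
attains the highest total log-likelihood of the three, which is the
direction the family comparison asserts.

## EM fitting

Nine free parameters: four (location, scale) pairs and the weight w.

* **Initialization** (the procedure is not uniquely determined by the
  model, so it is fixed deterministically): split the pairs at the median
  target intensity; the low half seeds the cooperative component by moment
  fits; w starts at 0.5. Optional restarts perturb locations additively
  (sd = 0.25·|loc| + 0.1), scales multiplicatively (log-sd 0.25) and draw
  w ~ U(0.2, 0.8) from the supplied seed; the restart with the highest
  final log-likelihood wins.
* **E-step** responsibilities and all densities are computed in log space
  (`logaddexp`), so extreme intensities cannot underflow.
* **M-step**: weighted closed-form mean/sd updates for lognormal (on
  log-intensities) and gaussian. For gamma, weighted MLE with Newton
  iterations on the shape via the digamma equation
  ln k − ψ(k) = ln(weighted mean) − weighted mean of logs, falling back to
  weighted method of moments if the Newton iteration leaves the positive
  half-line or the log-moment gap is non-positive.
* **Numerical floors**: responsibilities clamped to [1e-12, 1 − 1e-12],
  scales floored at 1e-6, w clamped to [1e-6, 1 − 1e-6]; these prevent
  component collapse on outliers. Data in which every pair is identical is
  rejected up front as degenerate.
* **Convergence**: relative log-likelihood change < 1e-6 (default), max
  1000 sweeps. The log-likelihood trace is stored on the fitted model and
  asserted non-decreasing at every sweep (tolerance 1e-8 relative, for
  floating-point noise).

Posteriors are the Bayes ratio evaluated in log space; classification is
strict (`posterior > α`). The fitted model serializes to a plain-text
key-value file.

## Knockout labels

Peak loss (no ≥ 1 bp overlap with any knockout replicate) always labels a
pair cooperative. For surviving peaks, `loss_only` mode labels everything
else independent — the fallback when per-replicate calls are unavailable.

`rank_change` mode uses normalized ranks (descending-intensity rank divided
by the sample's peak count, average ranks on ties, rank 1 = strongest): the
change Δr = mean knockout normalized rank − mean wild-type normalized rank
is compared against an empirical null of Δr built from all
wild-type-vs-wild-type replicate pairs (both directions, so the null is
sign-symmetric). Δr above the `significance` percentile (default 97.5) of
the null is cooperative (`rank_up`), below the `100 − significance`
percentile competitive (`rank_down`), otherwise independent. Because the
two cut-offs move outward monotonically with `significance`, lowering it
can only move labels out of the independent class.

**Known limitation.** Normalized ranks are comparable across samples with
*similar* peak counts. When knockout removes a large fraction of peaks, the
surviving peaks' normalized ranks inflate mechanically (same rank, smaller
denominator), biasing `rank_change` toward cooperative calls. Rank-change
results should therefore be interpreted together with the loss fraction;
`loss_only` is unaffected. Rank changes are also insensitive to a uniform
attenuation of the already-weakest class, which preserves the ordering.

Peak correspondence between samples is by largest interval overlap.

## Indirect-binding filter

Best-hit PWM scanning: the score of a window is the sum of per-position
log-odds (base-2, pseudocount 0.01·background per cell against a
zeroth-order background); the best hit maximizes over all offsets on both
strands (reverse strand scored on the reverse complement), ties resolved to
the smaller position, then the + strand. `N` bases score 0 (neutral);
sequences with no scannable window are flagged with a warning rather than
scored.

The threshold T is the nearest-rank (ceil) percentile — default 90th — of
best-hit scores over N unbound control windows of the mean peak length,
drawn by rejection sampling away from all peaks. A peak scoring strictly
below T is flagged indirect. By construction, background-sequence peaks are
flagged at rate ≈ k/(N+1) ≈ 0.9, which is what the calibration check
measures. The filter is idempotent and monotone in the percentile.

## Synthetic data

The generator's defaults are the reference study conditions used by the
test-suite and the acceptance script: 4000 pairs, w = 0.4, lognormal
marginals — cooperative target (μ = 1.0, σ = 0.5), cooperative partner
(2.0, 0.6), non-cooperative target (2.5, 0.5), non-cooperative partner
(2.1, 0.6) — a 3σ target-axis separation under which the Bayes-optimal
detector exceeds auROC 0.95. Knockout loss probability defaults to 0.8
with ×0.5 attenuation for cooperative survivors; two wild-type and two
knockout replicates with log-sd 0.1 intensity jitter (knockout assays in
the validation datasets this emulates typically had two replicates).

Genome plumbing: a single 5 Mb contig of i.i.d. background letters; target
peaks are placed one per slot on a jittered grid (slot = genome length /
n_pairs, required ≥ 3× the maximum peak length), so targets never overlap
each other and each partner peak — drawn to overlap its own target by
≥ 1 bp — stays inside its slot. This keeps the truth table in 1:1
correspondence with the emitted pairs. Peak lengths are normal
(200 ± 20 bp, clipped at 50); summit offsets are uniform within each peak
*independently of the label*, so summit distance carries no label signal
and the distance detector scores at chance on these data. A motif site
sampled from the PWM's probability matrix is planted at the target summit
at rate 0.9. The default simulation PWM (8 bp, consensus TGACGTCA, ~80%
per position) deliberately has heterogeneous off-consensus counts so that
best-hit scores are effectively continuous — a two-valued score alphabet
would tie heavily at the control percentile and distort the filter's
calibration.

**What the generator does not emulate:** read-level noise, mappability and
chromatin structure, peak-caller artefacts, inter-peak spacing biases,
dependence between x and y within a component, and indirect binding
itself. Passing tests therefore demonstrate correctness of the algorithms
under the model's own assumptions, not performance on real ChIP-seq data.

## Evaluation conventions

ROC points are tie-grouped (all observations sharing a score enter at one
threshold), so the trapezoidal auROC equals the Mann-Whitney U statistic
normalized by N_c·N_nc; this is cross-checked against brute-force pairwise
counting. The precision-recall area is the step-wise integral (average
precision), which equals class prevalence for uninformative scores. The
rank-sum test enumerates the exact U null for min(n, m) ≤ 8 without
cross-sample ties and otherwise uses the tie-corrected normal
approximation.

## Problem sizes

The acceptance script uses the reference 4000-pair simulation (20 seeds
for parameter recovery), 2000-pair end-to-end experiments, 800 pairs for
knockout-label recovery, 200 × 500-pair replicates for chance-detector
calibration, and 5 × 400-peak replicates with 2000 control windows for
filter calibration — sizes at which every reported quantity is stable to
well within its tolerance while the whole script completes in seconds.
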