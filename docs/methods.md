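# Methods

## Data model

An event log is a long table of (patient, date, code, system) rows. Rows
sharing a (patient, date) form one event; a code repeated on the same date
is kept as a multiset multiplicity. Intra-day ordering is not modelled:
claims data carry dates, and activities occurring at the same time belong to
one event. Codes live in single-parent forests (one tree per code system,
as in ICD-10 chapters, CCAM or ATC at the levels used here); poly-hierarchies
are rejected at load, and ancestor chains are capped at 10 steps.

**Hierarchy enrichment** adds, for each occurrence of a code, one occurrence
of each of its ancestors to the same event. An ancestor's multiplicity in an
event therefore equals the summed multiplicities of its recorded descendants
there (plus its own recorded occurrences). This "once per occurrence" rule —
rather than once per event — keeps count semantics consistent across
hierarchy levels, so a parent's matrix row is exactly the sum of its
children's rows. Codes recorded at several levels in the raw data are all
kept; enrichment never deduplicates.

**Frequency filtering** removes labels whose total occurrence count (over
occurrences, not distinct patients) falls below a threshold, after
enrichment, so rare leaves vanish while their common ancestors survive.
Retained labels are reported sorted; lexicographic order also breaks every
ranking tie in the package, making all reports reproducible.

## Tensorization

Window ``j`` (1-based, ``j = w`` most recent) covers the half-open interval
``[index − (w−j+1)·Δ, index − (w−j)·Δ)`` in days before the patient's index
date. The index date itself is excluded — history is strictly prior to the
prediction point — and events older than ``w·Δ`` are dropped with a logged
count rather than raised, since claims extracts routinely include
stragglers. Two presets cover two years of history: 24 windows of 30.44 days
(monthly) and 26 windows of 28 days (four-weekly); both are plain
`WindowSpec` values, neither is hard-coded.

Counts are mapped to [0, 1] by a single global factor — the maximum cell
value over the training dataset — rather than per-activity maxima, so
relative intensity between activities is preserved and training counts are
exactly recoverable by multiplying back. Test-time cells exceeding the
training maximum clip to 1.

LOF (per-label totals over the whole history) and TW (per-label totals in
``n_blocks`` window blocks, earliest block padded when ``w`` is not
divisible) exports are provided for tabular baselines; LOF equals the row
sums of the count matrix by construction.

## Autoencoder strategies

One dense topology serves all three architectures: flatten →
dense(d = 32, tanh) → linear latent head → dense(d = 32, tanh) →
dense(p, sigmoid) → reshape. The latent head emits d_latent = 8 values
(AE/DAE) or 2·d_latent means and log-variances (VAE). Dropout and batch
normalisation are deliberately absent: at these layer widths they buy
little and cost run-to-run reproducibility.

Training minimises the summed binary cross entropy between the
class-dependent target δ^α(x) and the decoding, averaged over the minibatch
(sum over cells, mean over batch — gradient scale independent of batch
size). The VAE adds the analytic KL of the diagonal-Gaussian posterior from
N(0, I) and draws one reparameterised sample per element per step; its
inference path (prediction, explanation, validation loss) always uses the
posterior mean, so every downstream quantity is deterministic given the
weights. The DAE flips ``round(noise_ratio · p)`` distinct input cells to
their complement, resampled every epoch from a (seed, epoch)-derived
stream; targets are always computed from the clean input.

Defaults: Adam with learning rate 1e-4, batch size 64, at most 5,000 epochs,
early stopping with patience 25 on a held-out stratified 10% of the training
set (the monitored quantity is the deterministic validation objective
including KL), best-validation weights restored. The decoder's output bias
is initialised at the logit of the mean target rate, which removes the long
initial phase where the network only learns the base rate. Cross entropy
clips outputs to [1e-7, 1 − 1e-7]; the backward pass uses the exact
(output − target) gradient of the fused sigmoid + cross-entropy form, so
clipping never produces gradient spikes.

The network is implemented directly in numpy (explicit forward/backward
passes and an Adam optimiser): at p ≈ 700 inputs and width 32 the matrices
are small enough that a framework adds nothing but a dependency, and the
bespoke objectives are the point of the package.

## Prediction and evaluation

y^F sums the decoded cells (range [0, p]); y^I = 1 − mean squared deviation
between input and decoding (range [0, 1]). The ``|·|²`` in the inverse score
is read as the per-cell square — this matches the normalisation by p and
the score's role as an inverse reconstruction error; an absolute-difference
reading would change the scale but not the ordering on binary inputs.

The classification threshold minimises the size-weighted two-leaf Gini
impurity (the CART split criterion) over midpoints of consecutive sorted
unique scores, ties resolved toward the smallest threshold. AUC-ROC,
AUC-PR (step integration / average precision) and MCC come from
scikit-learn; a zero confusion margin makes MCC undefined and is reported
as 0 with a warning.

## Explanation and validation

E = x̄₁ − x̄₀ is computed on the training split by default (the explanation
describes what the model learned); relative risks are computed on the whole
population (train + test), both configurable. Rankings: row sums of E over
windows 1..w−1 for recurrent factors, E in window w for last-window factors;
top-100 candidates per scope by default.

Exposure for activity i is binary: the patient's intensity (row-i sum over
windows 1..w−1, or the window-w value) at or above the population mean of
that quantity. The ≥ convention means a degenerate activity (identical for
all patients) makes everyone exposed; such records are skipped in batch
validation. The RR confidence interval is the Katz log-normal
exp(ln RR ± 1.96·SE), SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d); any zero cell
triggers a +0.5 continuity correction on all four cells, flagged in the
record. "Most significant" is operationalised as CI excluding 1 and RR > 1,
ordered by RR descending — a documented choice, since no specific test
statistic is attached to the selection in the underlying methodology. The
final report keeps the top 15.

## Synthetic benchmark

The generator emulates the *structure* of a claims extract, not its content:
independent Bernoulli background activity per (patient, window, activity),
a code forest of configurable shape, and a temporal motif — an ordered list
of (activity, window-offset) cells — planted into a fraction of positive
patients. Defaults: 2,000 patients, 40% outcome prevalence (a realistic
device-cohort figure), 20 background leaf activities under 2 systems of
depth 2, 26 four-week windows over two years, background rate 0.05 per
(patient, window, activity), a 6-step motif in the last six windows with
penetrance 0.9 among positives, and 5% of negatives carrying the first half
of the motif as confounding noise. Event dates sit on the most recent day of
their window so tensorization recovers the planted layout exactly.

What the generator does **not** emulate: realistic code frequencies, bursty
or correlated utilisation (comorbidity clusters, hospital stays), informative
censoring, or coding drift. Passing the benchmark therefore demonstrates
that the pipeline is internally correct and can recover a planted temporal
signal at realistic noise levels — not that it attains any particular
performance on real claims data.

Problem sizes in the test suite and the acceptance script (2,000 patients,
~26 retained labels, w = 26) are chosen so a full double-training run
completes in well under a minute on one CPU core while leaving the planted
signal detectable but non-trivial (held-out AUC is bounded near 0.95 by the
0.9 penetrance).

## Known limitations

- Encoder/decoder are dense only; recurrent or convolutional variants and
  per-activity window lengths are out of scope.
- Explanation is global; no per-patient attributions.
- RR validation is univariable: no adjustment for confounding between
  activities (an activity correlated with a true factor will also validate).
- The Gini threshold is fitted on training scores; with heavily imbalanced
  outcomes a different operating point may be preferable.
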