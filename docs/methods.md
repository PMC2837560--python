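# Methods

## Overview

`sigrev` chains five statistical stages: quality control and normalization
of log2 expression matrices, nearest-shrunken-centroid (PAM) classifier
discovery on the biopsy arm, SAM-style permutation differential expression
on the drug-treatment arm, directional reversal scoring of the classifier
genes, and ΔΔCT quantification of qPCR validation data. A seeded synthetic
generator supplies data with the same design so each stage can be tested
against planted ground truth. This note records the model assumptions, the
parameters that matter, and the design choices made where the method left
room.

## Synthetic data model

The generator emulates a two-arm colorectal study: a biopsy arm with 11
normal, 20 adenoma and 22 carcinoma profiles, and a cell-line arm with 3
treated and 3 control profiles. Per probe, a baseline mean is drawn
uniformly from `baseline_mean_range` (default 4–12 log2 units, the usual
mid-range of summarized array intensities). Each disease group receives a
disjoint set of `n_signature` probes (default 20) shifted by
± `effect_size` (default 2.0 log2, i.e. four-fold) in that group. Noise is
i.i.d. Gaussian on the log2 scale with `noise_sd` (default 0.5); no
probe–probe correlation, batch structure or intensity-dependent variance is
modeled. Passing tests therefore demonstrate correctness of the inference
machinery under the declared design, not robustness to the correlation
structure, mixed cell composition or platform artifacts of real biopsy
data.

In the treatment arm, `n_reversed` of each contrast's signature probes
(default 17 of 20) are shifted opposite to their disease sign in the
treated group; the remaining signature probes shift with the same sign by
default (`nonreversed_mode="same"`). The same-sign default was chosen
because under the alternative ("none"), the treatment log-fold-change of a
non-reversed probe is pure noise and its sign a coin flip, so the planted
reversed count would not be a deterministic recovery target. A
`background_de_fraction` (default 10%) of non-signature probes receives an
independent two-sided shift, emulating a broad, signature-unrelated drug
response; reversal counting must be (and is) insensitive to it.

CT tables encode each gene's planted log2 shift as a *decrease* in threshold
cycle on top of a gene-specific base cycle (uniform 20–30), with triplicate
technical replicates at `ct_replicate_sd` (default 0.1 cycles) and a
group-independent reference gene fixed at 12 cycles, mimicking a
high-abundance ribosomal control. At zero replicate noise the ΔΔCT pipeline
recovers planted fold changes exactly, which the tests exploit as a closed
form. `noise_sd` may be zero so these noiseless limits are expressible,
even though positive noise is the realistic default.

## QC and normalization

- **Present-call proxy.** True detection calls need probe-level data, so the
  gate is the fraction of probes above a background threshold (default: the
  25th percentile of the pooled intensity distribution); a sample fails if
  that fraction is ≤ 25% (the gate is strict). QC reports and never mutates;
  exclusion is an explicit option of the pipeline (`exclude_failed_qc`).
- **Replicate distance.** All pairwise Euclidean distances between samples
  are computed; a sample is flagged when its mean within-group distance
  exceeds `max_ratio` (default 2.0) times the group's median within-group
  pairwise distance. In groups of three, one divergent member inflates the
  median itself, so ratios below 1 are needed to single it out; the default
  is calibrated for reporting, not automatic rejection. Singleton groups
  are unevaluable, not failed.
- **Quantile normalization** maps each column onto the row-wise mean of the
  column-sorted matrix. Ties receive the mean of the reference values at
  their tied (average) ranks via linear interpolation — deterministic and
  rank-preserving up to ties.
- **Median polish** sweeps row medians first, then column medians (results
  differ slightly by sweep order, hence the order is fixed and documented),
  folding effect medians into the overall term, until all sweep medians are
  below `tol` (default 1e-9) or `max_iter` (default 20) is reached;
  non-convergence is flagged, not raised. The per-sample summary is
  overall + column effect. The decomposition pins row- and column-effect
  medians to zero, which makes it identifiable.

## SAM differential expression

The two-class unpaired moderated t-statistic is `d_i = r_i/(s_i + s0)` with
`r_i` the difference of group means (equal to the log2 fold change) and
`s_i` the pooled standard error. `s0` is selected from the 0th–100th
percentiles (step 5) of `s_i` by minimizing the coefficient of variation of
windowed median absolute deviations of `d` — the standard "fudge factor"
procedure; it is deterministic and breaks ties toward the smallest
candidate.

The null pools |d| across all probes and label permutations. When
`C(n_a+n_b, n_a)` is at most the exhaustive cap (default 2000) all
assignments are enumerated — a 3-vs-3 design yields exactly 20 — otherwise
distinct assignments are sampled without replacement, seeded. The p-value
uses a +1 pseudocount so p ∈ (0, 1]. Pooling across probes is essential at
these sample sizes: 20 relabelings alone can never produce a per-probe
p < 0.05. A probe with zero variance in both groups and `s0 = 0` is flagged
degenerate (d = NaN) rather than reported as infinite. Selection defaults
follow the study convention: p < 0.05, with two-fold gates logFC > 1 and
logFC < −1. A SAM-style median false-call estimate at a |d| cutoff is
available (`median_false_calls`) but is not part of the default selection
path. Whether an original "P < 0.05" refers to a permutation p or a
q-value is ambiguous in such studies; the permutation p is the documented
default here.

## PAM classification

Fitting follows the standard construction: overall and class centroids,
pooled within-class SD `s_i`, `s0 = median(s_i)`, and standardizing factor
`m_k = sqrt(1/n_k − 1/n)` — the variance factor of `x̄_ik − x̄_i` when the
overall centroid includes class k. Some presentations use the "+" form;
it is available as `mk_form="plus"` but the internally consistent "minus"
form is the default. Shrinkage is plain soft thresholding; survivors are
probes with any nonzero shrunken deviation. The discriminant is the
diagonal-weighted squared distance to the shrunken centroid minus
`2·log π_k`; probabilities are the softmax of `−δ_k/2`. Zero survivors fall
back to the priors, flagged.

**Threshold selection.** Δ is chosen by stratified k-fold cross-validation
(default 10 folds, capped at the smallest class size, seeded). Among grid
points attaining the minimum CV error, consecutive runs with a constant
full-data survivor count are formed and the run spanning the widest
Δ-interval is selected; the largest Δ within it is returned. Rationale:
with a strongly separating gene set the zero-error region typically extends
until only one or two genes survive, so "largest minimizing Δ" alone would
discard most of the real signature, while "smallest minimizing Δ" keeps
every noise probe. The widest stable plateau identifies the gene set that
is insensitive to the exact threshold — the planted signature in synthetic
data — and degenerates gracefully to the largest minimizing Δ when no
plateau exists. Sensitivity (disease class positive; configurable) and
specificity are computed from the held-out predictions at the chosen Δ.

## Reversal scoring

Per classifier gene, the disease direction is the sign of the
disease-minus-normal shrunken-centroid difference (equal to the sign of the
raw centroid difference for any survivor in a two-class model). The gene is
reversed when `direction × sign(treatment logFC) < 0` and
`|logFC| > min_change`; `min_change` defaults to 0 so any opposite-sign
change counts, with the statistical weight carried by the significance
layer (`treatment p < α`). A treatment logFC of exactly zero is "no
change", never reversal. Matching is by probe ID (both arms on one
platform); a symbol-level fallback takes the probe with the largest
|treatment logFC| among those sharing the symbol and flags the match
ambiguous. Unmatched probes are listed, never silently dropped, and stay
out of the count denominators.

## ΔΔCT quantification

Technical replicate triples are accepted when max − min < 0.5 cycles
(strict), then collapsed to their mean; undetermined CTs (NaN; no
amplification in the 40-cycle run) are excluded with a reason rather than
imputed at the cycle cap, which would bias ΔΔCT toward the cap. The ΔRn
quality rule is made concrete as a per-gene k·SD filter (default k = 3,
nothing excluded at SD = 0); note a single outlier among n assays cannot
exceed (n−1)/√n sample SDs of the contaminated mean, so the filter only
bites for reasonably many assays. ΔCT is target minus reference per sample;
ΔΔCT is the difference of arithmetic group means of ΔCT; fold change is
exactly `2^(−ΔΔCT)`. Group comparison uses the pooled-variance (Student)
two-sample t-test on per-sample ΔCT, with Welch available by argument;
degenerate zero-variance cases resolve to t = 0, p = 1 (equal means) or
p = 0 (unequal). Concordance with microarray fold changes is directional:
both sides of 1; exact 1 on either side is indeterminate and leaves the
denominator.

## Pipeline and determinism

Stage order: QC → quantile normalization → PAM per disease contrast → SAM
on the treatment contrast → reversal per contrast → ΔΔCT (skipped without a
CT table). Every stage writes plain TSV/CSV/JSON artifacts so it can be
re-run in isolation, and per-stage counts are logged so the
records-surviving-each-filter chain is inspectable. All randomness derives
from the single config seed through fixed per-stage offsets; the report
carries no timestamp and is byte-identical across reruns of the same
config. Failure in any stage halts the run with the stage named; input
paths are checked before any computation.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at 150–5000
probes: 2000 probes for end-to-end reversal recovery and null calibration,
5000 probes over five seeds for signature recovery, the emulated 53 + 6
sample design throughout. These sizes give stable recovery statistics while
keeping a full run in seconds; results at genome scale (~54k probe sets)
differ only in runtime.

## Known limitations

- The QC present-call gate is a proxy; true detection p-values need
  probe-level input, which is out of scope (as is gcRMA background
  correction — the normalization entry point accepts any upstream-corrected
  matrix, and a hook exists where background correction would run).
- The permutation null is exchangeable-samples; no batch or pairing
  structure.
- Multiclass (>2) shrunken-centroid analyses are fit but reversal direction
  calls assume one disease class against one normal class per contrast.
- The synthetic generator's independence assumptions understate the
  false-discovery pressure of correlated real arrays; classifier counts on
  real data will be more threshold-sensitive than the synthetic plateaus
  suggest.
- The qPCR concordance p-value reported is the group-comparison t-test on
  ΔCT; no attempt is made to model a correlation statistic between
  platforms.
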