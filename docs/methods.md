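# Methods

## Model and procedure

The caller treats differential expression as a group-consistency question,
not a magnitude question. Each sample either clears a biological-relevance
threshold for a probe or it does not; significance then rests on whether
the treated group accumulates more same-direction flags than label
permutation can explain. Beyond the threshold, magnitude is deliberately
ignored: in short studies the measured level of induction depends strongly
on sampling time, whereas the direction of change is transferable.

### Step 1: flagging

Per probe, log10 ratios are taken against the *arithmetic* mean of the
control group's linear intensities (not the geometric mean — the reference
is a mean intensity, not a mean log). A (probe, sample) is flagged when
|log-ratio| ≥ θ_r and platform p ≤ θ_p.

* **θ_r = 0.097** by default. This is the printed working value for a
  1.25-fold cutoff, and the implementation is deliberately literal about
  it: log10(1.25) = 0.09691 < 0.097, so a sample at exactly 1.25-fold does
  not pass. Users who want the exact fold boundary can pass
  `theta_from_fold(1.25)` (or `--fold 1.25` on the CLI, which sets
  θ_r = log10(fold)).
* **θ_p = 0.1** by default, applied to a per-measurement platform p-value.

Directional counts S (up) and R (down) are taken per group. A treated-group
tie S = R > 0 marks the probe non-interpretable and removes it from step 2;
the rule is scoped to the treated group because step 2 compares groups
within one direction, where mixed control behaviour is informative rather
than disqualifying. Probes whose control-pool mean is zero are excluded
outright and reported.

A structural consequence of ratioing against the pool's own mean: k control
samples at fold f above the mean force k·f ≤ n_c, so with f > 1.25 at most
3 of 5 controls can flag up, and at most 4 of 5 can flag down (four small
values, one large). The one-direction maximum is therefore 4 for n_c = 5,
which fixes the row range of the FDR grid below.

### Platform p-values

The platform's own error model is treated as an input. Three modes:

* `passthrough` — a user-supplied p matrix, used verbatim;
* `control-spread` (default) — a documented stand-in: per probe, a z-score
  of each sample's log-ratio against the SD (ddof = 1) of the control
  samples' log-ratios, converted to a two-sided normal p. An SD floor of
  10⁻³ guards probes whose simulated control replicates coincide. Two-sided
  was chosen because the flagging criterion is two-sided; nothing in the
  procedure depends on the choice once θ_p is calibrated against it.
* `disabled` — p ≡ 0; flagging reduces to the fold-change criterion. This
  is also what the brute-force test oracles use, keeping them independent
  of the z-model.

### Step 2: permutation FDR

The null for a probe is that its flagged samples are distributed between
the groups only by labelling. All C(n_c + n_t, n_t) label partitions are
enumerated (252 for 5 vs 5; the observed labelling is necessarily among
them) and **step 1 is recomputed in full for each partition** — pool mean,
log-ratios, p-values, flags, counts. The cheaper alternative of freezing
the observed flags and re-partitioning them is available
(`null_mode="label-shuffle"`) but is not the default: with frozen flags the
null collapses to a hypergeometric draw and misses the way a shifted probe
drags the permuted pool mean with it. Above `max_perms` partitions
(default 100,000) a uniform sample of distinct partitions is drawn with an
explicit seed (default 1). Designs with fewer than 10 samples in total
trigger a warning: 70 partitions (4 vs 4) is too coarse a null for stable
FDR estimates.

Probes are histogrammed over cells (t, j), pooling up- and down-dominant
probes into one grid; j ∈ 0..n_t, t ∈ 0..(n_c + n_t − 1), the upper bound
following the pool-mean constraint above. Probes with zero treated flags
sit in column j = 0 (t from the larger control count — the choice cannot
affect calls, since j = 0 fails the treated-majority rule). Per cell,

    FDR_tj = (mean permuted count) / (observed count),  clipped to [0, 1],

with the mean (not median) across permutations as the numerator, the
standard choice for permutation FDR. Observed-empty cells are defined as
FDR 1 (nothing to call); occupied cells never reached under permutation get
FDR 0. Because the observed partition is part of an exhaustive plan, an
occupied cell's FDR is bounded below by 1/252 rather than 0 unless the
probe count in that cell grows. Per-cell FDR can be non-monotone in j at
sparse cells; `FDRMatrix.monotone()` provides a running-minimum variant,
off by default because the per-cell definition is the primary one.

Significance: FDR_tj ≤ q (default 0.05), strict treated majority
(j > t − j), interpretable probe. The per-probe representative fold change
is the signed linear fold from the mean treated log-ratio — the usual
"averaged fold across the treatment group" convention — and is what the
probe→gene collapse maximises.

## SAM comparator

Implemented from the original definition rather than wrapped: d = (group
mean difference) / (pooled SE + s0) on log2 intensities, s0 by the
percentile search minimising the coefficient of variation of windowed MADs
of d. Calling uses the delta band between observed and permutation-expected
order statistics; the per-delta FDR numerator is the median permuted call
count (mean available). Delta tuning targets an estimated FDR within 10%
*under* the target (i.e. in [0.9·q, q]), falling back to the smallest delta
with FDR ≤ q, then to the largest delta with a warning — the only reading
of "fine-tune delta so the FDR lands just under the target" that yields a
well-defined rule. The default delta grid spans the 50th percentile to the
maximum of |d − d̄| in 10 steps; pass an explicit grid for finer tuning.
Zero intensities are floored at the smallest positive matrix entry before
log2.

## Synthetic data

The generator emulates a small two-group array study: per-probe baseline
log10 intensity ~ N(2.5, 0.5) (mid-range signal over ~3 decades),
i.i.d. Gaussian noise on the log10 scale per (probe, sample) (default
SD 0.05, ~12% CV — a typical within-group spread for array replicates),
multiplicative DE shifts of chosen fold and direction applied to
responding treated samples, per-(probe, sample) non-responders, and
symmetric control outliers at a chosen fold. Everything derives from one
`numpy` Generator seed; equal seeds give bit-identical matrices.

What it does *not* emulate: probe-level array artifacts, intensity-
dependent variance (noise is homoscedastic in log space), correlated
samples, or heavy-tailed biological variation. Tests passing on this
generator therefore demonstrate the algorithmic properties of the caller
(calibration of the permutation null, tolerance of non-responders, the
contrast with variance-based calling), not performance on any real
platform's noise.

## Problem sizes and numerical choices

The validation suites run the full recompute-per-partition null on
2,000-probe (calibration, three seeds) and 5,200-probe (spiked recovery)
matrices with the exhaustive 252-partition plan — large enough for stable
cell counts at the default thresholds, and a size at which the vectorised
per-partition recomputation completes in about a second. Oracle-equivalence
tests run tiny inputs (≤ 10 × 10) against pure-Python brute-force
re-implementations. Ratios are floored at 10⁻¹² before log10 so
zero intensities yield large finite negative log-ratios (flagged down)
instead of -inf; FDR division guards observed-zero cells before dividing.
Probe→gene collapse breaks |fold| ties by input order and logs the tie.

## Known limitations

* The FDR grid is estimated from the same data being called; with very few
  probes the cell counts (and hence FDR values) are unstable.
* Exactly-repeated responder subsets are partially rediscovered by the
  exhaustive null: a probe responding in exactly the same 3 of 5 treated
  samples as the observed labelling keeps cell (3, 3) FDR near
  C(7,2)/252 ≈ 0.083, structurally above q = 0.05. Sensitivity at j = 3
  is therefore data-dependent, exactly as per-cell permutation FDR implies.
* Designs below 5 + 5 are supported but warned against; the 70-partition
  null of 4 vs 4 quantises FDR too coarsely.
* Only two-group unpaired designs; no paired, multi-class or
  dose-response variants.
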