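# Methods

## Input model: renewal pulse protocols

Time is discretized to a 1-minute grid throughout; light pulses are
point events on grid points. A protocol is an interval distribution
p(I) over integer minutes (`IntervalDistribution`). Because intervals
are i.i.d., the pulse indicator process is a renewal process and the
conditional pulse probability at a timepoint depends only on the time
since the previous pulse: the hazard h(L) = p(L) / P(I ≥ L), with
h(max support) = 1 (a pulse is forced once only the longest interval
remains). The input entropy rate is 60 · H(I)/E[I] bit/h, where H is
the Shannon entropy of the interval law in bits. Entropy is computed in
nats internally and converted to bits once, at the reporting boundary.

The experimental stimulation sequence is represented by its interval
occurrence counts (support 5–35 min, 57 intervals, 1010 min ≈ 17 h);
these counts give an entropy rate of 16.44 bit/h. The full
experimental ordering is not reproduced; orderings for synthetic runs
are built by `order_intervals`, which assigns to each interval length
with m occurrences the reference-law quantiles at levels j/(m+1) as
predecessor targets and chains the multiset greedily (closest pending
target to the interval just emitted, deterministic under a seed; if
targets cannot be met the ordering is best-effort and a warning is
logged). The reference law is explicit — by default the Gamma(shape 4,
scale 5 min) design target, discretized to 1-min bins — because the
choice between the design law and the empirical multiset is not
determined by the sequence itself.

Hazard probabilities are clipped to [1e-4, 1 − 1e-4] before logit
transforms; the forced pulse at the maximum interval would otherwise
contribute an infinite prior logit.

## Synthetic track generator

The generator emulates what the estimator consumes, not receptor
biochemistry. Each cell draws a phenotype: responder flag
~ Bernoulli(responder fraction), responder peak amplitude log-normal
(default median 0.4 in negative-log trajectory units, log-sd 0.3),
nuclear-import dip amplitude a fixed fraction (0.25) of the peak,
optoFGFR expression log-normal. A pulse adds a deterministic kernel to
the trajectory: a raised-cosine dip maximal 2 min post-pulse (gone by
6 min) minus-signed, and a raised-cosine peak maximal 7 min post-pulse
decaying below 5% by 20 min — the measured peak times; only the peak
times and qualitative shape are constrained by data, and smooth cosine
bumps are the simplest shape with those properties. Refractoriness
scales the whole response by 1 − 2^(−L/halftime) of the preceding
interval L (halftime default 9 min, matching the ~8–10 min effective
refractory time of the RTK/ERK channel; `None` disables it, emulating
the fast-recovering RTK/calcineurin channel, refractory time < 5 min).
Kernels from successive pulses superpose additively; per-frame Gaussian
noise (default sd 0.04 = one tenth of the default peak) is added; a
90-min unstimulated lead-in precedes the first pulse. Tracks are
emitted in the raw CSV schema with a shared per-frame illumination
factor, so the negative-log frame-mean normalization is exercised (and
exactly cancelled) downstream. Default responder fraction is 0.6, in
the range of transmitting fractions seen across real conditions.

Non-responders are exactly zero-amplitude rather than weak responders:
mixtures of the two configs then have an unambiguous ground truth for
the transmitting split. What passing tests show is therefore recovery
under the model's own assumptions — Gaussian frame noise, additive
superposition, deterministic kernel shape; they do not validate the
kernel shape or the noise law against real microscopy data, and real
cells with intermediate responsiveness will blur the split.

## Preprocessing

y(t) = −log(nuclear intensity / frame mean intensity); the sign makes
ERK-driven cytoplasmic translocation (nucleus emptying) positive.
Records with non-positive intensities are dropped and counted. Tracks
spanning < 180 min are removed (threshold inclusive: a 180-min track
stays). Gating on optoFGFR expression uses per-track means over
stimulated frames only and keeps tracks within [μ, μ+3σ] (BEAS-2B) or
[μ−0.5σ, μ+2σ] (STE-1), where μ, σ are track-length-weighted population
moments computed within each (cell line, replicate) cohort. Response
amplitude per pulse is y(pulse+7) − y(pulse), baseline-corrected by the
cohort average of y(p+L+7) − y(p+L) over pulses followed by a gap of at
least L+7 min, which cancels the relaxation tail of the previous
response (and any global drift) exactly. Responsiveness s is the
population standard deviation of all 7-min differences of a track,
over all observed frames. Missing frames are tolerated; any datapoint
or readout whose 7-min window is incomplete is dropped rather than
interpolated.

## Decoder and bitrate estimation

One datapoint per (track, timepoint k) with k strictly after the first
pulse, at or before the last, and y(k..k+r) observed. Feature vector
(length r+6 = 12, fixed order): log last, Δy₁..Δy₆, s, cell-line code
(STE-1 = 0, BEAS-2B = 1), and three inhibitor concentrations in µM
(not log-transformed). Features are standardized to zero mean, unit sd
over the training dataset; zero-variance columns pass through.

The MLP (40, 20 hidden units, leaky ReLU 0.01) outputs the logit update
u_Bayes; the posterior logit is u_Bayes plus the prior logit of the
clipped hazard. Training minimizes cross-entropy with Adam
(lr 1e-3) on minibatches of 10⁴ datapoints drawn by the two-stage
sampler: (interval, last) pairs from the protocol's joint law
P(I, L) = p(I)/E[I], then uniform within the matching dataset group.
Pairs absent from the training tracks (a fraction of a percent of
protocol mass at most, from track ends) are renormalized away with a
warning. 10% of tracks are held out; a protocol-weighted validation
cross-entropy (each datapoint weighted by q(pair)/count(pair), which is
deterministic — no sampling noise in the stopping signal) is evaluated
every 25 batches, training stops after 300 batches without improvement,
and the best weights are restored. The default budget is 3000 batches;
loss, batch size and architecture are fixed by the method, while the
optimizer, schedule and early stopping are package choices surfaced in
the estimator's parameters. The output layer is initialized near zero
so training starts at the prior (u_Bayes ≈ 0), which makes the
null-data fixed point (no improvement over the prior, bitrate ≈ 0)
explicit. Posterior probabilities are clipped to [1e-6, 1−1e-6] inside
the loss and the information accounting.

Pointwise information is log₂ p_post(x) − log₂ p_prior(x); the
population bitrate is its dataset mean × 60, single-cell bitrates are
within-track means × 60 with weights w_j = timepoint counts, and the
weighted-mean decomposition identity holds to float precision by
construction. The transmitting split sorts cells by (bitrate, track id)
— the tie-break makes it deterministic — and marks the longest prefix
with strictly negative weighted mean as non-transmitting;
`strict=False` switches to a non-positive threshold (the two readings
of "averages to a negative value"). Negative single-cell bitrates are
meaningful: that cell's responses mislead a decoder trained on the
population. Leave-one-replicate-out retraining
(`crossvalidate_by_replicate`) reports the held-out bitrate change per
fold as an overfitting check. A single decoder is trained across all
conditions and evaluated per condition without retraining.

## Protocol optimization and capacity

The optimization variable ϕ is the vector of unnormalized interval
log-probabilities on 5–90 min, normalized by softmax — an unconstrained
parametrization, so plain gradient ascent preserves normalization
exactly. Each step: freeze ϕ′ ← ϕ, draw a 10⁴ batch of (I, L) pairs
from q_ϕ′ with datapoints fetched from the experimental groups, compute
the importance-weighted objective (weights q_ϕ/q_ϕ′, all 1 at the
freeze point) and its analytic gradient — the score-function term plus
the prior-hazard term, with zero gradient through active clips — take
one ascent step (default step 0.05, 500 steps; the acceptance runs use
300) on the objective minus the smoothness penalty
α · mean((ΔΔ log p)²), α = 0.003. The analytic gradient is checked
against central finite differences in the test suite (relative error
< 1e-3 on a fixed batch).

Intervals above 35 min reuse the 35-min interval's trajectory slices:
elapsed time is preserved when < 10 min, time-to-next-pulse when that
is < 10 min, and the middle stretch is rescaled linearly and rounded to
the grid; the decoder always receives the true `last` in its feature
and prior. The justification is that measured responses saturate
beyond ~20-min intervals. Intervals below 5 min are excluded from the
support by default (cells rarely respond to them); the bound is
configurable, with the caveat that excluding them may underestimate
capacity for fast-recovering channels. Optimization runs on the
transmitting subpopulation determined under the experimental protocol,
since the split itself would otherwise depend on the protocol being
optimized.

Capacity is reported from a fresh 10⁵ evaluation batch under the final
distribution, decoupling the reported number from per-step sampling
noise. If the final distribution scores below the initial one (it has
not in practice), the initial protocol — which is in the feasible set —
is returned with a warning, so the reported capacity never falls below
the measured bitrate by construction.

## Numerical and design notes

- Initialization of ϕ adds a 1e-4 floor to the initial probabilities
  (the experimental law has no mass above 35 min) before the log; the
  reference "initial bitrate" is nevertheless evaluated under the exact
  initial law.
- The degenerate gating case σ = 0 keeps all tracks (window collapses
  to {μ}).
- `sample_pulse_sequence` draws i.i.d. intervals until the duration is
  exhausted; sequences built from interval multisets are padded 10 min
  past the last pulse so that every (interval, last) pair of the final
  interval yields complete feature windows.
- All randomness flows through `numpy` Generators seeded explicitly;
  same seed, same result, including training.

## Problem sizes and limitations

The recovery studies in the test suite and acceptance script use
populations of 200–500 cells over one ~18.3 h recording (90 min lead-in
+ 1010 min stimulation), decoders trained up to 3000 minibatches, and
300-step protocol optimizations; these sizes give stable estimates for
the synthetic generator's noise levels. Known limitations: the
estimator provides a lower bound, so undertrained decoders
underestimate the bitrate; the renewal assumption excludes
history-dependent encodings; the transmitting split is a population
construct (a cell's label depends on the cohort); capacity rests on the
long-interval imputation, which is an extrapolation beyond the measured
alphabet; and the synthetic generator's Gaussian, additively-superposed
responses are an idealization of real reporter noise.
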