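# pulsebit

Quantifies how fast a cellular signaling pathway transmits information.
Cells are stimulated with a pseudo-random train of short light pulses
(optogenetically activated receptor tyrosine kinases), and each cell's
response is read out as an ERK kinase-translocation-reporter (KTR)
trajectory sampled once per minute. `pulsebit` estimates the mutual
information rate between the pulse train and single-cell trajectories,
decomposes it into per-cell bitrates with a transmitting /
non-transmitting split, and optimizes the stimulation protocol in silico
to estimate the pathway's channel capacity. A synthetic track generator
with the same statistical structure as microscopy-derived track tables
makes the whole pipeline testable end to end.

It is aimed at quantitative cell biologists and systems biologists
analyzing pulsatile optogenetic stimulation experiments (or simulations
of them).

## The method

The input is a binary sequence X = X₁…X_N (one bit per minute: pulse or
no pulse) whose inter-pulse intervals are i.i.d. draws from an interval
distribution — a renewal process. The prior probability of a pulse at
time k then depends only on `last_k`, the minutes since the previous
pulse, through the renewal hazard h(L) = P(I = L)/P(I ≥ L).

A classifier p_θ predicts X_k from `last_k` plus a short slice of the
cell's trajectory (r = 6 consecutive 1-min differences Δy), the cell's
responsiveness s = Std(y_k − y_{k+7}), and condition covariates (cell
line, inhibitor concentrations). It is a small MLP (hidden sizes 40/20,
leaky ReLU) that outputs a logit *update* u_Bayes added to the prior
logit:

    logit p_θ(X_k = 1 | ·) = u_Bayes + logit p(X_k = 1 | last_k)

Training minimizes cross-entropy on minibatches whose (interval, last)
frequencies follow the assumed protocol. The bitrate lower bound is the
average surprisal reduction, in bits per timepoint × 60 = bit/h:

    b ≥ −E[ log p(x_k | last_k) − log p_θ(x_k | last_k, Δy, s, …) ]

Averaging the same pointwise quantity within one track gives single-cell
bitrates b_j with weights w_j (timepoints per track), which satisfy
b = Σ w_j b_j / Σ w_j exactly. Sorting b_j ascending and taking the
longest prefix with a negative weighted mean defines the
non-transmitting subpopulation; the rest transmit.

With the classifier frozen, the bitrate becomes a function of the input
interval distribution (it sets both the prior hazard and the sampling
law). `pulsebit` maximizes it by gradient ascent on softmax-parametrized
interval log-probabilities over 5–90 min, using importance weights
p_ϕ/p_ϕ′ sampled from a frozen copy ϕ′ (score-function gradient),
imputing responses to intervals beyond the measured 35 min from the
35-min interval, and regularizing with a second-difference smoothness
penalty (α = 0.003). The maximum is the channel capacity under renewal
encodings.

## Worked example

Simulate a 50/50 mixture of responding and non-responding cells under
the experimental stimulation sequence (57 intervals, ~17 h, input
entropy rate 16.4 bit/h), train the decoder, and estimate bitrates:

```python
from pulsebit.workflows import synthetic_bitrate_study

study = synthetic_bitrate_study(n_cells=60, responder_fraction=0.5,
                                noise_sd=0.04, refractory_halftime=9.0,
                                seed=7, n_batches=1200)
r = study.report
print(f"input entropy rate : {r.input_entropy_rate:.2f} bit/h")
print(f"population bitrate : {r.bitrate:.2f} bit/h")
print(f"transmitting cells : {100 * r.split.fraction_weighted:.1f}%")
print(f"transmitting mean  : {r.split.mean_bitrate_transmitting:.2f} bit/h")
print(f"non-transmitting   : {r.split.mean_bitrate_nontransmitting:.2f} bit/h")
```

prints

```
input entropy rate : 16.44 bit/h
population bitrate : 5.76 bit/h
transmitting cells : 68.3%
transmitting mean  : 8.44 bit/h
non-transmitting   : -0.00 bit/h
```

The input carries 16.44 bit/h; the population as a whole decodes
5.76 bit/h of it. The split assigns ~2/3 of cells to the transmitting
subpopulation (responders plus noise cells whose chance fluctuations
score weakly positive), which averages 8.44 bit/h, while the
non-transmitting prefix averages zero by construction. Per-cell
bitrates, the (interval, last) diagnostic table and the capacity
optimizer are available from `study.report` and
`pulsebit.ProtocolOptimizer`.

The same stages are exposed as a CLI:

```
pulsebit simulate --config cfg.yaml --seed 1 --out-dir data
pulsebit preprocess --tracks data/tracks.csv --pulses data/pulses.csv --out proc.csv
pulsebit train --tracks data/tracks.csv --pulses data/pulses.csv --model-out model.json
pulsebit estimate --tracks data/tracks.csv --pulses data/pulses.csv --model model.json
pulsebit optimize --tracks data/tracks.csv --pulses data/pulses.csv --model model.json
pulsebit run --config cfg.yaml --seed 1      # everything, into one directory
```

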