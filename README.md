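# apneadbn

Detection of obstructive apnea episodes from a single-lead ECG with
conditional linear Gaussian (CLG) dynamic Bayesian networks.

## The problem

Obstructive apnea briefly closes the upper airway; the struggle against the
obstruction leaves fingerprints on the ECG — the heart slows (the RR
interval lengthens) and the QRS complex changes shape as respiratory effort
modulates the electrical axis. This package models those beat-to-beat
fingerprints probabilistically and turns them into an episode detector
operating on 15-second epochs, much finer than the 1-minute epochs common in
sleep-apnea screening. It is built around the experimental protocol used in
anesthetized-rat models of obstructive sleep apnea: five subjects, three
15-minute recordings each, with 15-s obstructions applied at 20, 40 or 60
events/hour. Because such animal recordings are not publicly deposited, the
package ships a fully seeded synthetic generator of the whole protocol, so
every stage is testable end to end.

## The model

Per heartbeat t, let `Ap_t ∈ {0,1}` be the hidden apnea indicator and
`y_t` the observed markers (RR interval; R and S amplitudes Ra, Sa; their
difference RSd; QRS up/down slopes US, DS; or the PCA combination QRSpca).
A dynamic Bayesian network of Markov order L ties slice t to slices
t−1 … t−L with a time-homogeneous structure. The joint factorizes as
`P(X) = Π_i P(X_i | pa(X_i))`; discrete nodes carry conditional probability
tables (and may have only discrete parents), while each continuous node is
conditionally Gaussian,

    f(z | z_D, z_C) = N(z; α(z_D) + β(z_D)ᵀ z_C, σ²(z_D)),

switched by its discrete parents. Structure is learned by dynamic max–min
hill-climbing (a candidate-parent screen followed by BIC-scored greedy
search, first intra-slice then across slices), parameters by maximum
likelihood. Detection computes the exact filtering density
`p(Ap_t | y_{1:t})` by a forward recursion over the 2^L recent-history
states, smooths it with a 40-beat moving average, and classifies each 15-s
epoch as apneic when the RMS of the smoothed posterior reaches a threshold
δ (default 0.2). Performance is scored by sensitivity, specificity,
accuracy and rank-based AUC under two protocols: *ideal record-specific*
(train and test on the same recording) and *record-specific* (train on each
subject's first recording, test on the other two).

## Worked example

```python
from apneadbn import ApneaDBN
from apneadbn.simulate import GeneratorParams, generate_protocol, generate_marker_series

schedule = generate_protocol(n_rats=1, seed=7).recordings[0]   # 15 min, F=20/40/60
train = generate_marker_series(schedule, GeneratorParams(), seed=7)

results = ApneaDBN(train, markers=("RR", "DS"), order=5).fit()
print(results.summary())
```

prints (abridged):

```
Apnea CLG-DBN results
====================================================
markers:        RR, DS
Markov order:   5
beats (train):  5979
arcs:           10
log-likelihood: -12847.814
BIC:            -12952.156
training RMSE:  0.1415
----------------------------------------------------
arcs (parent -> child):
  Ap@0 -> DS@0
  Ap@0 -> RR@0
  Ap@1 -> Ap@0
  DS@0 -> RR@0
  DS@1 -> DS@0
  RR@1 -> RR@0
  ...
```

The learned arcs say: apnea persists beat to beat (`Ap@1 -> Ap@0`), slows
the heart and shifts the R downstroke (`Ap@0 -> RR@0`, `Ap@0 -> DS@0`),
and both markers are autocorrelated. The training RMSE of 0.14 means the
filtered posterior sits close to the true 0/1 labels. Detection on a second
recording of the same schedule:

```python
test = generate_marker_series(schedule, GeneratorParams(), seed=8)
epochs = results.detect(test, intervals=schedule.episodes,
                        duration_s=schedule.duration_s, delta=0.2)
from apneadbn.detection import score
print(score(epochs).to_dict())
```

```
{'TP': 5, 'FP': 1, 'TN': 54, 'FN': 0, 'Se': 100.0, 'Sp': 98.18...,
 'Acc': 98.33..., 'AUC': 0.9963...}
```

i.e. all five provoked episodes found, one false epoch out of 55 normal
ones. A command-line interface mirrors the pipeline
(`apneadbn simulate | extract | detrend | train | infer | detect |
evaluate`).

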