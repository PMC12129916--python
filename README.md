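# sinkvec

Interictal iEEG biomarker of the epileptogenic zone (EZ) based on the
leading right eigenvector of windowed linear dynamical network models.

Epilepsy surgery depends on localizing the EZ — the cortical region that
generates seizures. Clinical localization requires days-to-weeks of
invasive monitoring to capture seizures. This package implements an
*interictal* (between-seizure) alternative: from a few minutes of
multichannel intracranial EEG, it estimates a linear time-varying
dynamical network model and reads the EZ out of the model's steady-state
structure. It is written for researchers working on quantitative iEEG
biomarkers and network models of epilepsy.

## The model and the biomarker

Each non-overlapping 500 ms window of preprocessed iEEG is modelled as a
linear time-invariant system

```
x(t+1) = A x(t) + e(t)
```

where `x(t) ∈ R^N` holds the `N` channel voltages, `e(t)` is white
Gaussian noise, and `A` is estimated per window by least squares. Entry
`A_ij` is the influence of channel `j`'s current activity on channel
`i`'s next sample, so a channel with a strong row of `A` receives much
network influence (a **sink**) and one with a strong column exerts much
influence (a **source**).

Because the noiseless trajectory satisfies `x(t) = A^t x(0) ≈ λ₁ᵗ α₁ v₁`
for large `t`, the leading right eigenvector `v₁` (eigenvalue of largest
modulus) is the direction of the steady state: its largest components
mark the channels where network activity accumulates — the sinks. The
per-channel biomarker is the component of `v_avg`, the average of the
per-window leading eigenvectors; the per-patient biomarker is the
contrast

```
θ = mean(v_avg over EZ channels) − mean(v_avg over non-EZ channels),
```

which is large when the clinically annotated EZ coincides with the
network's sinks. Cross-validated logistic regressions evaluate two
questions: can per-channel features classify EZ vs non-EZ channels
(leave-one-patient-out), and does θ predict surgical success (Engel 1)
vs failure (Engel 2–4) (stratified 10-fold CV)? Source-sink metrics
derived from the row/column norms of `A` are included as a comparison
feature set.

Since clinical iEEG cannot be redistributed, the package ships a
synthetic-cohort generator that plants sink channels in stable random
networks (spectral radius 0.95) and simulates stationary recordings, so
the whole pipeline is testable end to end.

## Worked example

The three-node network

```python
import numpy as np
from sinkvec import leading_eigvec

A = np.array([[0.2, 0.6, 0.0],
              [0.5, 0.3, 0.8],
              [0.0, 0.7, 0.9]])
pair = leading_eigvec(A)
print(round(pair.lam, 3))   # 1.487
print(np.round(pair.v, 4))  # [0.287  0.6155 0.734 ]
```

has its largest eigenvector component on node 3 — the node with the
largest row norm of `A`, i.e. the strongest sink. On simulated data the
full pipeline recovers planted sinks:

```python
from sinkvec import synth, DynamicalNetworkModel

net = synth.make_sink_network(N=12, n_sinks=2, rho=0.95, seed=7)
snap = synth.simulate_snapshot(net, fs=1000, duration_s=10, noise_sd=1.0, seed=7)
mask = np.zeros(12, bool); mask[sorted(net.sink_set)] = True
res = DynamicalNetworkModel.from_arrays(snap.samples, snap.fs,
                                        ez_mask=mask, apply_car=False).fit()
print(res.summary())
```

prints

```
Dynamical Network Model Results
==============================================
Channels:            12
Windows fitted:      20
Window length:       500 ms
Sampling rate:       1000 Hz
Mean |lambda_1|:     0.9269
v_EZ (mean EVC, EZ): 0.6280
v_nEZ (non-EZ):      0.1272
theta (contrast):    +0.5008
----------------------------------------------
Top channels by averaged eigenvector component:
  CH012        0.6910  [EZ]
  CH005        0.5650  [EZ]
  CH001        0.1645
  CH008        0.1527
  CH002        0.1344
```

The two planted sinks (channels 5 and 12) top the eigenvector ranking,
and θ ≈ +0.50 reflects an accurately annotated EZ. A mis-annotated
patient (EZ mask disjoint from the true sinks) gives θ ≈ 0, which is the
mechanism behind outcome prediction: failed surgeries are modelled as
mislocalized EZ annotations.

A command-line interface mirrors the library
(`sinkvec synth | preprocess | fit | biomarkers | classify-ez |
classify-outcome | run`); every run writes its resolved configuration
next to its outputs.

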