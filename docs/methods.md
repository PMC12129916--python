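# Methods

## Model

Each preprocessed iEEG snapshot is segmented into non-overlapping 500 ms
windows and each window is modelled as a first-order linear dynamical
network, `x(t+1) = A x(t) + e(t)`, with `x(t)` the vector of channel
voltages and `e(t)` white Gaussian innovations. This is the lag-1
special case of a multivariate autoregressive model; the time-varying
model for a whole snapshot is the ordered sequence of per-window `A`
matrices. The per-window `A` is the ordinary least-squares solution of
the one-step regression over the window's consecutive sample pairs, with
no intercept and no demeaning: the 0.5 Hz high-pass already removes
offsets, and an intercept would break exact recovery of a noiseless
generator. Rank-deficient windows return the minimum-norm solution
(`numpy.linalg.lstsq`) rather than failing, because short windows at low
sampling rates with many channels can be ill-conditioned; an optional
ridge penalty exists but defaults to zero.

Assumptions worth stating plainly: linearity and short-horizon
stationarity (within 500 ms), Gaussian innovations, and a strictly
dominant leading eigenvalue when the steady-state reading is invoked.

## Biomarker

For each window the modulus-largest eigenpair of `A` is extracted with a
dense eigensolver. The eigenvector is normalized to unit Euclidean
length and mapped to a fixed representative: element-wise modulus when
the pair is complex, otherwise the sign making the component sum
nonnegative. The per-channel biomarker is the component-wise mean of the
representatives across windows (`v_avg`); the per-patient statistic is
`θ = mean(v_avg[EZ]) − mean(v_avg[non-EZ])`. The modulus convention for
complex pairs preserves the "which channels dominate the steady state"
interpretation and is independent of basis sign.

Source-sink metrics are provided as comparison features. Their exact
published formulas belong to earlier work; here they follow a documented
convention: Euclidean row and column norms of `A`; a 2-D rank space with
row-norm rank (incoming influence) and column-norm rank (outgoing); a
sink index equal to 2 minus the distance from the ideal sink corner
(larger = more sink-like, always nonnegative); and mean received
connection strength from the most source-like and most sink-like
quartiles. Nothing downstream depends on their absolute values — only on
rank behaviour, which is what the tests assert.

## Preprocessing

Defaults follow standard clinical practice: fourth-order Butterworth
bandpass 0.5–300 Hz applied forward-backward (zero-phase, so filter
group delay cannot skew the lag-1 regression), zero-phase notches at the
60 Hz line frequency and its harmonics below min(Nyquist, bandpass edge)
with a 2 Hz stopband, channel exclusion (bad/white-matter channels, all
exclusions before re-referencing so that broken channels never corrupt
the reference), common average reference (CAR), then windowing at
`round(0.5 · fs)` samples with the trailing partial window discarded.

One consequential finding is documented here because it shapes the
synthetic experiments: CAR projects the data onto the subspace with zero
across-channel mean. Eigenvectors of transition matrices estimated from
CAR'd data therefore have component sums near zero, which makes the
sign-fixing convention for real eigenvectors degenerate — the chosen
sign flips essentially at random from window to window and the average
cancels. On clinical recordings CAR removes large common-mode artifacts
and is worth this cost; the synthetic generator's innovations are
channel-independent, so its data contain no common mode and CAR would
only remove signal. The synthetic-cohort pipeline consequently applies
the bandpass and notch filters but not CAR, while the clinical default
configuration keeps CAR. Both are explicit, serialized configuration
flags (`apply_car`, `apply_filters`).

## Synthetic cohorts

The generator emulates the study conditions of multicenter interictal
sEEG: by default 95 channels, 1 kHz sampling, 5-minute snapshots, unit
innovation standard deviation, and two planted sink channels per
patient. Sinks are planted by scaling a dense uniform nonnegative base
matrix — sink rows up, sink columns down (gain 4, with a deterministic
extra rescale guaranteeing sink row norms at least twice any other row
norm) — and the whole matrix is rescaled to spectral radius ρ = 0.95:
stationary, but near the instability that the epilepsy literature
associates with seizure-prone networks. (The worked three-node example's
λ₁ = 1.487 is unstable and is used for algebra only; eigenvectors are
invariant to positive scaling, so a stable multiple of that matrix seeds
simulations.) Snapshots iterate the dynamics from zero with Gaussian
innovations and discard a burn-in of 10·N samples, after which the
process is stationary.

A cohort contains "success" patients (Engel 1), whose annotated EZ
equals the planted sink set, and "failure" patients (Engel 2–4), whose
annotated EZ is drawn disjoint from the true sinks — mis-annotation
being the standing explanation for failed surgery. The rule
`misannotation_rule="identical"` provides the null construction in which
the two groups are indistinguishable.

What the generator does *not* emulate: 1/f spectra, oscillatory rhythms,
interictal spikes, nonstationarity across vigilance states, volume
conduction, or common-mode artifacts. Passing tests therefore show that
the estimator, eigenvector averaging, contrast, and cross-validation
machinery are correct under the model's own assumptions — not that the
biomarker separates outcomes in clinical data.

## Classification experiments

EZ-channel prediction uses leave-one-patient-out cross-validation on
channel-level features; outcome prediction uses stratified 10-fold CV on
patient-level EZ-minus-nonEZ feature differences (for the eigenvector
model this is exactly θ). Three feature sets are supported: eigenvector
only, source-sink metrics only, and combined. Models are unpenalized
maximum-likelihood logistic regressions (a ridge strength is exposed,
default off; no class reweighting by default). The decision threshold is
chosen on the training fold only, by maximizing Youden's
J = sensitivity + specificity − 1 over the ROC operating points of the
rule `score ≥ threshold`, ties broken toward the smaller threshold —
the standard ROC-based choice where none is otherwise specified.
Accuracy, sensitivity and specificity are reported per fold and as
means, in percent; an undefined ratio (a fold with a single truth class)
is reported as NaN with a warning and excluded from means. Stratified
folds are seeded and the seed is recorded in the serialized results.

## Numerical choices

- Leading-eigenvalue ties within 1e-12 in modulus are broken toward the
  larger real part with a warning; a complex-conjugate pair is not
  treated as a tie (both members give the same representative).
- `steady_state_direction` renormalizes at every step so unstable
  matrices cannot overflow and stable ones cannot underflow.
- Degenerate inputs fail loudly: windows shorter than two samples,
  non-finite data, single-channel CAR, all-true/all-false EZ masks,
  single-class training folds, annotation labels that match no channel.
- Uninformative or inverted classification scores (Youden's J ≤ 0
  everywhere) warn and return the degenerate threshold instead of
  failing, matching how an uninformative feature should behave inside a
  CV loop.

## Problem sizes in the test suite

The test suite and the acceptance script run the full pipeline at
reduced scale — cohorts of 20 + 20 patients with 30 channels, 30 s at
500 Hz, and recovery experiments with 12 channels and 5 s of data — our
choice of the smallest sizes at which the planted structure is
recovered essentially at ceiling, so the checks exercise every stage
without redundant computation. The generator's defaults remain at the
clinical scale (95 channels, 5 minutes, 1 kHz), and nothing in the
implementation depends on problem size.

## Known limitations

- The estimator is the correct maximum-likelihood fit only under the
  model's own linear-Gaussian assumptions; on clinical data the model is
  a deliberate simplification.
- With ~95 channels and 500 ms windows at ≤512 Hz the regression is
  underdetermined per window; the minimum-norm solution is then one of
  many exact fits, and biomarker stability relies on averaging across
  many windows.
- The source-sink metrics are a convention, not a reproduction of the
  published index; comparisons should use ranks.
- θ requires at least one annotated EZ channel and one non-EZ channel;
  cohorts without both surgical outcomes cannot run the outcome
  experiment.
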