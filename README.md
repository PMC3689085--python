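# selfemg

Self-enhancing LDA/QDA classifiers for continuous surface-EMG pattern
recognition.

## The problem

Pattern-recognition myoelectric control maps multi-channel surface EMG to
discrete hand/wrist motion classes: a 200 ms analysis window slides in 25 ms
steps over the signal and each window is classified, producing a continuous
decision stream for a prosthesis controller.  EMG is nonstationary over hours
(electrode impedance, sweating, fatigue), so a classifier trained once
degrades as a session progresses.

`selfemg` implements a *self-enhancing* remedy: after the Gaussian
discriminant classifier labels a testing window `z` as class `k`, it folds
`z` into its own parameters with rank-one recursions and discards the data.
With pre-update class count `n_ck` and total count `N`:

    mu_k'     = (n_ck mu_k + z) / (n_ck + 1)
    C_k       = n_ck/(n_ck + 1) (z - mu_k)(z - mu_k)^T
    Sigma_k'  = n_ck/(n_ck + 1) Sigma_k + C_k/(n_ck + 1)    (SEQDA)
    Sigma_W'  = N/(N + 1) Sigma_W + C_k/(N + 1)             (SELDA)

Under the maximum-likelihood covariance normalisation these recursions are
*exactly* a batch refit on the training data plus the predicted-labelled
stream, computed with O(d^2) memory.  The decision rule is the Gaussian
discriminant score

    g_i(x) = log p(w_i) - (x - mu_i)^T Sigma^-1 (x - mu_i) / 2  [- log|Sigma_i| / 2]

with the pooled covariance `Sigma_W` for LDA and per-class `Sigma_i` for QDA.

The package also provides the two standard EMG feature sets (6th-order Burg
AR coefficients + RMS, and Fourier-derived cepstral coefficients: the DCT of
the log-magnitude DFT of the window), a synthetic drifting-EMG generator, and
an evaluation harness with recognition-accuracy metrics, parameter-drift
diagnostics and paired-t comparisons.

## Worked example

```python
import selfemg as se
from selfemg.features import WindowSpec, extract_features, segment_windows

# one simulated subject: 10 motions, 4 channels, 1 kHz, 20 cycles of
# 5 s contraction / 5 s rest, with slow cross-cycle drift
protocol = se.ProtocolSpec(seed=1)
record = se.simulate_recording(protocol, drift=se.DriftSpec(delta=se.BENCHMARK_DELTA))

config = se.RunConfig()
feats = extract_features(
    segment_windows(record, WindowSpec.from_config(config, record.fs)), "FC", config
)

static = se.evaluate_protocol(record, config, mode="qda", policy="none",
                              features=feats, train_cycles=6)
enhanced = se.evaluate_protocol(record, config, mode="qda", policy="mc",
                                features=feats, train_cycles=6)
print(f"QDA   {static.overall_ra:.2f}%  (first->last cycle: "
      f"{static.per_cycle_ra[0]:.1f} -> {static.per_cycle_ra[-1]:.1f})")
print(f"SEQDA {enhanced.overall_ra:.2f}%")
```

Output:

```
QDA   93.59%  (first->last cycle: 96.6 -> 87.6)
SEQDA 98.67%
```

The static QDA starts near 97% and loses ~9 points by the last testing cycle
as the simulated signal drifts away from the training condition; the
self-enhancing SEQDA tracks the drift through its own predictions and holds
~99%.  `static.cumulative_ra`, `per_class_ra`, `per_trial_ra` and
`confusion` carry the finer-grained metrics; `se.drift_diagnostics` tracks
the geometry (mean lengths, principal-axis lengths and angles) of the
adapting classes.

A `selfemg` command-line tool wraps the same pipeline
(`selfemg simulate / extract / train / stream / evaluate / compare`).

## Acceptance script

`scripts/acceptance.py` re-runs the headline computation from scratch:
it simulates one full-scale drifting subject, extracts FC features, and
evaluates static LDA/QDA against SELDA/SEQDA on the streamed testing cycles,
printing the recognition accuracies and writing a JSON result file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
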