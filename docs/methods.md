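# Methods

## Model

Each motion class `w_i` (i = 1..C) is modelled as a multivariate Gaussian
over the d-dimensional window feature vector, with mean `mu_i` and covariance
`Sigma_i`.  Classification maximises

    g_i(x) = log p(w_i) - (x - mu_i)^T Sigma^-1 (x - mu_i)/2  [- log|Sigma_i|/2]

where `Sigma = Sigma_W` (pooled within-class covariance) for LDA and
`Sigma = Sigma_i` for QDA; ties go to the lowest class index.  The
log-determinant term is included by default (`include_logdet=True`): it is
required for Bayes-optimal QDA with unequal covariances.  A flag disables it
to reproduce the bare quadratic form, since either convention appears in the
myoelectric-control literature.

### Covariance normalisation

The package uses the maximum-likelihood normalisation `Sigma_i = S_i / n_i`
and pooled `Sigma_W = sum_i (n_i / N) Sigma_i` everywhere by default.  This
is a deliberate choice: the streaming update recursions below are only
*exact* (identical to a batch refit) under the ML divisor.  An `unbiased`
option (`n_i - 1` divisor, `(n_i - 1)/(N - C)` pooled weights) exists for
static baselines; it must not be combined with streaming updates.

### Priors

`p(w_i)` defaults to relative class counts `n_i / N` (near-uniform for the
balanced protocols here); a uniform option exists.  Under counts mode the
priors track the growing counts during streaming.

## Self-enhancing updates

After a testing window `z` is classified as class `k` (using the
*pre-update* parameters), the model absorbs it:

* mean: `mu_k' = (n_ck mu_k + z)/(n_ck + 1)`
* correction: `C_k = n_ck/(n_ck+1) (z - mu_k)(z - mu_k)^T`, taken about the
  pre-update mean — the only reading under which the scatter identity
  `S_k' = S_k + C_k` holds exactly
* SEQDA: `Sigma_k' = n_ck/(n_ck+1) Sigma_k + C_k/(n_ck+1)` (class k only)
* SELDA: `Sigma_W' = N/(N+1) Sigma_W + C_k/(N+1)` (pooled only; per-class
  covariances are not maintained, they do not enter the LDA rule)

Counts increment under every non-static policy, including the means-only (M)
and covariances-only (C) ablations, so that repeated application matches the
recursions' own bookkeeping.  Under policy C the correction is computed about
the frozen training mean.  Every historical window keeps equal weight; there
is no forgetting factor.  Updates use predicted labels only — ground truth is
visible solely to the evaluation scorer, and the stream engine accepts a
one-window-at-a-time iterator, so memory is O(C d^2) regardless of stream
length.

With both updates active (policy MC), the final parameters equal a batch ML
fit on training data plus the predicted-labelled test windows to ~1e-15
relative error; the test suite asserts 1e-8 across d in {2, 8, 28} and
C in {2, 10}.

## Features

* **AR+RMS**: 6th-order Burg autoregressive coefficients per channel (monic
  convention, `x[n] + sum a_k x[n-k] = e[n]`; Burg keeps all reflection
  coefficients in [-1, 1], hence stable models), plus window RMS.  A
  zero-variance window returns zero coefficients rather than dividing by
  zero.  d = 7 x n_channels.
* **FC**: full-N-point DFT of the raw window, `Y_k = log(|X[k]| + eps)` with
  `eps = 1e-12` guarding zero bins, then the first 7 DCT-II coefficients of
  Y over all N bins.  The sum deliberately runs over the full
  conjugate-symmetric spectrum, and no taper or detrending is applied.  The
  FFT+DCT fast path matches a literal O(N^2) double sum to 1e-9 relative.
  d = 7 x n_channels.

With 4 channels both sets are 28-dimensional.  (These feature sets are
sometimes described as 24-dimensional in the literature, which is
inconsistent with the per-channel make-up above; other dimensionalities are
reachable through `ar_order`, `n_fc` and the channel count.)

Windows (200 ms, 25 ms increment by default) are taken only from annotated
non-rest segments and never straddle a segment boundary; a 5 s contraction
yields floor((5000-200)/25)+1 = 193 windows.  Transitional windows at
contraction/rest boundaries are discarded.

## Synthetic data generator

The generator emulates 4-channel, 1000 Hz recordings of 10 motion classes
performed as 5 s contractions separated by 5 s rest, in repeated cycles
(protocol 1: 6 training + 14 testing cycles; protocol 2 adds a between-
session step change).  Within a window the signal is wide-sense stationary:
white Gaussian excitation through a stable order-4 all-pole filter (two
conjugate pole pairs, angles in the 20–500 Hz band), scaled by a
class/channel gain, with 100 ms raised-cosine ramps, additive low-level
sensor noise, and a log-normal trial-to-trial contraction-strength jitter
(sd 0.10) shared by all windows of one contraction.

Classes are drawn as small offsets around a shared per-channel base spectrum
(class pole-frequency sd 10 Hz, class log-gain sd 0.12): this mirrors the
fact that real motions drive overlapping muscle groups, and it places the
10-class recognition accuracy in the mid-90s rather than at a trivial 100%.

**Drift.**  Nonstationarity is a linear-in-cycle displacement of gains and
pole angles; `delta = 1` traverses one between-class standard deviation of
each drifted parameter over the testing span, and `delta = 0` is exactly
stationary.  `BENCHMARK_DELTA = 1.0` was calibrated (as the evaluation
design prescribes) so that a static QDA's per-cycle accuracy declines by at
least 5 points from the first to the last testing cycle; measured declines
on seeds 1–5 are 9.1/6.5/5.8/18.6/27.9 points, while SEQDA(MC) gains
+7.8 points mean RA over QDA and SELDA(MC) +7.4 over LDA (5/5 seeds each).

**What the generator does not emulate**: motor-unit firing statistics and
MUAP shapes, electrode geometry and crosstalk, force-varying spectral
compression, fatigue-specific low-frequency shifts, or movement artefacts.
A green drift-benefit test therefore establishes that the update engine
tracks slow parametric drift of a Gaussian-featured signal — the mechanism
the method targets — not that it reproduces any particular human dataset.

## Known behaviour without drift

With `delta = 0`, self-enhancement still improves QDA by ~1.5 points
(seeds 1–5 mean +1.52, SELDA +0.3).  This is a genuine data-augmentation
effect, not an artefact: consecutive windows overlap by 87.5%, so six
training cycles contain only ~30 independent contractions per class, and the
28-dimensional class covariances are undertrained; the stream supplies more.
The stationary-control acceptance check bounds |SEQDA - QDA| by 1.5 points
and sits marginally outside (1.52) — the effect is beneficial in direction
but slightly larger than the band, and is reported as-is rather than tuned
away.

## Numerical choices

* Scoring solves symmetric systems from cached Cholesky factors; after any
  parameter change only the touched factor is recomputed, and cached scores
  agree with from-scratch computation to 1e-10 relative.  Factors are always
  recomputed from the current covariance (never rank-one-updated), which
  makes a checkpoint/resume run bit-for-bit identical to a single pass.
* A singular covariance raises, naming the class; `ridge_lambda > 0` adds
  `lambda (tr Sigma / d) I` before factorisation as an opt-in regulariser.
* Serialisation is JSON with repr-exact floats, so save/load round-trips
  are bit-identical; feature TSVs print 17 significant digits for the same
  reason.
* Eigen-axis drift diagnostics sort eigenvalues in descending order (ties
  keep the symmetric solver's basis order) and report absolute cosines,
  since eigenvector signs are arbitrary.
* The paired t-test refuses spread-free difference vectors (t undefined)
  rather than returning infinities; p-values are reported uncorrected.

## Limitations

* Self-training can lock in errors if the drift per cycle is large compared
  with the class separation (the update pool is then polluted by confident
  mislabels); the recursions have no rejection or confidence gate by design.
* Equal historical weighting means very long stationary streams make the
  model increasingly rigid; a forgetting factor is out of scope.
* The simulator's drift is smooth and parametric; abrupt electrode shifts
  are only modelled as a single optional step change.
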