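"""Sliding-window segmentation and EMG feature extraction.

Two feature sets are provided, both computed per channel and concatenated in
channel order:

* **AR+RMS** — coefficients of a 6th-order autoregressive model estimated with
  the Burg method, plus the window RMS amplitude: ``[a_1..a_p, RMS]`` per
  channel.  Coefficients follow the monic-polynomial convention
  ``x[n] + sum_k a_k x[n-k] = e[n]``.
* **FC (Fourier-derived cepstral)** — the DCT of the log-magnitude of the
  full N-bin Fourier spectrum of the window; the first ``n_fc`` coefficients
  per channel.  The index-1 coefficient is the DC-like term.

Windows are taken only from non-rest annotation segments and never straddle a
segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from statsmodels.regression.linear_model import burg as _sm_burg

from .emg_io import RESTING, RunConfig, SignalRecord

__all__ = [
    "WindowSpec",
    "Window",
    "LabelledFeatureSet",
    "segment_windows",
    "rms",
    "ar_coefficients",
    "fc_coefficients",
    "extract_features",
]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry: N samples per window, m samples increment."""

    n_window: int
    n_increment: int

    def __post_init__(self) -> None:
        if not (self.n_window >= self.n_increment >= 1):
            raise ValueError("require n_window >= n_increment >= 1")

    @classmethod
    def from_config(cls, config: RunConfig, fs: float) -> "WindowSpec":
        return cls(
            n_window=int(round(config.window_ms * fs / 1000.0)),
            n_increment=int(round(config.increment_ms * fs / 1000.0)),
        )


@dataclass
class Window:
    """One labelled analysis window (a view into the parent signal)."""

    start_sample: int
    data: np.ndarray  # (n_window, n_channels)
    label: str
    cycle: int


@dataclass
class LabelledFeatureSet:
    """Per-window feature vectors with motion labels and cycle indices."""

    features: np.ndarray  # (n_windows, d)
    labels: np.ndarray  # (n_windows,) object/str
    cycles: np.ndarray  # (n_windows,) int
    feature_kind: str  # "AR" | "FC"
    window_index: np.ndarray = field(default=None)  # start sample per window

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_windows, d)")
        if not np.isfinite(self.features).all():
            raise ValueError("feature matrix contains non-finite values")
        self.labels = np.asarray(self.labels, dtype=object)
        self.cycles = np.asarray(self.cycles, dtype=int)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.cycles) != n:
            raise ValueError("labels/cycles length must match feature rows")
        if self.window_index is None:
            self.window_index = np.arange(n)
        self.window_index = np.asarray(self.window_index, dtype=int)
        if len(self.window_index) != n:
            raise ValueError("window_index length must match feature rows")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, mask: np.ndarray) -> "LabelledFeatureSet":
        return LabelledFeatureSet(
            features=self.features[mask],
            labels=self.labels[mask],
            cycles=self.cycles[mask],
            feature_kind=self.feature_kind,
            window_index=self.window_index[mask],
        )


def segment_windows(record: SignalRecord, spec: WindowSpec) -> list[Window]:
    """Slide an N-sample window with m-sample increment over non-rest segments.

    Each non-rest segment of length L samples yields
    ``floor((L - n_window)/n_increment) + 1`` windows (zero when L < n_window),
    labelled with the segment's class and cycle.  Windows never straddle a
    segment boundary and are returned ordered by start time.
    """
    windows: list[Window] = []
    for seg in record.segments:
        if seg.label == RESTING:
            continue
        start = int(round(seg.onset_s * record.fs))
        stop = int(round(seg.offset_s * record.fs))
        length = stop - start
        if length < spec.n_window:
            continue
        n_win = (length - spec.n_window) // spec.n_increment + 1
        for i in range(n_win):
            s = start + i * spec.n_increment
            windows.append(
                Window(
                    start_sample=s,
                    data=record.data[s : s + spec.n_window],
                    label=seg.label,
                    cycle=seg.cycle,
                )
            )
    windows.sort(key=lambda w: w.start_sample)
    return windows


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a window channel."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method AR coefficients of one window channel.

    Returns the ``order`` coefficients ``a_k`` of the monic prediction-error
    filter ``x[n] + sum_k a_k x[n-k] = e[n]``.  Burg's lattice recursion keeps
    every reflection coefficient in [-1, 1], so the model is always stable.
    A constant (zero-variance) input returns all zeros instead of dividing by
    zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("ar_coefficients expects a 1-D window channel")
    if len(x) <= order:
        raise ValueError(f"window length {len(x)} must exceed AR order {order}")
    if not np.isfinite(x).all():
        raise ValueError("ar_coefficients requires finite input")
    # zero-variance fallback: the lattice denominator would vanish
    if np.ptp(x) == 0.0:
        return np.zeros(order)
    rho, _sigma2 = _sm_burg(x, order=order, demean=False)
    # statsmodels returns process-form coefficients (x[n] = sum rho_k x[n-k]);
    # negate to the monic-polynomial convention used here.
    a = -np.asarray(rho, dtype=float)
    if not np.isfinite(a).all():
        return np.zeros(order)
    return a


def _dct_head(Y: np.ndarray, n_fc: int) -> np.ndarray:
    """First n_fc DCT-II coefficients of Y along the last axis, unnormalised.

    Matches ``FC_i = sum_k Y_k cos((k + 1/2)(i - 1) pi / N)`` for i = 1..n_fc;
    scipy's DCT-II carries an extra factor of 2.
    """
    return 0.5 * scipy.fft.dct(Y, type=2, axis=-1, norm=None)[..., :n_fc]


def fc_coefficients(
    x: np.ndarray, n_fc: int = 7, epsilon: float = 1e-12
) -> np.ndarray:
    """Fourier-derived cepstral coefficients of one window channel.

    Computes the full N-point DFT magnitude, applies the log nonlinearity
    ``Y_k = log(|X[k]| + epsilon)``, then takes the first ``n_fc`` DCT-II
    coefficients of Y over all N bins (the magnitude spectrum is conjugate-
    symmetric for real input; the sum deliberately runs over the full
    spectrum).  No taper or detrending is applied before the DFT.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fc_coefficients expects a 1-D window channel")
    N = len(x)
    if n_fc > N:
        raise ValueError(f"n_fc={n_fc} exceeds window length {N}")
    mag = np.abs(np.fft.fft(x))
    Y = np.log(mag + epsilon)
    return _dct_head(Y, n_fc)


def _fc_batch(data: np.ndarray, n_fc: int, epsilon: float) -> np.ndarray:
    """Vectorised FC over a (n_windows, n_channels, N) stack."""
    N = data.shape[-1]
    half = np.abs(np.fft.rfft(data, axis=-1))
    # mirror the conjugate-symmetric upper half: |X[N-k]| = |X[k]|
    k = np.arange(N)
    idx = np.where(k < half.shape[-1], k, N - k)
    mag = half[..., idx]
    Y = np.log(mag + epsilon)
    return _dct_head(Y, n_fc)


def extract_features(
    windows: list[Window],
    kind: str,
    config: RunConfig | None = None,
    n_channels: int | None = None,
) -> LabelledFeatureSet:
    """Compute per-channel features for each window, concatenated by channel.

    ``kind`` is ``"AR"`` (``[a_1..a_p, RMS]`` per channel, d = C*(p+1)) or
    ``"FC"`` (``[FC_1..FC_n]`` per channel, d = C*n_fc).  ``n_channels`` is
    only needed to declare the dimensionality of an empty window list.
    """
    config = config or RunConfig()
    kind = kind.upper()
    if kind not in ("AR", "FC"):
        raise ValueError(f"unknown feature kind {kind!r}")

    if not windows:
        per = (config.ar_order + 1) if kind == "AR" else config.n_fc
        d = (n_channels or 0) * per
        return LabelledFeatureSet(
            features=np.zeros((0, d)),
            labels=np.zeros(0, dtype=object),
            cycles=np.zeros(0, dtype=int),
            feature_kind=kind,
            window_index=np.zeros(0, dtype=int),
        )

    n_channels = windows[0].data.shape[1]
    n_window = windows[0].data.shape[0]
    stack = np.empty((len(windows), n_channels, n_window))
    for i, w in enumerate(windows):
        stack[i] = w.data.T
    if kind == "FC":
        fc = _fc_batch(stack, config.n_fc, config.fc_epsilon)  # (n, C, n_fc)
        feats = fc.reshape(len(windows), n_channels * config.n_fc)
    else:
        p = config.ar_order
        feats = np.empty((len(windows), n_channels * (p + 1)))
        for i in range(len(windows)):
            for c in range(n_channels):
                xc = stack[i, c]
                feats[i, c * (p + 1) : c * (p + 1) + p] = ar_coefficients(xc, p)
                feats[i, c * (p + 1) + p] = rms(xc)
    return LabelledFeatureSet(
        features=feats,
        labels=np.array([w.label for w in windows], dtype=object),
        cycles=np.array([w.cycle for w in windows], dtype=int),
        feature_kind=kind,
        window_index=np.array([w.start_sample for w in windows], dtype=int),
    )
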