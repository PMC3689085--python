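"""Reading and writing of signal recordings, annotations, feature tables and models.

All on-disk artifacts are plain text: signals and annotations are TSV with a
``#fs=<Hz>`` header line, feature tables are TSV with a ``#kind=`` header, and
fitted models are a self-describing JSON container.  Times are in seconds and
segment intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel label for rest periods; rest windows are never classified.
RESTING = "REST"

__all__ = [
    "RESTING",
    "AnnotationSegment",
    "SignalRecord",
    "RunConfig",
    "read_signal",
    "write_signal",
    "read_features",
    "write_features",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class AnnotationSegment:
    """One annotated interval of a recording.

    ``label`` is a motion-class identifier or :data:`RESTING`; ``cycle`` is the
    index of the measurement cycle the segment belongs to.
    """

    onset_s: float
    offset_s: float
    label: str
    cycle: int

    def __post_init__(self) -> None:
        if not (self.offset_s > self.onset_s >= 0.0):
            raise ValueError(
                f"segment must satisfy 0 <= onset < offset, got "
                f"[{self.onset_s}, {self.offset_s})"
            )
        if self.cycle < 0:
            raise ValueError(f"cycle must be non-negative, got {self.cycle}")


@dataclass
class SignalRecord:
    """A multi-channel sampled signal with its annotation track.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal samples, arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    segments : list of AnnotationSegment
        Sorted by onset; non-rest segments must not overlap.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    segments: list[AnnotationSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("signal data must be 2-D (n_samples, n_channels)")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"signal contains non-finite value at sample {bad[0]}, "
                f"channel {bad[1]}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data columns")
        self.segments = sorted(self.segments, key=lambda s: s.onset_s)
        dur = self.duration_s
        prev_end = None
        for seg in self.segments:
            if seg.offset_s > dur + 1e-9:
                raise ValueError(
                    f"segment [{seg.onset_s}, {seg.offset_s}) exceeds the "
                    f"{dur:g} s signal duration"
                )
            if seg.label != RESTING:
                if prev_end is not None and seg.onset_s < prev_end - 1e-9:
                    raise ValueError(
                        f"non-rest segments overlap at {seg.onset_s:g} s"
                    )
                prev_end = seg.offset_s

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def class_labels(self) -> list[str]:
        """Sorted non-rest labels present in the annotation track."""
        return sorted({s.label for s in self.segments if s.label != RESTING})


@dataclass
class RunConfig:
    """Pipeline configuration: windowing, features, classifier and updating."""

    window_ms: float = 200.0
    increment_ms: float = 25.0
    ar_order: int = 6
    n_fc: int = 7
    fc_epsilon: float = 1e-12
    classifier_mode: str = "lda"
    update_policy: str = "none"
    include_logdet: bool = True
    ridge_lambda: float = 0.0
    prior_mode: str = "counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window_ms >= self.increment_ms > 0):
            raise ValueError("require window_ms >= increment_ms > 0")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.n_fc < 1:
            raise ValueError("n_fc must be >= 1")
        self.classifier_mode = self.classifier_mode.lower()
        if self.classifier_mode not in ("lda", "qda"):
            raise ValueError(f"unknown classifier_mode {self.classifier_mode!r}")
        self.update_policy = self.update_policy.lower()
        if self.update_policy not in ("none", "m", "c", "mc"):
            raise ValueError(f"unknown update_policy {self.update_policy!r}")
        if self.prior_mode not in ("counts", "uniform"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")


# ---------------------------------------------------------------------------
# signal + annotation TSV


def _read_table(path: Path, n_header_comments: int) -> pd.DataFrame:
    """Read a TSV body as floats, naming the offending cell on failure."""
    df = pd.read_csv(path, sep="\t", skiprows=n_header_comments, dtype=str)
    out = {}
    for j, col in enumerate(df.columns):
        try:
            out[col] = df[col].astype(float)
        except ValueError:
            vals = df[col].to_numpy()
            for i, v in enumerate(vals):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: malformed numeric cell at data row {i}, "
                        f"column {col!r} (value {v!r})"
                    ) from None
            raise
    return pd.DataFrame(out)


def read_signal(
    path: str | Path,
    annotation_path: str | Path | None = None,
    vocabulary: Sequence[str] | None = None,
) -> SignalRecord:
    """Read a signal TSV (``#fs=`` header + channel columns) and annotations.

    If ``vocabulary`` is given, annotation labels outside it (other than
    :data:`RESTING`) are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#fs="):
        raise ValueError(f"{path}: missing '#fs=<Hz>' header line")
    fs = float(header[4:])
    with open(path) as fh:
        fh.readline()
        names = fh.readline().strip().split("\t")
    body = _read_table(path, n_header_comments=1)
    data = body.to_numpy(dtype=float)

    segments: list[AnnotationSegment] = []
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        required = ["onset_s", "offset_s", "label", "cycle"]
        if list(ann.columns) != required:
            raise ValueError(
                f"{annotation_path}: expected columns {required}, "
                f"got {list(ann.columns)}"
            )
        for _, row in ann.iterrows():
            label = str(row["label"])
            if vocabulary is not None and label != RESTING and label not in vocabulary:
                raise ValueError(
                    f"{annotation_path}: label {label!r} outside declared vocabulary"
                )
            segments.append(
                AnnotationSegment(
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                    label=label,
                    cycle=int(row["cycle"]),
                )
            )
    return SignalRecord(data=data, fs=fs, channel_names=names, segments=segments)


def write_signal(
    record: SignalRecord,
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write a SignalRecord as signal TSV plus optional annotation TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#fs={record.fs:.17g}\n")
        fh.write("\t".join(record.channel_names) + "\n")
        np.savetxt(fh, record.data, fmt="%.17g", delimiter="\t")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("onset_s\toffset_s\tlabel\tcycle\n")
            for s in record.segments:
                fh.write(f"{s.onset_s:.17g}\t{s.offset_s:.17g}\t{s.label}\t{s.cycle}\n")


# ---------------------------------------------------------------------------
# feature tables


def write_features(feature_set, path: str | Path) -> None:
    """Write a LabelledFeatureSet as TSV: cycle, window_index, label, features.

    Values are printed with 17 significant digits so the round trip is
    bit-identical for doubles.
    """
    path = Path(path)
    d = feature_set.d
    with open(path, "w") as fh:
        fh.write(f"#kind={feature_set.feature_kind}\n")
        cols = ["cycle", "window_index", "label"] + [f"f{i}" for i in range(d)]
        fh.write("\t".join(cols) + "\n")
        for i in range(feature_set.n_windows):
            vals = "\t".join(f"{v:.17g}" for v in feature_set.features[i])
            fh.write(
                f"{feature_set.cycles[i]}\t{feature_set.window_index[i]}\t"
                f"{feature_set.labels[i]}\t{vals}\n"
            )


def read_features(path: str | Path):
    """Read a feature TSV written by :func:`write_features`."""
    from .features import LabelledFeatureSet

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#kind="):
            raise ValueError(f"{path}: missing '#kind=' header line")
        kind = header[6:]
        names = fh.readline().strip().split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    d = len(names) - 3
    if d < 0:
        raise ValueError(f"{path}: feature header has too few columns")
    for i, row in enumerate(rows):
        if len(row) != len(names):
            raise ValueError(
                f"{path}: row {i} has {len(row)} columns, expected {len(names)}"
            )
    if rows:
        cycles = np.array([int(r[0]) for r in rows])
        window_index = np.array([int(r[1]) for r in rows])
        labels = np.array([r[2] for r in rows], dtype=object)
        feats = np.array([[float(v) for v in r[3:]] for r in rows], dtype=float)
    else:
        cycles = np.zeros(0, dtype=int)
        window_index = np.zeros(0, dtype=int)
        labels = np.zeros(0, dtype=object)
        feats = np.zeros((0, d))
    return LabelledFeatureSet(
        features=feats,
        labels=labels,
        cycles=cycles,
        feature_kind=kind,
        window_index=window_index,
    )


# ---------------------------------------------------------------------------
# model container

_MODEL_FORMAT = "selfemg-discriminant"
_MODEL_VERSION = 1


def save_model(results, path: str | Path) -> None:
    """Serialize DiscriminantResults to a self-describing JSON container."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "mode": results.mode,
        "include_logdet": results.include_logdet,
        "ridge_lambda": results.ridge_lambda,
        "prior_mode": results.prior_mode,
        "total_n": int(results.total_n),
        "pooled_cov": None
        if results.pooled_cov is None
        else results.pooled_cov.tolist(),
        "classes": [
            {
                "class_id": s.class_id,
                "n": int(s.n),
                "mean": s.mean.tolist(),
                "scatter": s.scatter.tolist(),
                "cov": s.cov.tolist(),
                "prior": s.prior,
            }
            for s in results.classes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path):
    """Load DiscriminantResults saved by :func:`save_model`."""
    from .discriminant import DiscriminantResults, GaussianClassStats

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} container")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(
            f"{path}: unsupported container version {payload.get('version')}"
        )
    required = {"mode", "include_logdet", "ridge_lambda", "prior_mode",
                "total_n", "pooled_cov", "classes"}
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"{path}: missing fields {sorted(missing)}")
    mode = payload["mode"]
    pooled = payload["pooled_cov"]
    if mode == "lda" and pooled is None:
        raise ValueError(f"{path}: LDA model is missing the pooled covariance")
    classes = [
        GaussianClassStats(
            class_id=c["class_id"],
            n=int(c["n"]),
            mean=np.asarray(c["mean"], dtype=float),
            scatter=np.asarray(c["scatter"], dtype=float),
            cov=np.asarray(c["cov"], dtype=float),
            prior=float(c["prior"]),
        )
        for c in payload["classes"]
    ]
    return DiscriminantResults(
        classes=classes,
        pooled_cov=None if pooled is None else np.asarray(pooled, dtype=float),
        total_n=int(payload["total_n"]),
        mode=mode,
        include_logdet=bool(payload["include_logdet"]),
        ridge_lambda=float(payload["ridge_lambda"]),
        prior_mode=payload["prior_mode"],
    )
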