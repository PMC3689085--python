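"""Protocol harness and metrics for continuous EMG classification.

Recognition accuracy (RA) is the percentage of analysis windows assigned
their true motion class.  The harness fits a discriminant classifier on the
training cycles, streams the testing cycles through the self-enhancing
engine in temporal order, and scores the decision stream against ground
truth — which is visible only here, never to the update engine.

Cumulative RA follows the convention that the i-th value averages the
classification results over the first i testing cycles, so the last value is
the overall RA.  A "trial" is a block of five consecutive cycles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .discriminant import DiscriminantResults, fit_discriminant
from .emg_io import RunConfig, SignalRecord
from .features import LabelledFeatureSet, WindowSpec, extract_features, segment_windows
from .self_enhance import UpdatePolicy, run_stream

__all__ = [
    "EvalResult",
    "DriftDiagnostics",
    "evaluate_protocol",
    "cosine_angle",
    "drift_diagnostics",
    "paired_t_test",
    "compare_methods",
]

CYCLES_PER_TRIAL = 5


@dataclass
class EvalResult:
    """Scored decision stream plus the derived accuracy metrics."""

    decisions: np.ndarray
    truths: np.ndarray
    cycles: np.ndarray
    overall_ra: float
    cumulative_ra: np.ndarray  # over testing cycles, i-th = RA of cycles 1..i
    per_cycle_ra: np.ndarray  # RA of each testing cycle alone
    per_class_ra: dict[str, float]
    per_trial_ra: np.ndarray  # trial = 5 consecutive testing cycles
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    test_cycle_ids: np.ndarray
    final_model: DiscriminantResults | None = None
    model_snapshots: list[DiscriminantResults] = field(default_factory=list)


def _score_stream(
    decisions: np.ndarray, truths: np.ndarray, cycles: np.ndarray, class_ids
) -> dict:
    correct = decisions == truths
    overall = 100.0 * float(np.mean(correct))
    cycle_ids = np.unique(cycles)
    per_cycle = np.array(
        [100.0 * float(np.mean(correct[cycles == c])) for c in cycle_ids]
    )
    cumulative = np.array(
        [
            100.0 * float(np.mean(correct[np.isin(cycles, cycle_ids[: i + 1])]))
            for i in range(len(cycle_ids))
        ]
    )
    per_class = {
        cid: 100.0 * float(np.mean(correct[truths == cid]))
        for cid in class_ids
        if np.any(truths == cid)
    }
    n_trials = len(cycle_ids) // CYCLES_PER_TRIAL
    per_trial = np.array(
        [
            100.0
            * float(
                np.mean(
                    correct[
                        np.isin(
                            cycles,
                            cycle_ids[
                                t * CYCLES_PER_TRIAL : (t + 1) * CYCLES_PER_TRIAL
                            ],
                        )
                    ]
                )
            )
            for t in range(n_trials)
        ]
    )
    confusion = pd.DataFrame(
        0, index=list(class_ids), columns=list(class_ids), dtype=int
    )
    for t, p in zip(truths, decisions):
        confusion.loc[t, p] += 1
    return {
        "overall_ra": overall,
        "per_cycle_ra": per_cycle,
        "cumulative_ra": cumulative,
        "per_class_ra": per_class,
        "per_trial_ra": per_trial,
        "confusion": confusion,
        "test_cycle_ids": cycle_ids,
    }


def evaluate_protocol(
    record: SignalRecord,
    config: RunConfig | None = None,
    mode: str | None = None,
    policy=None,
    kind: str = "FC",
    train_cycles: int = 6,
    snapshot_models: bool = False,
    features: LabelledFeatureSet | None = None,
) -> EvalResult:
    """Fit on the first ``train_cycles`` cycles, stream the rest, score.

    ``features`` may carry a pre-extracted feature set for the same record to
    avoid recomputation when several classifier variants are compared.
    """
    config = config or RunConfig()
    mode = (mode or config.classifier_mode).lower()
    policy = UpdatePolicy.coerce(policy if policy is not None else config.update_policy)
    if features is None:
        spec = WindowSpec.from_config(config, record.fs)
        features = extract_features(segment_windows(record, spec), kind, config)
    train = features.subset(features.cycles < train_cycles)
    test = features.subset(features.cycles >= train_cycles)
    if test.n_windows == 0:
        raise ValueError("no testing windows after the training cycles")
    for c in np.unique(test.cycles):
        if not np.any(test.cycles == c):  # pragma: no cover - defensive
            raise ValueError(f"test cycle {c} contains no windows")

    model = fit_discriminant(train, mode=mode, config=config)
    class_ids = model.class_ids

    snapshots: list[DiscriminantResults] = []
    decisions: list[str] = []
    if snapshot_models:
        for c in np.unique(test.cycles):
            sub = test.subset(test.cycles == c)
            if sub.n_windows == 0:
                raise ValueError(f"test cycle {c} contains no windows")
            dec, model, _ = run_stream(model, iter(sub.features), policy)
            decisions.extend(dec)
            snapshots.append(model.copy())
    elif policy is UpdatePolicy.NONE:
        decisions = list(model.classify(test.features))
    else:
        decisions, model, _ = run_stream(model, iter(test.features), policy)

    decisions = np.asarray(decisions, dtype=object)
    scored = _score_stream(decisions, test.labels, test.cycles, class_ids)
    return EvalResult(
        decisions=decisions,
        truths=test.labels,
        cycles=test.cycles,
        final_model=model,
        model_snapshots=snapshots,
        **scored,
    )


def cosine_angle(v0: np.ndarray, vi: np.ndarray) -> float:
    """cos of the angle between two nonzero vectors, clipped to [-1, 1]."""
    v0 = np.asarray(v0, dtype=float).ravel()
    vi = np.asarray(vi, dtype=float).ravel()
    n0, ni = np.linalg.norm(v0), np.linalg.norm(vi)
    if n0 == 0.0 or ni == 0.0:
        raise ValueError("cosine_angle is undefined for a zero vector")
    return float(np.clip(v0 @ vi / (n0 * ni), -1.0, 1.0))


@dataclass
class DriftDiagnostics:
    """Per-(testing cycle, class) geometry of the classifier parameters.

    Columns: length of the class mean vector, lengths of the first two
    principal axes of the class covariance (square roots of the two largest
    eigenvalues), cosine of the mean against the training mean, and absolute
    cosines of the first two principal axes against the training axes
    (eigenvector sign is arbitrary, so the absolute value is reported).
    """

    table: pd.DataFrame


def _principal_axes(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs in descending eigenvalue order; ties keep eigh's basis order."""
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def drift_diagnostics(
    snapshots: list[DiscriminantResults], training: DiscriminantResults
) -> DriftDiagnostics:
    """Track mean/covariance geometry across per-cycle model snapshots."""
    ref_axes = {}
    for s in training.classes:
        w, v = _principal_axes(s.cov)
        ref_axes[s.class_id] = (s.mean, v[:, :2])
    rows = []
    for i, snap in enumerate(snapshots, start=1):
        for s in snap.classes:
            mu0, ax0 = ref_axes[s.class_id]
            w, v = _principal_axes(s.cov)
            rows.append(
                {
                    "cycle": i,
                    "class": s.class_id,
                    "mean_length": float(np.linalg.norm(s.mean)),
                    "axis1_length": float(np.sqrt(max(w[0], 0.0))),
                    "axis2_length": float(np.sqrt(max(w[1], 0.0))),
                    "mean_cos": cosine_angle(mu0, s.mean),
                    "axis1_cos": abs(cosine_angle(ax0[:, 0], v[:, 0])),
                    "axis2_cos": abs(cosine_angle(ax0[:, 1], v[:, 1])),
                }
            )
    return DriftDiagnostics(table=pd.DataFrame(rows))


def paired_t_test(a, b) -> tuple[float, float]:
    """Classic paired t-test on the differences a - b, df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(np.std(d, ddof=1), 0.0):
        raise ValueError(
            "paired differences have zero spread; the t statistic is undefined"
        )
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


def compare_methods(
    records: list[SignalRecord],
    config: RunConfig | None = None,
    modes: tuple[str, ...] = ("lda", "qda"),
    policies: tuple[str, ...] = ("none", "m", "c", "mc"),
    kinds: tuple[str, ...] = ("AR", "FC"),
    train_cycles: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the method grid over simulated subjects (one record each).

    Returns a per-subject RA table (plus mean/std rows) with one column per
    (kind, mode, policy) combination, and a paired-t table comparing each
    enhanced variant against its static counterpart across subjects.
    """
    config = config or RunConfig()
    columns: dict[str, list[float]] = {}
    for kind in kinds:
        feature_cache = []
        for record in records:
            spec = WindowSpec.from_config(config, record.fs)
            feature_cache.append(
                extract_features(segment_windows(record, spec), kind, config)
            )
        for mode, policy in itertools.product(modes, policies):
            name = _column_name(kind, mode, policy)
            columns[name] = [
                evaluate_protocol(
                    rec,
                    config,
                    mode=mode,
                    policy=policy,
                    kind=kind,
                    train_cycles=train_cycles,
                    features=fs,
                ).overall_ra
                for rec, fs in zip(records, feature_cache)
            ]
    table = pd.DataFrame(
        columns, index=[f"S{i + 1}" for i in range(len(records))]
    )
    table.loc["mean"] = table.mean()
    table.loc["std"] = table.iloc[: len(records)].std(ddof=1)

    tests = []
    for kind, mode, policy in itertools.product(kinds, modes, policies):
        if policy == "none":
            continue
        enhanced = _column_name(kind, mode, policy)
        static = _column_name(kind, mode, "none")
        if len(records) >= 2:
            try:
                t, p = paired_t_test(table.loc[: f"S{len(records)}", enhanced],
                                     table.loc[: f"S{len(records)}", static])
            except ValueError:
                t, p = np.nan, np.nan
        else:
            t, p = np.nan, np.nan
        tests.append(
            {
                "kind": kind,
                "enhanced": enhanced,
                "static": static,
                "mean_gain": float(
                    table.loc["mean", enhanced] - table.loc["mean", static]
                ),
                "t": t,
                "p": p,
            }
        )
    return table, pd.DataFrame(tests)


def _column_name(kind: str, mode: str, policy: str) -> str:
    mode = mode.lower()
    policy = UpdatePolicy.coerce(policy).value
    if policy == "none":
        base = mode.upper()
    else:
        base = f"SE{mode.upper()}"
        if policy in ("m", "c"):
            base += f"({policy.upper()})"
    return f"{kind}:{base}"
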