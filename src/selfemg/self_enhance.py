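"""Self-enhancing (self-training) updates for streaming LDA/QDA.

After the discriminant model labels a new testing window ``z`` as class ``k``
with pre-update count ``n_ck`` (total ``N``), its parameters are refreshed by
rank-one recursions and ``z`` is discarded:

.. math::

    \\tilde\\mu_k   &= (n_{ck}\\,\\mu_k + z) / (n_{ck} + 1) \\\\
    C_k            &= \\frac{n_{ck}}{n_{ck}+1}(z-\\mu_k)(z-\\mu_k)^T \\\\
    \\tilde S_k    &= S_k + C_k \\\\
    \\tilde\\Sigma_k &= \\frac{n_{ck}}{n_{ck}+1}\\Sigma_k
                       + \\frac{1}{n_{ck}+1} C_k
                       \\qquad \\text{(SEQDA, class covariance)} \\\\
    \\tilde\\Sigma_W &= \\frac{N}{N+1}\\Sigma_W + \\frac{1}{N+1} C_k
                       \\qquad \\text{(SELDA, pooled covariance)}

The correction matrix ``C_k`` is always taken about the *pre-update* mean;
with both mean and covariance updating the recursions reproduce a batch
ML refit on training data plus the predicted-labelled stream exactly.  Only
class ``k`` (and the pooled matrix) changes at a step; every historical
window carries equal weight (no forgetting factor).  Updates use the model's
own predicted labels — ground truth never enters this module.

Update policies: ``none`` (static), ``m`` (means only), ``c`` (covariances
only, about the frozen mean), ``mc`` (both).  Counts ``n_ck`` and ``N``
increment under every non-``none`` policy so repeated application matches the
recursions' own bookkeeping; counts-based priors track the updated counts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

import numpy as np

from .discriminant import DiscriminantResults, GaussianClassStats

__all__ = [
    "UpdatePolicy",
    "UpdateEvent",
    "update_mean",
    "correction_matrix",
    "update_class_cov",
    "update_pooled_cov",
    "enhance_step",
    "run_stream",
]


class UpdatePolicy(str, Enum):
    NONE = "none"
    M = "m"  # mean vectors only
    C = "c"  # covariances only
    MC = "mc"  # both

    @classmethod
    def coerce(cls, value) -> "UpdatePolicy":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class UpdateEvent:
    """Audit record of one self-enhancing step."""

    window_index: int
    predicted: str
    trace_correction: float
    pre_hash: int
    post_hash: int


def _snapshot_hash(model: DiscriminantResults, class_id: str) -> int:
    s = model.class_stats(class_id)
    h = zlib.crc32(s.mean.tobytes())
    h = zlib.crc32(s.cov.tobytes(), h)
    if model.pooled_cov is not None:
        h = zlib.crc32(model.pooled_cov.tobytes(), h)
    return zlib.crc32(np.int64(s.n).tobytes(), h)


def update_mean(stats: GaussianClassStats, z: np.ndarray) -> np.ndarray:
    """Updated mean (n_ck*mu_k + z)/(n_ck + 1); pure, no mutation."""
    z = np.asarray(z, dtype=float)
    return (stats.n * stats.mean + z) / (stats.n + 1)


def correction_matrix(stats: GaussianClassStats, z: np.ndarray) -> np.ndarray:
    """Rank-one correction C_k = n_ck/(n_ck+1) (z-mu_k)(z-mu_k)^T.

    Symmetric PSD of rank <= 1; the coefficient uses the class count n_ck —
    the only choice under which S_k + C_k equals the scatter of the augmented
    class about its updated mean.
    """
    z = np.asarray(z, dtype=float)
    dev = z - stats.mean
    return (stats.n / (stats.n + 1)) * np.outer(dev, dev)


def update_class_cov(stats: GaussianClassStats, C: np.ndarray) -> np.ndarray:
    """Updated class covariance n_ck/(n_ck+1)*Sigma_k + 1/(n_ck+1)*C_k."""
    n = stats.n
    return (n / (n + 1)) * stats.cov + C / (n + 1)


def update_pooled_cov(model: DiscriminantResults, C: np.ndarray) -> np.ndarray:
    """Updated pooled covariance N/(N+1)*Sigma_W + 1/(N+1)*C_k."""
    N = model.total_n
    return (N / (N + 1)) * model.pooled_cov + C / (N + 1)


def enhance_step(
    model: DiscriminantResults, z: np.ndarray, policy="mc"
) -> tuple[str, DiscriminantResults]:
    """Classify ``z`` with the current model, then update it in place.

    Returns ``(predicted class id, model)``.  The ordering matters: the
    decision uses the pre-update parameters; the correction matrix is taken
    about the pre-update mean; the mean (if updated) moves afterwards; counts
    increment last.  ``z`` is not retained.
    """
    policy = UpdatePolicy.coerce(policy)
    z = np.asarray(z, dtype=float)
    if z.shape != (model.d,):
        raise ValueError(f"expected a {model.d}-vector, got shape {z.shape}")
    if not np.isfinite(z).all():
        raise ValueError("enhance_step requires a finite feature vector")
    k = model.classify(z)
    if policy is not UpdatePolicy.NONE:
        _apply_update(model, z, k, policy)
    return k, model


def _apply_update(
    model: DiscriminantResults, z: np.ndarray, k: str, policy: UpdatePolicy
) -> None:
    """Apply the rank-one recursions for a window already classified as k."""
    stats = model.class_stats(k)
    if policy in (UpdatePolicy.C, UpdatePolicy.MC):
        C = correction_matrix(stats, z)
        if model.mode == "qda":
            stats.cov = update_class_cov(stats, C)
            stats.scatter = stats.scatter + C
        else:
            model.pooled_cov = update_pooled_cov(model, C)
            # per-class covariances are deliberately left untouched in LDA
            # mode; only the pooled matrix enters the decision rule.
            stats.scatter = stats.scatter + C
    if policy in (UpdatePolicy.M, UpdatePolicy.MC):
        stats.mean = update_mean(stats, z)

    stats.n += 1
    model.total_n += 1
    if model.prior_mode == "counts":
        for s in model.classes:
            s.prior = s.n / model.total_n

    if policy in (UpdatePolicy.C, UpdatePolicy.MC):
        model.refresh_cache(k if model.mode == "qda" else None)


def run_stream(
    model: DiscriminantResults,
    feature_stream: Iterable[np.ndarray],
    policy="mc",
    start_index: int = 0,
) -> tuple[list[str], DiscriminantResults, list[UpdateEvent]]:
    """Apply :func:`enhance_step` to each window of a one-at-a-time iterator.

    The engine holds only the model parameters and the current window — the
    stream may be a generator and is never materialised — which is what makes
    the method deployable with constant memory.  Returns the decision stream,
    the final model (updated in place) and an audit log of update events.
    """
    policy = UpdatePolicy.coerce(policy)
    decisions: list[str] = []
    events: list[UpdateEvent] = []
    it: Iterator[np.ndarray] = iter(feature_stream)
    for i, z in enumerate(it, start=start_index):
        z = np.asarray(z, dtype=float)
        k = model.classify(z)
        decisions.append(k)
        if policy is UpdatePolicy.NONE:
            continue
        pre = _snapshot_hash(model, k)
        dev = z - model.class_stats(k).mean
        nck = model.class_stats(k).n
        C_trace = float(nck / (nck + 1) * dev @ dev)
        _apply_update(model, z, k, policy)
        events.append(
            UpdateEvent(
                window_index=i,
                predicted=k,
                trace_correction=C_trace,
                pre_hash=pre,
                post_hash=_snapshot_hash(model, k),
            )
        )
    return decisions, model, events
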