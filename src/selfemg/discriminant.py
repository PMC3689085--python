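"""Gaussian maximum-likelihood discriminant classifiers (LDA / QDA).

The model assumes each motion class :math:`\\omega_i` generates feature
vectors from a multivariate normal with mean :math:`\\mu_i` and covariance
:math:`\\Sigma_i`.  The discriminant score of a feature vector ``x`` is

.. math::

    g_i(x) = \\log p(\\omega_i)
             - \\tfrac12 (x - \\mu_i)^T \\Sigma^{-1} (x - \\mu_i)
             \\; [- \\tfrac12 \\log|\\Sigma_i|]

with :math:`\\Sigma = \\Sigma_W` (the pooled within-class covariance) for LDA
and :math:`\\Sigma = \\Sigma_i` for QDA.  The log-determinant term (bracketed)
is the textbook QDA normalisation; it can be switched off to reproduce the
unnormalised quadratic form.  The class of ``x`` is the arg-max of the scores,
ties broken by lowest class index.

Covariances use the maximum-likelihood normalisation ``Sigma = S / n`` by
default so that the streaming update recursions in :mod:`selfemg.self_enhance`
agree exactly with a batch refit; an unbiased option exists for static
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .emg_io import RunConfig

__all__ = [
    "GaussianClassStats",
    "GaussianDiscriminant",
    "DiscriminantResults",
    "fit_discriminant",
    "discriminant_scores",
    "classify",
]


@dataclass
class GaussianClassStats:
    """Sufficient statistics of one class: count, mean, scatter, covariance, prior."""

    class_id: str
    n: int
    mean: np.ndarray  # (d,)
    scatter: np.ndarray  # (d, d), sum of outer products about the mean
    cov: np.ndarray  # (d, d)
    prior: float

    def copy(self) -> "GaussianClassStats":
        return GaussianClassStats(
            class_id=self.class_id,
            n=self.n,
            mean=self.mean.copy(),
            scatter=self.scatter.copy(),
            cov=self.cov.copy(),
            prior=self.prior,
        )


class GaussianDiscriminant:
    """Gaussian discriminant model bound to a labelled feature matrix.

    Parameters
    ----------
    features : ndarray, shape (n, d)
    labels : array-like of str, shape (n,)
    mode : {"lda", "qda"}

    Examples
    --------
    >>> model = GaussianDiscriminant(X, y, mode="qda")
    >>> res = model.fit()
    >>> res.classify(X_new)
    """

    def __init__(self, features, labels, mode: str = "lda"):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("features must be (n, d) with d >= 1")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        self.labels = np.asarray(labels, dtype=object)
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels length must match feature rows")
        mode = mode.lower()
        if mode not in ("lda", "qda"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode

    @classmethod
    def from_feature_set(cls, feature_set, mode: str = "lda") -> "GaussianDiscriminant":
        return cls(feature_set.features, feature_set.labels, mode=mode)

    def fit(
        self,
        normalization: str = "ml",
        prior_mode: str = "counts",
        ridge_lambda: float = 0.0,
        include_logdet: bool = True,
    ) -> "DiscriminantResults":
        """Estimate per-class means, covariances and the pooled covariance.

        ``normalization="ml"`` uses divisor ``n`` and pooled weighting
        ``sum_i (n_i/N) Sigma_i``; ``"unbiased"`` uses ``n-1`` and
        ``(n_i-1)/(N-C)`` (static baselines only — the streaming recursions
        assume ML).  ``ridge_lambda`` adds ``lambda*(tr(Sigma)/d)*I`` to each
        covariance before factorisation.
        """
        if normalization not in ("ml", "unbiased"):
            raise ValueError(f"unknown normalization {normalization!r}")
        if prior_mode not in ("counts", "uniform"):
            raise ValueError(f"unknown prior_mode {prior_mode!r}")
        X, y = self.features, self.labels
        class_ids = sorted({str(v) for v in y})
        C = len(class_ids)
        N = X.shape[0]
        d = X.shape[1]
        stats: list[GaussianClassStats] = []
        pooled = np.zeros((d, d))
        for cid in class_ids:
            Xi = X[np.array([str(v) == cid for v in y])]
            ni = Xi.shape[0]
            if ni < 2:
                raise ValueError(
                    f"class {cid!r} has {ni} sample(s); at least 2 are required"
                )
            mu = Xi.mean(axis=0)
            dev = Xi - mu
            S = dev.T @ dev
            if normalization == "ml":
                cov = S / ni
                pooled += (ni / N) * cov
            else:
                cov = S / (ni - 1)
                pooled += (ni - 1) / (N - C) * cov
            prior = ni / N if prior_mode == "counts" else 1.0 / C
            stats.append(
                GaussianClassStats(
                    class_id=cid, n=ni, mean=mu, scatter=S, cov=cov, prior=prior
                )
            )
        return DiscriminantResults(
            classes=stats,
            pooled_cov=pooled,
            total_n=N,
            mode=self.mode,
            include_logdet=include_logdet,
            ridge_lambda=ridge_lambda,
            prior_mode=prior_mode,
        )


def fit_discriminant(
    feature_set, mode: str | None = None, config: RunConfig | None = None
) -> "DiscriminantResults":
    """Convenience wrapper: fit from a LabelledFeatureSet with a RunConfig."""
    config = config or RunConfig()
    mode = (mode or config.classifier_mode).lower()
    model = GaussianDiscriminant.from_feature_set(feature_set, mode=mode)
    return model.fit(
        prior_mode=config.prior_mode,
        ridge_lambda=config.ridge_lambda,
        include_logdet=config.include_logdet,
    )


class DiscriminantResults:
    """Fitted LDA/QDA parameters with cached factorizations.

    Holds one :class:`GaussianClassStats` per class (sorted by class id),
    the pooled within-class covariance, the total pattern count, and scoring
    configuration.  The factorization cache is refreshed automatically after
    any parameter change routed through :meth:`refresh_cache`; scores via the
    cache agree with from-scratch computation to <= 1e-10 relative.
    """

    def __init__(
        self,
        classes: list[GaussianClassStats],
        pooled_cov: np.ndarray | None,
        total_n: int,
        mode: str,
        include_logdet: bool = True,
        ridge_lambda: float = 0.0,
        prior_mode: str = "counts",
    ):
        self.classes = sorted(classes, key=lambda s: s.class_id)
        self.pooled_cov = pooled_cov
        self.total_n = int(total_n)
        self.mode = mode.lower()
        if self.mode not in ("lda", "qda"):
            raise ValueError(f"unknown mode {mode!r}")
        if self.mode == "lda" and pooled_cov is None:
            raise ValueError("LDA results require a pooled covariance")
        self.include_logdet = bool(include_logdet)
        self.ridge_lambda = float(ridge_lambda)
        self.prior_mode = prior_mode
        self._index = {s.class_id: i for i, s in enumerate(self.classes)}
        self.refresh_cache()

    # -- bookkeeping --------------------------------------------------------

    @property
    def class_ids(self) -> list[str]:
        return [s.class_id for s in self.classes]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def d(self) -> int:
        return len(self.classes[0].mean)

    def class_stats(self, class_id: str) -> GaussianClassStats:
        return self.classes[self._index[class_id]]

    def copy(self) -> "DiscriminantResults":
        return DiscriminantResults(
            classes=[s.copy() for s in self.classes],
            pooled_cov=None if self.pooled_cov is None else self.pooled_cov.copy(),
            total_n=self.total_n,
            mode=self.mode,
            include_logdet=self.include_logdet,
            ridge_lambda=self.ridge_lambda,
            prior_mode=self.prior_mode,
        )

    def _regularized(self, cov: np.ndarray) -> np.ndarray:
        if self.ridge_lambda > 0:
            d = cov.shape[0]
            return cov + self.ridge_lambda * (np.trace(cov) / d) * np.eye(d)
        return cov

    def _factor(self, cov: np.ndarray, what: str):
        try:
            c, low = scipy.linalg.cho_factor(self._regularized(cov), lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance for {what}; use ridge_lambda > 0 or more data"
            ) from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return (c, low), logdet

    def refresh_cache(self, class_id: str | None = None) -> None:
        """Recompute cached Cholesky factors (one class, or everything)."""
        if class_id is None:
            if self.mode == "qda":
                self._class_factors = {}
                self._class_logdets = {}
                for s in self.classes:
                    f, ld = self._factor(s.cov, f"class {s.class_id!r}")
                    self._class_factors[s.class_id] = f
                    self._class_logdets[s.class_id] = ld
                self._pooled_factor = None
            else:
                self._pooled_factor, self._pooled_logdet = self._factor(
                    self.pooled_cov, "pooled covariance"
                )
                self._class_factors = None
        elif self.mode == "qda":
            s = self.class_stats(class_id)
            f, ld = self._factor(s.cov, f"class {class_id!r}")
            self._class_factors[class_id] = f
            self._class_logdets[class_id] = ld
        else:
            self._pooled_factor, self._pooled_logdet = self._factor(
                self.pooled_cov, "pooled covariance"
            )

    # -- scoring ------------------------------------------------------------

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Discriminant scores g_i(x) for one vector (d,) or a batch (n, d)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d}-dimensional input, got {X.shape[1]}")
        if not np.isfinite(X).all():
            raise ValueError("scores require finite input")
        out = np.empty((X.shape[0], self.n_classes))
        for i, s in enumerate(self.classes):
            dev = X - s.mean
            if self.mode == "qda":
                factor = self._class_factors[s.class_id]
                logdet = self._class_logdets[s.class_id]
            else:
                factor = self._pooled_factor
                logdet = 0.0
            sol = scipy.linalg.cho_solve(factor, dev.T)
            maha = np.einsum("ij,ji->i", dev, sol)
            g = np.log(s.prior) - 0.5 * maha
            if self.mode == "qda" and self.include_logdet:
                g = g - 0.5 * logdet
            out[:, i] = g
        return out[0] if single else out

    def classify(self, x: np.ndarray):
        """Arg-max class of the scores; ties go to the lowest class index."""
        sc = self.scores(x)
        if sc.ndim == 1:
            return self.classes[int(np.argmax(sc))].class_id
        idx = np.argmax(sc, axis=1)
        return np.array([self.classes[int(i)].class_id for i in idx], dtype=object)

    # -- streaming / persistence handles ------------------------------------

    def enhance_step(self, z, policy="mc"):
        """Classify ``z`` then update the model in place (see self_enhance)."""
        from .self_enhance import enhance_step

        return enhance_step(self, z, policy)

    def stream(self, feature_stream, policy="mc", start_index: int = 0):
        """Run the self-enhancing engine over an iterator of feature vectors."""
        from .self_enhance import run_stream

        return run_stream(self, feature_stream, policy, start_index=start_index)

    def save(self, path) -> None:
        from .emg_io import save_model

        save_model(self, path)

    def summary(self) -> str:
        """Human-readable fit summary (per-class counts, priors, spread)."""
        rows = []
        for s in self.classes:
            rows.append(
                {
                    "class": s.class_id,
                    "n": s.n,
                    "prior": round(s.prior, 4),
                    "|mean|": round(float(np.linalg.norm(s.mean)), 4),
                    "tr(cov)": round(float(np.trace(s.cov)), 4),
                }
            )
        table = pd.DataFrame(rows).to_string(index=False)
        head = (
            f"Gaussian discriminant results ({self.mode.upper()}), "
            f"d={self.d}, C={self.n_classes}, N={self.total_n}\n"
        )
        if self.mode == "lda":
            head += f"pooled covariance trace: {float(np.trace(self.pooled_cov)):.4f}\n"
        return head + table


def discriminant_scores(model: DiscriminantResults, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`DiscriminantResults.scores`."""
    return model.scores(x)


def classify(model: DiscriminantResults, x: np.ndarray):
    """Functional alias for :meth:`DiscriminantResults.classify`."""
    return model.classify(x)
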