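import numpy as np
import pytest

import selfemg as se


@pytest.fixture(scope="session")
def tiny_protocol() -> se.ProtocolSpec:
    """Small, fast protocol: 3 classes, 2 channels, 1 s contractions."""
    return se.ProtocolSpec(
        n_classes=3,
        n_channels=2,
        contraction_s=1.0,
        rest_s=0.5,
        n_cycles=4,
        train_cycles=2,
        test_cycles=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_record(tiny_protocol) -> se.SignalRecord:
    return se.simulate_recording(tiny_protocol)


@pytest.fixture(scope="session")
def tiny_features(tiny_record) -> se.LabelledFeatureSet:
    cfg = se.RunConfig()
    spec = se.WindowSpec.from_config(cfg, tiny_record.fs)
    return se.extract_features(se.segment_windows(tiny_record, spec), "FC", cfg)


def gaussian_problem(seed, n_classes=3, d=4, n_per_class=100, spread=3.0):
    """Labelled draws from well-separated Gaussians, plus their parameters."""
    rng = np.random.default_rng(seed)
    mus = rng.normal(0.0, spread, size=(n_classes, d))
    covs = []
    X, y = [], []
    for i in range(n_classes):
        A = rng.normal(0.0, 0.4, size=(d, d))
        cov = A @ A.T + np.eye(d)
        covs.append(cov)
        X.append(rng.multivariate_normal(mus[i], cov, size=n_per_class))
        y.extend([f"c{i}"] * n_per_class)
    return np.concatenate(X), np.array(y, dtype=object), mus, covs
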