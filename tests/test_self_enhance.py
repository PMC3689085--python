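"""The incremental update engine: hand-derivable micro-examples of the
rank-one recursions, the incremental-vs-batch refit equivalence that is the
method's defining property, and the streaming/checkpointing contracts."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selfemg as se
from selfemg.discriminant import GaussianClassStats
from selfemg.self_enhance import UpdatePolicy


def stats_from_points(points, class_id="k", prior=0.5):
    P = np.asarray(points, dtype=float)
    mu = P.mean(axis=0)
    S = (P - mu).T @ (P - mu)
    return GaussianClassStats(
        class_id=class_id, n=len(P), mean=mu, scatter=S, cov=S / len(P), prior=prior
    )


class TestUpdateMean:
    def test_fixed_point(self):
        s = stats_from_points([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(se.update_mean(s, s.mean), s.mean)

    def test_hand_example(self):
        s = GaussianClassStats("k", 2, np.array([1.0, 3.0]), np.eye(2), np.eye(2), 0.5)
        np.testing.assert_allclose(se.update_mean(s, np.array([4.0, 0.0])), [2.0, 2.0])

    @given(seed=st.integers(0, 100))
    @settings(deadline=None, max_examples=25)
    def test_equals_batch_mean_of_augmented_points(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(int(rng.integers(2, 12)), 3))
        z = rng.normal(size=3)
        s = stats_from_points(P)
        np.testing.assert_allclose(
            se.update_mean(s, z),
            np.vstack([P, z]).mean(axis=0),
            rtol=1e-12,
            atol=1e-12,
        )


class TestCorrectionMatrix:
    def test_zero_at_the_mean(self):
        s = stats_from_points([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_allclose(se.correction_matrix(s, s.mean), 0.0)

    def test_hand_example_half_outer(self):
        s = GaussianClassStats(
            "k", 1, np.zeros(2), np.zeros((2, 2)), np.zeros((2, 2)), 1.0
        )
        C = se.correction_matrix(s, np.array([2.0, 0.0]))
        np.testing.assert_allclose(C, [[2.0, 0.0], [0.0, 0.0]])

    @given(seed=st.integers(0, 100))
    @settings(deadline=None, max_examples=25)
    def test_scatter_identity_and_psd(self, seed):
        """S_k + C_k equals the scatter of the augmented set about its new mean."""
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(int(rng.integers(2, 10)), 4))
        z = rng.normal(size=4)
        s = stats_from_points(P)
        C = se.correction_matrix(s, z)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        w = np.linalg.eigvalsh(C)
        assert w.min() > -1e-10
        assert np.sum(w > 1e-10) <= 1  # rank <= 1
        A = np.vstack([P, z])
        mu_new = A.mean(axis=0)
        S_new = (A - mu_new).T @ (A - mu_new)
        np.testing.assert_allclose(s.scatter + C, S_new, rtol=1e-9, atol=1e-9)


class TestCovarianceUpdates:
    def test_shrinkage_with_zero_correction(self):
        s = stats_from_points([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]])
        out = se.update_class_cov(s, np.zeros((2, 2)))
        np.testing.assert_allclose(out, s.n / (s.n + 1) * s.cov)

    def test_class_cov_hand_example(self):
        s = stats_from_points([[0.0, 0.0], [2.0, 0.0]])
        z = np.array([1.0, 3.0])
        C = se.correction_matrix(s, z)
        np.testing.assert_allclose(C, [[0.0, 0.0], [0.0, 6.0]])
        out = se.update_class_cov(s, C)
        np.testing.assert_allclose(out, [[2.0 / 3.0, 0.0], [0.0, 2.0]])
        # batch oracle: ML covariance of the augmented points
        A = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        np.testing.assert_allclose(out, np.cov(A.T, bias=True), rtol=1e-12)

    def test_pooled_cov_hand_example(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 5.0], [5.0, 7.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = se.GaussianDiscriminant(X, y, mode="lda").fit()
        np.testing.assert_allclose(model.pooled_cov, 0.5 * np.eye(2))
        C = se.correction_matrix(model.class_stats("a"), np.array([1.0, 3.0]))
        out = se.update_pooled_cov(model, C)
        np.testing.assert_allclose(out, [[0.4, 0.0], [0.0, 1.6]])

    def test_pooled_shrinkage_telescopes(self):
        """T updates at the class mean give Sigma_W -> N/(N+T) Sigma_W."""
        X, y = _gaussians(0, C=2, d=3, n=20)
        model = se.GaussianDiscriminant(X, y, mode="lda").fit()
        pooled0, N = model.pooled_cov.copy(), model.total_n
        mu = model.class_stats(model.classify(model.classes[0].mean)).mean.copy()
        T = 7
        for _ in range(T):
            se.enhance_step(model, mu, "c")
        np.testing.assert_allclose(
            model.pooled_cov, N / (N + T) * pooled0, rtol=1e-10
        )

    @given(seed=st.integers(0, 50))
    @settings(deadline=None, max_examples=20)
    def test_updated_cov_stays_psd(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(5, 3))
        z = 10.0 * rng.normal(size=3)
        s = stats_from_points(P)
        out = se.update_class_cov(s, se.correction_matrix(s, z))
        assert np.linalg.eigvalsh(out).min() > -1e-10


def _gaussians(seed, C=3, d=4, n=30, spread=4.0):
    rng = np.random.default_rng(seed)
    mus = rng.normal(0, spread, (C, d))
    X = np.concatenate([mus[i] + rng.standard_normal((n, d)) for i in range(C)])
    y = np.concatenate([[f"c{i}"] * n for i in range(C)]).astype(object)
    return X, y


def batch_oracle(Xtr, ytr, decisions, Z, mode, policy):
    """Recursion-defined batch forms, computed independently of the engine.

    MC: plain ML refit of train + predicted-labelled stream.  M: means-only
    refit, training covariances kept.  C: plain loop over the printed
    recursions with frozen means (their defining form).
    """
    base = se.GaussianDiscriminant(Xtr, ytr, mode=mode).fit()
    if policy == "mc":
        return se.GaussianDiscriminant(
            np.concatenate([Xtr, Z]), np.concatenate([ytr, decisions]), mode=mode
        ).fit()
    out = base.copy()
    if policy == "m":
        for s in out.classes:
            pts = [Xtr[i] for i in range(len(ytr)) if ytr[i] == s.class_id]
            pts += [Z[i] for i in range(len(decisions)) if decisions[i] == s.class_id]
            s.mean = np.mean(pts, axis=0)
            s.n = len(pts)
        out.total_n = len(ytr) + len(Z)
    else:  # policy == "c", frozen means
        counts = {s.class_id: s.n for s in out.classes}
        N = out.total_n
        for z, k in zip(Z, decisions):
            s = out.class_stats(k)
            dev = z - s.mean
            Ck = counts[k] / (counts[k] + 1) * np.outer(dev, dev)
            if mode == "qda":
                s.cov = counts[k] / (counts[k] + 1) * s.cov + Ck / (counts[k] + 1)
            else:
                out.pooled_cov = N / (N + 1) * out.pooled_cov + Ck / (N + 1)
            counts[k] += 1
            N += 1
        out.total_n = N
        for s in out.classes:
            s.n = counts[s.class_id]
    if out.prior_mode == "counts":
        for s in out.classes:
            s.prior = s.n / out.total_n
    return out


class TestIncrementalBatchEquivalence:
    @pytest.mark.parametrize("mode", ["lda", "qda"])
    @pytest.mark.parametrize(
        "d, C, T", [(2, 2, 1), (2, 2, 50), (8, 2, 50), (2, 10, 50), (8, 10, 500)]
    )
    def test_mc_equals_batch_ml_refit(self, mode, d, C, T):
        rng = np.random.default_rng(d * 1000 + C * 10 + T)
        X, y = _gaussians(d + C + T, C=C, d=d, n=25)
        model = se.GaussianDiscriminant(X, y, mode=mode).fit()
        Z = rng.normal(0, 4, size=(T, d))
        dec, model, _ = se.run_stream(model, iter(Z), "mc")
        batch = batch_oracle(X, y, np.array(dec, dtype=object), Z, mode, "mc")
        _assert_params_close(model, batch, mode, policy="mc")

    @pytest.mark.parametrize("mode", ["lda", "qda"])
    @pytest.mark.parametrize("policy", ["m", "c"])
    def test_single_parameter_policies_match_their_forms(self, mode, policy):
        rng = np.random.default_rng(99)
        X, y = _gaussians(1, C=3, d=4, n=20)
        model = se.GaussianDiscriminant(X, y, mode=mode).fit()
        Z = rng.normal(0, 4, size=(120, 4))
        dec, model, _ = se.run_stream(model, iter(Z), policy)
        batch = batch_oracle(X, y, np.array(dec, dtype=object), Z, mode, policy)
        _assert_params_close(model, batch, mode, policy=policy)

    def test_counts_monotone_and_consistent(self):
        X, y = _gaussians(2)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit()
        rng = np.random.default_rng(3)
        last_total = model.total_n
        for z in rng.normal(0, 4, size=(40, 4)):
            se.enhance_step(model, z, "mc")
            assert model.total_n == last_total + 1
            assert sum(s.n for s in model.classes) == model.total_n
            last_total = model.total_n


def _assert_params_close(model, batch, mode, policy):
    for a, b in zip(model.classes, batch.classes):
        assert a.n == b.n
        np.testing.assert_allclose(a.mean, b.mean, rtol=1e-8, atol=1e-10)
        if policy in ("c", "mc") and mode == "qda":
            np.testing.assert_allclose(a.cov, b.cov, rtol=1e-8, atol=1e-10)
        if policy == "m":
            np.testing.assert_allclose(a.cov, b.cov, rtol=0, atol=0)  # untouched
    if mode == "lda":
        np.testing.assert_allclose(
            model.pooled_cov, batch.pooled_cov, rtol=1e-8, atol=1e-10
        )
    assert model.total_n == batch.total_n


class TestEnhanceStep:
    def test_policy_none_is_bit_identical_to_static(self):
        X, y = _gaussians(4)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit()
        frozen = model.copy()
        rng = np.random.default_rng(5)
        Z = rng.normal(0, 4, size=(200, 4))
        dec, model, events = se.run_stream(model, iter(Z), UpdatePolicy.NONE)
        assert events == []
        np.testing.assert_array_equal(np.array(dec), frozen.classify(Z))
        for a, b in zip(model.classes, frozen.classes):
            np.testing.assert_array_equal(a.mean, b.mean)
            np.testing.assert_array_equal(a.cov, b.cov)
            assert a.n == b.n

    def test_other_classes_bit_identical_after_step(self):
        X, y = _gaussians(6)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit(prior_mode="uniform")
        z = model.classes[1].mean + 0.1
        before = {s.class_id: (s.mean.copy(), s.cov.copy(), s.n) for s in model.classes}
        k, model = se.enhance_step(model, z, "mc")
        for s in model.classes:
            if s.class_id == k:
                continue
            mu0, cov0, n0 = before[s.class_id]
            assert np.array_equal(s.mean, mu0)
            assert np.array_equal(s.cov, cov0)
            assert s.n == n0

    def test_step_at_class_mean_only_shrinks_pooled(self):
        """z = mu_k leaves the 2-class LDA boundary unchanged up to the
        N/(N+1) shrinkage of the pooled covariance."""
        X, y = _gaussians(7, C=2, d=3)
        model = se.GaussianDiscriminant(X, y, mode="lda").fit(prior_mode="uniform")
        pooled0, N = model.pooled_cov.copy(), model.total_n
        mu1 = model.classes[0].mean.copy()
        k, model = se.enhance_step(model, mu1, "mc")
        assert k == model.classes[0].class_id
        np.testing.assert_allclose(model.pooled_cov, N / (N + 1) * pooled0, rtol=1e-12)
        np.testing.assert_allclose(model.classes[0].mean, mu1, rtol=1e-12)
        # equal-prior LDA boundary is invariant under scaling of Sigma_W
        rng = np.random.default_rng(8)
        Q = rng.normal(0, 4, size=(200, 3))
        static = se.GaussianDiscriminant(X, y, mode="lda").fit(prior_mode="uniform")
        model.prior_mode = "uniform"
        for s in model.classes:
            s.prior = 0.5
        np.testing.assert_array_equal(model.classify(Q), static.classify(Q))

    def test_nonfinite_feature_rejected(self):
        X, y = _gaussians(9)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit()
        with pytest.raises(ValueError, match="finite"):
            se.enhance_step(model, np.array([np.nan, 0, 0, 0]), "mc")


class TestRunStream:
    def test_empty_stream(self):
        X, y = _gaussians(10)
        model = se.GaussianDiscriminant(X, y, mode="lda").fit()
        dec, out, events = se.run_stream(model, iter([]), "mc")
        assert dec == [] and events == []
        assert out is model

    def test_accepts_pure_generator(self):
        """Memory contract: the engine must work from a one-shot generator."""
        X, y = _gaussians(11)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit()
        rng = np.random.default_rng(12)

        def gen():
            for _ in range(50):
                yield rng.normal(0, 4, size=4)

        dec, _, events = se.run_stream(model, gen(), "mc")
        assert len(dec) == len(events) == 50

    def test_checkpoint_resume_equals_single_pass(self, tmp_path):
        """Splitting a stream across a save/load boundary is bit-for-bit
        identical to one pass."""
        X, y = _gaussians(13)
        rng = np.random.default_rng(14)
        Z = rng.normal(0, 4, size=(80, 4))
        for mode in ("lda", "qda"):
            one = se.GaussianDiscriminant(X, y, mode=mode).fit()
            dec_one, one, _ = se.run_stream(one, iter(Z), "mc")

            two = se.GaussianDiscriminant(X, y, mode=mode).fit()
            dec_a, two, _ = se.run_stream(two, iter(Z[:37]), "mc")
            path = tmp_path / f"ckpt_{mode}.json"
            se.save_model(two, path)
            resumed = se.load_model(path)
            dec_b, resumed, _ = se.run_stream(resumed, iter(Z[37:]), "mc")

            assert dec_one == dec_a + dec_b
            for a, b in zip(one.classes, resumed.classes):
                assert np.array_equal(a.mean, b.mean)
                assert np.array_equal(a.cov, b.cov)
                assert a.n == b.n
            if mode == "lda":
                assert np.array_equal(one.pooled_cov, resumed.pooled_cov)

    def test_stationary_stream_mc_matches_none_decisions(self):
        """On a drift-free Gaussian stream, self-enhancement leaves >= 99%
        of the 2000 decisions unchanged."""
        X, y = _gaussians(15, C=3, d=4, n=200, spread=3.0)
        rng = np.random.default_rng(16)
        mus = np.stack([s.mean for s in se.GaussianDiscriminant(X, y).fit().classes])
        Z = mus[rng.integers(0, 3, 2000)] + rng.standard_normal((2000, 4))
        static = se.GaussianDiscriminant(X, y, mode="qda").fit()
        dec_none = static.classify(Z)
        enhanced = se.GaussianDiscriminant(X, y, mode="qda").fit()
        dec_mc, _, _ = se.run_stream(enhanced, iter(Z), "mc")
        agree = np.mean(np.array(dec_mc, dtype=object) == dec_none)
        assert agree >= 0.99

    def test_audit_log_records_rank_one_traces(self):
        X, y = _gaussians(17)
        model = se.GaussianDiscriminant(X, y, mode="qda").fit()
        rng = np.random.default_rng(18)
        Z = rng.normal(0, 4, size=(10, 4))
        dec, model2, events = se.run_stream(model, iter(Z), "mc")
        for e, z, k in zip(events, Z, dec):
            assert e.predicted == k
            assert e.trace_correction >= 0.0
            assert e.pre_hash != e.post_hash  # parameters actually moved
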