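"""Equation oracles, gradient verification, training contracts and metrics."""

import numpy as np
import pytest

from mimil.features import MODALITIES
from mimil.model import (
    MILNet,
    Metrics,
    ModelConfig,
    SplitSpec,
    TrainedModel,
    _attention_mil_net,
    _concat_instances,
    _mimil_net,
    attention_pool,
    classify,
    compute_metrics,
    evaluate,
    fuse_modalities,
    person_disjoint_split,
    ridge_feature_ranking,
    train_model,
)


# ---------------------------------------------------------------------------
# explicit-loop reference implementations (oracles)
# ---------------------------------------------------------------------------


def attention_pool_loops(E, V, w):
    """Direct per-definition evaluation of the attention pooling equation."""
    k, M = E.shape
    logits = np.array([w @ np.tanh(V @ E[i]) for i in range(k)])
    ex = np.exp(logits - logits.max())
    a = ex / ex.sum()
    t = sum(a[i] * E[i] for i in range(k))
    return t, a


def fusion_loops(X, w_theta, w_phi, w_g):
    """Explicit double loop over all dimension pairs of the non-local fusion."""
    D = len(X)
    Z = np.zeros(D)
    for i in range(D):
        f = np.array([np.exp(w_theta * X[i] * w_phi * X[j]) for j in range(D)])
        C = f.sum()
        Z[i] = sum(f[j] / C * (w_g * X[j]) for j in range(D))
    return Z


class TestAttentionPooling:
    def test_single_instance(self):
        E = np.array([[1.0, -2.0]])
        t, a = attention_pool(E, np.eye(2), np.ones(2))
        assert np.allclose(a, [1.0])
        assert np.allclose(t, E[0])

    def test_equal_embeddings_uniform_attention(self):
        e = np.array([0.3, -0.7, 1.1])
        E = np.tile(e, (19, 1))
        rng = np.random.default_rng(0)
        t, a = attention_pool(E, rng.normal(size=(5, 3)), rng.normal(size=5))
        assert np.allclose(a, 1 / 19)
        assert np.allclose(t, e)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k, M, L = rng.integers(2, 8), rng.integers(1, 6), rng.integers(1, 6)
            E = rng.normal(size=(k, M))
            V = rng.normal(size=(L, M))
            w = rng.normal(size=L)
            t, a = attention_pool(E, V, w)
            t0, a0 = attention_pool_loops(E, V, w)
            assert np.allclose(a, a0, atol=1e-10)
            assert np.allclose(t, t0, atol=1e-10)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(a >= 0)


class TestFusion:
    def test_zero_weights_uniform_attention(self):
        rng = np.random.default_rng(2)
        ts = [rng.normal(size=2) for _ in range(4)]
        Z = fuse_modalities(*ts, w_theta=0.0, w_phi=0.0, w_g=1.5)
        X = np.concatenate(ts)
        assert np.allclose(Z, np.mean(1.5 * X))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ts = [rng.normal(size=2) for _ in range(4)]
            wt, wp, wg = rng.normal(size=3) * 0.5
            Z = fuse_modalities(*ts, w_theta=wt, w_phi=wp, w_g=wg)
            Z0 = fusion_loops(np.concatenate(ts), wt, wp, wg)
            assert Z.shape == (8,)
            assert np.allclose(Z, Z0, atol=1e-10)

    def test_scaling_behaviour_against_oracle(self):
        rng = np.random.default_rng(4)
        ts = [rng.normal(size=2) for _ in range(4)]
        wt, wp, wg = 0.3, -0.2, 1.1
        for c in (0.5, 2.0):
            scaled = [c * t for t in ts]
            Z = fuse_modalities(*scaled, w_theta=wt, w_phi=wp, w_g=wg)
            Z0 = fusion_loops(c * np.concatenate(ts), wt, wp, wg)
            assert np.allclose(Z, Z0, atol=1e-10)


class TestClassifier:
    def test_zero_weights_give_half(self):
        Z = np.random.default_rng(0).normal(size=8)
        p = classify(Z, np.zeros((8, 4)), np.zeros(4), np.zeros(4), 0.0)
        assert p == pytest.approx(0.5)

    def test_output_in_open_interval_and_monotone(self):
        rng = np.random.default_rng(5)
        W1, b1 = rng.normal(size=(8, 4)), rng.normal(size=4)
        W2 = rng.normal(size=4)
        ps = [classify(rng.normal(size=8) * 100, W1, b1, W2, b) for b in (-3, 0, 3)]
        assert all(0 < p < 1 for p in ps)
        Z = rng.normal(size=8)
        p_lo = classify(Z, W1, b1, W2, -1.0)
        p_hi = classify(Z, W1, b1, W2, +1.0)
        assert p_hi > p_lo


class TestNetworkForward:
    def _random_batch(self, rng, B=4, d=6):
        return {m: rng.normal(size=(B, 19, d)) for m in MODALITIES}

    def test_deterministic(self):
        net = _mimil_net(ModelConfig())
        params = net.init_params(0)
        xs = self._random_batch(np.random.default_rng(0))
        p1 = net.predict_proba(params, xs)
        p2 = net.predict_proba(params, xs)
        assert np.array_equal(p1, p2)

    def test_instance_permutation_invariance(self):
        """No positional term: shuffling instances within every modality
        leaves the bag probability unchanged."""
        net = _mimil_net(ModelConfig())
        params = net.init_params(1)
        rng = np.random.default_rng(6)
        xs = self._random_batch(rng, B=3)
        perm = rng.permutation(19)
        xs_p = {m: X[:, perm, :] for m, X in xs.items()}
        assert np.allclose(
            net.predict_proba(params, xs), net.predict_proba(params, xs_p), atol=1e-12
        )

    def test_attention_weights_sum_to_one(self):
        net = _mimil_net(ModelConfig())
        params = net.init_params(2)
        xs = self._random_batch(np.random.default_rng(7), B=5)
        _, cache = net.forward(params, xs)
        for m in MODALITIES:
            _, _, A = cache["att"][m]
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(A >= 0)

    def test_fusion_rows_softmax_to_one_and_z_dim(self):
        net = _mimil_net(ModelConfig())
        params = net.init_params(3)
        xs = self._random_batch(np.random.default_rng(8), B=2)
        _, cache = net.forward(params, xs)
        S, _ = cache["fus"]
        assert np.allclose(S.sum(axis=2), 1.0, atol=1e-6)
        Z = cache["clf"][0]
        assert Z.shape[1] == cache["X4"].shape[1] == 4 * net.cfg.embedding_dim

    def test_zeroing_one_modality_only_changes_its_pathway(self):
        cfg = ModelConfig(fusion=False)
        net = _mimil_net(cfg)
        params = net.init_params(4)
        xs = self._random_batch(np.random.default_rng(9), B=2)
        _, cache = net.forward(params, xs)
        xs0 = {m: (np.zeros_like(X) if m == "hr" else X) for m, X in xs.items()}
        _, cache0 = net.forward(params, xs0)
        p = cfg.embedding_dim
        for i, m in enumerate(MODALITIES):
            same = np.allclose(
                cache["X4"][:, i * p : (i + 1) * p], cache0["X4"][:, i * p : (i + 1) * p]
            )
            assert same == (m != "hr")

    def test_ablation_equivalence_with_attention_mil(self):
        """With a single modality and no fusion, MI-MIL and attention-MIL are
        the same architecture: identical parameters give identical outputs."""
        cfg = ModelConfig(fusion=False)
        single = MILNet({"eda": 6}, cfg, fusion=False)
        amil = MILNet({"all": 6}, cfg, fusion=False)
        params = single.init_params(11)
        params_amil = {k.replace("_eda_", "_all_"): v for k, v in params.items()}
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 19, 6))
        p1 = single.predict_proba(params, {"eda": X})
        p2 = amil.predict_proba(params_amil, {"all": X})
        assert np.allclose(p1, p2, atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("fusion", [True, False])
    def test_finite_difference_check(self, fusion):
        """Hand-derived gradients match central finite differences."""
        cfg = ModelConfig(
            embedding_dim=3,
            attention_hidden_dim=2,
            embedding_hidden_dim=4,
            classifier_hidden_dim=3,
            fusion=fusion,
        )
        net = MILNet({m: 2 for m in MODALITIES}, cfg)
        params = net.init_params(0)
        rng = np.random.default_rng(13)
        xs = {m: rng.normal(size=(3, 5, 2)) for m in MODALITIES}
        y = np.array([1.0, 0.0, 1.0])
        _, grads = net.loss_and_grads(params, xs, y)
        eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1) if params[key].ndim else None
            n_checks = min(5, params[key].size)
            for idx in range(n_checks):
                def value_at(delta):
                    p2 = {k: v.copy() for k, v in params.items()}
                    if p2[key].ndim:
                        p2[key].reshape(-1)[idx] += delta
                    else:
                        p2[key] = p2[key] + delta
                    loss, _ = net.loss_and_grads(p2, xs, y)
                    return loss

                num = (value_at(eps) - value_at(-eps)) / (2 * eps)
                ana = grads[key].reshape(-1)[idx] if grads[key].ndim else float(grads[key])
                assert ana == pytest.approx(num, abs=1e-5, rel=1e-4), key


class TestTraining:
    def _separable_bags(self, rng, B=60):
        """Linearly separable synthetic bags: class 1 has a witness instance."""
        xs = {m: rng.normal(size=(B, 19, 6)) for m in MODALITIES}
        y = (np.arange(B) % 2).astype(float)
        for b in np.flatnonzero(y):
            pos = rng.integers(19)
            xs["eda"][b, pos] += 4.0
        return xs, y

    def test_loss_decreases_and_deterministic(self):
        rng = np.random.default_rng(20)
        xs, y = self._separable_bags(rng)
        cfg = ModelConfig(epochs=10, patience=10, batch_size=16)
        m1 = train_model(xs, y, xs, y, cfg, seed=0)
        m2 = train_model(xs, y, xs, y, cfg, seed=0)
        losses = [h[1] for h in m1.history]
        assert losses[-1] < losses[0]
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(21)
        xs = {m: rng.normal(size=(8, 19, 6)) for m in MODALITIES}
        with pytest.raises(ValueError):
            train_model(xs, np.ones(8), xs, np.ones(8), ModelConfig())

    def test_learns_separable_problem(self):
        rng = np.random.default_rng(22)
        xs, y = self._separable_bags(rng, B=80)
        cfg = ModelConfig(epochs=40, patience=40)
        model = train_model(xs, y, xs, y, cfg, seed=0)
        acc = np.mean(model.predict(xs) == y)
        assert acc > 0.9


class TestMetricsAndSplits:
    def test_confusion_arithmetic(self):
        # TP=2, FP=1, FN=0, TN=1
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 1, 1, 0])
        m = compute_metrics(y_true, y_pred)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.5)

    def test_perfect_and_inverted(self):
        y = np.array([1, 0, 1, 0])
        perfect = compute_metrics(y, y)
        assert all(v == 1.0 for v in perfect.as_dict().values())
        inverted = compute_metrics(y, 1 - y)
        assert inverted.accuracy == pytest.approx(1 - perfect.accuracy)

    def test_person_disjoint_split_counts(self):
        participants = {f"CWS_{i}": "CWS" for i in range(16)}
        participants.update({f"CWNS_{i}": "CWNS" for i in range(19)})
        split = person_disjoint_split(participants, seed=0)
        train_cws = sum(1 for p in split.train if p.startswith("CWS_"))
        train_cwns = sum(1 for p in split.train if p.startswith("CWNS_"))
        assert (train_cws, train_cwns) == (10, 13)
        assert len(split.test) == len(split.validation) == 6
        all_ids = split.train + split.validation + split.test
        assert len(all_ids) == len(set(all_ids)) == 35

    def test_split_deterministic_under_seed(self):
        participants = {f"CWS_{i}": "CWS" for i in range(8)}
        participants.update({f"CWNS_{i}": "CWNS" for i in range(8)})
        s1 = person_disjoint_split(participants, seed=3)
        s2 = person_disjoint_split(participants, seed=3)
        assert s1.test == s2.test and s1.validation == s2.validation

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train=["a"], validation=["a"], test=["b"])


class TestRidgeRanking:
    def _bags_from_matrix(self, X24, y):
        from mimil.features import FeatureBag

        bags = []
        for row, label in zip(X24, y):
            mats = {
                m: np.tile(row[i * 6 : (i + 1) * 6], (19, 1))
                for i, m in enumerate(MODALITIES)
            }
            bags.append(
                FeatureBag(
                    participant_id="p",
                    group="CWS" if label else "CWNS",
                    window_kind="free_speech",
                    representation="raw",
                    matrices=mats,
                )
            )
        return bags

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(30)
        y = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 24))
        X[:, 7] = y * 2.0 + rng.normal(0, 0.1, size=100)
        ranked = ridge_feature_ranking(self._bags_from_matrix(X, y))
        from mimil.features import feature_names

        assert ranked[0][0] == feature_names("raw")[7]

    def test_duplicated_feature_splits_coefficient(self):
        rng = np.random.default_rng(31)
        y = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 24))
        signal = y * 2.0 + rng.normal(0, 0.1, size=100)
        X[:, 3] = signal
        X[:, 9] = signal
        ranked = dict(ridge_feature_ranking(self._bags_from_matrix(X, y), alpha=10.0))
        from mimil.features import feature_names

        names = feature_names("raw")
        c1, c2 = ranked[names[3]], ranked[names[9]]
        assert c1 == pytest.approx(c2, rel=0.15)

    def test_noise_coefficients_shrink_with_penalty(self):
        rng = np.random.default_rng(32)
        y = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 24))
        bags = self._bags_from_matrix(X, y)
        small = max(abs(c) for _, c in ridge_feature_ranking(bags, alpha=1.0))
        large = max(abs(c) for _, c in ridge_feature_ranking(bags, alpha=1e4))
        assert large < small


class TestEvaluateSeedAveraging:
    def test_average_over_models(self):
        rng = np.random.default_rng(40)
        xs = {m: rng.normal(size=(10, 19, 6)) for m in MODALITIES}
        y = (np.arange(10) % 2).astype(float)
        cfg = ModelConfig(epochs=2, patience=2)
        models = [train_model(xs, y, xs, y, cfg, seed=s) for s in (0, 1)]
        avg = evaluate(models, xs, y)
        singles = [evaluate(m, xs, y) for m in models]
        assert avg.f1 == pytest.approx(np.mean([s.f1 for s in singles]))
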