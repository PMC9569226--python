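"""Full network: loss composition, training loop, prediction contracts."""

import numpy as np
import pytest

from mvconn.encoder import EncoderSpec
from mvconn.network import (FusionSpec, MultiViewNet, TrainConfig,
                            build_network, predict, predict_with, total_loss,
                            train)
from mvconn.prototypes import (LossConfig, PrototypeSet, class_prob, distances,
                               init_prototypes)
from mvconn.synth import SynthConfig, generate_multiview


def _toy(rng, n=6):
    net = MultiViewNet([5, 4], EncoderSpec((4, 3), pretrain=False),
                       FusionSpec(position=2, K=3), seed=1)
    X = [rng.standard_normal((n, 5)), rng.standard_normal((n, 4))]
    y = np.arange(n) % 2
    proto = init_prototypes(net.forward(X), y)
    return net, X, y, proto


class TestTotalLoss:
    def test_reduces_to_dce_when_weights_zero(self, rng):
        net, X, y, proto = _toy(rng)
        cfg = LossConfig(gamma=0.8, lambda1=0.0, lambda2=0.0)
        loss, comps, _ = total_loss(net, X, y, proto, cfg)
        d = distances(net.forward(X), proto.prototypes)
        p = class_prob(d, 0.8)
        want = float(np.mean(-np.log(p[np.arange(len(y)), proto.class_index(y)])))
        assert loss == pytest.approx(want, abs=1e-12)
        assert comps["dce"] == pytest.approx(want, abs=1e-12)

    def test_components_match_independent_calls(self, rng):
        from mvconn.fusion import ncc_batch
        from mvconn.prototypes import mp_loss

        net, X, y, proto = _toy(rng)
        cfg = LossConfig(gamma=0.8, margin=0.5, lambda1=0.7, lambda2=0.2)
        loss, comps, _ = total_loss(net, X, y, proto, cfg)
        g, cache = net.forward(X, return_cache=True)
        d = distances(g, proto.prototypes)
        idx = proto.class_index(y)
        rows = np.arange(len(y))
        d_y = d[rows, idx]
        masked = d.copy()
        masked[rows, idx] = np.inf
        d_r = masked.min(axis=1)
        assert comps["mp"] == pytest.approx(mp_loss(d_y, d_r, 0.5), abs=1e-12)
        u = cache["u"]
        assert comps["mv"] == pytest.approx(
            float(np.mean(ncc_batch(u[0], u[1]))), abs=1e-12)
        assert loss == pytest.approx(
            comps["dce"] + 0.7 * comps["mp"] - 0.2 * comps["mv"], abs=1e-12)

    @pytest.mark.parametrize("mode,position", [("fuse", 1), ("fuse", 2),
                                               ("concat", 1), ("concat", 2)])
    def test_gradients_match_finite_differences(self, mode, position, rng):
        net = MultiViewNet([5, 4], EncoderSpec((4, 3), pretrain=False),
                           FusionSpec(mode=mode, position=position, K=3), seed=1)
        X = [rng.standard_normal((6, 5)), rng.standard_normal((6, 4))]
        y = np.arange(6) % 2
        proto = init_prototypes(net.forward(X), y)
        cfg = LossConfig(gamma=0.7, margin=0.5, lambda1=0.5, lambda2=0.3)
        _, _, grads = total_loss(net, X, y, proto, cfg)
        eps = 1e-6
        rng2 = np.random.default_rng(9)
        for key, P in net.params.items():
            flat = P.reshape(-1)
            for pos in rng2.choice(flat.size, size=min(5, flat.size), replace=False):
                old = flat[pos]
                flat[pos] = old + eps
                up, _, _ = total_loss(net, X, y, proto, cfg, want_grads=False)
                flat[pos] = old - eps
                dn, _, _ = total_loss(net, X, y, proto, cfg, want_grads=False)
                flat[pos] = old
                fd = (up - dn) / (2 * eps)
                assert grads[key].reshape(-1)[pos] == pytest.approx(fd, abs=1e-4), key


class TestTrain:
    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        net, X, y, _ = _toy(rng, n=8)
        before = net.clone_params()
        train(net, X, y, LossConfig(), TrainConfig(epochs=0, batch_size=4))
        for k in before:
            assert np.array_equal(net.params[k], before[k])

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        data, _ = generate_multiview(
            SynthConfig(N=120, region_counts=(6, 5), s=3, effect=5.0, seed=0))
        X = [v.X for v in data.views[:2]]
        net = MultiViewNet(data.view_widths[:2],
                           EncoderSpec((8, 4), pretrain=False),
                           FusionSpec(position=2, K=4), seed=0)
        model = train(net, X, data.labels, LossConfig(),
                      TrainConfig(batch_size=32, learning_rate=1e-2,
                                  epochs=200, seed=0))
        assert max(model.history["train_acc"]) == 1.0

    def test_identical_seeds_identical_histories(self, rng):
        data, _ = generate_multiview(
            SynthConfig(N=40, region_counts=(5, 4), s=2, effect=2.0, seed=1))
        X = [v.X for v in data.views]
        runs = []
        for _ in range(2):
            net = MultiViewNet(data.view_widths, EncoderSpec((6, 3), pretrain=False),
                               FusionSpec(position=2, K=3), seed=5)
            model = train(net, X, data.labels, LossConfig(),
                          TrainConfig(batch_size=16, learning_rate=1e-2,
                                      epochs=10, seed=5))
            runs.append(model.history["train_loss"])
        assert runs[0] == runs[1]

    def test_validation_checkpointing_restores_best(self, rng):
        data, _ = generate_multiview(
            SynthConfig(N=60, region_counts=(5, 4), s=2, effect=3.0, seed=2))
        X = [v.X[:40] for v in data.views]
        Xv = [v.X[40:] for v in data.views]
        net = MultiViewNet(data.view_widths, EncoderSpec((6, 3), pretrain=False),
                           FusionSpec(position=2, K=3), seed=0)
        model = train(net, X, data.labels[:40], LossConfig(),
                      TrainConfig(batch_size=16, learning_rate=1e-2,
                                  epochs=20, seed=0),
                      val_views=Xv, val_y=data.labels[40:])
        assert model.best_epoch == int(np.argmax(model.history["val_acc"]))


class TestPredict:
    def test_instance_at_prototype(self):
        proto = PrototypeSet(np.array([[0.0, 0.0], [10.0, 10.0]]),
                             np.array([0, 1]), gamma=1.0)
        net = MultiViewNet([2], EncoderSpec((2,), pretrain=False, activation="tanh"),
                           FusionSpec(position=1, K=2), seed=0)
        # identity-ish: drive the fusion map so g(x) = x
        net.params["fus0_W"] = np.eye(2)
        labels, prob = predict_with(net, proto, [np.array([[0.0, 0.0]])])
        assert labels[0] == 0
        assert prob[0, 0] > 0.5

    def test_equidistant_tie_breaks_to_lower_class_index(self):
        proto = PrototypeSet(np.array([[1.0, 0.0], [-1.0, 0.0]]),
                             np.array([3, 7]), gamma=1.0)
        net = MultiViewNet([2], EncoderSpec((2,), pretrain=False),
                           FusionSpec(position=1, K=2), seed=0)
        net.params["fus0_W"] = np.eye(2)
        labels, _ = predict_with(net, proto, [np.array([[0.0, 5.0]])])
        assert labels[0] == 3

    def test_batch_matches_per_instance_loop(self, rng):
        net, X, y, proto = _toy(rng, n=10)
        labels, prob = predict_with(net, proto, X)
        for i in range(10):
            li, pi = predict_with(net, proto, [x[i:i + 1] for x in X])
            assert li[0] == labels[i]
            assert np.allclose(pi[0], prob[i])


def test_prototype_recomputation_idempotent(rng):
    net, X, y, _ = _toy(rng, n=12)
    a = init_prototypes(net.forward(X), y)
    b = init_prototypes(net.forward(X), y)
    assert np.array_equal(a.prototypes, b.prototypes)


def test_build_network_pretrains_per_view_layers(rng):
    X = [rng.standard_normal((20, 6)), rng.standard_normal((20, 5))]
    spec = EncoderSpec((4, 3), pretrain=True, pretrain_epochs=5)
    fus = FusionSpec(position=2, K=3)
    net = build_network([6, 5], spec, fus, X_views=X, seed=0)
    raw = MultiViewNet([6, 5], spec, fus, seed=0)
    # pretraining must have moved the per-view layer away from raw init
    assert not np.allclose(net.params["enc0_W0"], raw.params["enc0_W0"])
    assert net.forward(X).shape == (20, 3)
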