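"""Layer-wise training, rate features, and the multi-objective readout."""

import numpy as np
import pytest

from hetsnn.network import ConvLayerSpec, NetworkConfig, build_network
from hetsnn.synthetic import MotionSpec, SequenceSample, make_sprite, render_sequence
from hetsnn.training import (
    ReadoutModel,
    TrainSchedule,
    bce_loss,
    extract_rate_features,
    layerwise_train,
    predict_readout,
    train_readout,
)

ROT_STATIC = MotionSpec(kind="static", applies_to="rotation")


def _config(n_layers=1, depth=4, shape=(16, 16), seed=0):
    layers = [ConvLayerSpec(kernel=(3, 3), depth=depth, stride=2)
              for _ in range(n_layers)]
    return NetworkConfig(input_shape=shape, layers=layers, mopm_sections=[], seed=seed)


def _moving_bar_sequences(n=4):
    tr = MotionSpec(kind="constant", speed=1.0, direction=(0, 1))
    sprite = make_sprite("vbar", 8)
    return [render_sequence(sprite, tr, ROT_STATIC, canvas=(16, 16), n_frames=5)
            for _ in range(n)]


def _two_pattern_sequences(n=6):
    """Each sequence shows a vertical bar (left half) and a horizontal bar
    (right half) moving simultaneously -- the two-pattern toy input."""
    tr_d = MotionSpec(kind="constant", speed=1.0, direction=(1, 0))
    tr_r = MotionSpec(kind="constant", speed=1.0, direction=(0, 1))
    out = []
    for _ in range(n):
        a = render_sequence(make_sprite("vbar", 8), tr_d, ROT_STATIC,
                            canvas=(16, 16), n_frames=7)
        b = render_sequence(make_sprite("hbar", 8), tr_r, ROT_STATIC,
                            canvas=(16, 16), n_frames=7)
        out.append(SequenceSample(np.concatenate([a.frames, b.frames], axis=2), 0, 0, 0))
    return out


class TestLayerwise:
    def test_staging_only_current_layer_mutates(self):
        net = build_network(_config(n_layers=2, depth=2))
        init = [l.W_learn.copy() for l in net.layers]
        seqs = _moving_bar_sequences(2)
        sched = TrainSchedule(t_train=40.0, seed=1)
        # train layer 1 only
        rng = np.random.default_rng(sched.seed)
        from hetsnn.training import _encode, _sequence_seed

        for idx in rng.permutation(len(seqs)):
            raster = _encode(seqs[idx], sched, _sequence_seed(sched.seed, int(idx)))
            net.reset_state()
            for t in range(raster.shape[-1]):
                net.forward_step(raster[None, :, :, t].astype(float), t=float(t), learn_layer=0)
        assert not np.array_equal(net.layers[0].W_learn, init[0])
        assert np.array_equal(net.layers[1].W_learn, init[1])
        assert np.array_equal(net.layers[1].W_mem, init[1])  # memory untouched

    def test_transfer_happens_per_stage(self):
        net = build_network(_config(n_layers=1, depth=2))
        layerwise_train(net, _moving_bar_sequences(2), TrainSchedule(t_train=40.0, seed=1))
        assert np.array_equal(net.layers[0].W_mem, net.layers[0].W_learn)

    def test_identical_seed_identical_conductances(self):
        def run():
            net = build_network(_config(depth=2, seed=5))
            layerwise_train(net, _moving_bar_sequences(2), TrainSchedule(t_train=40.0, seed=3))
            return net.layers[0].W_learn.copy()

        assert np.array_equal(run(), run())

    def test_oriented_patterns_learned_by_distinct_kernels(self):
        """On the two-pattern toy input, the two most active kernels are
        dissimilar to each other (< 0.5) and each matches its oriented
        template (> 0.7)."""
        seqs = _two_pattern_sequences(6)
        cfg = NetworkConfig(input_shape=(16, 32),
                           layers=[ConvLayerSpec(kernel=(3, 3), depth=4, stride=2)],
                           mopm_sections=[], seed=3)
        net = build_network(cfg)
        sched = TrainSchedule(t_train=250.0, seed=9)
        layerwise_train(net, seqs, sched)
        W = net.layers[0].W_learn[:, 0]

        def cos(a, b):
            return float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))

        v_templates, h_templates = [], []
        for i in range(3):
            v = np.zeros((3, 3)); v[:, i] = 1; v_templates.append(v)
            h = np.zeros((3, 3)); h[i, :] = 1; h_templates.append(h)
        for c0 in range(2):
            v = np.zeros((3, 3)); v[:, c0:c0 + 2] = 1; v_templates.append(v)
            h = np.zeros((3, 3)); h[c0:c0 + 2, :] = 1; h_templates.append(h)

        # activity ranking on one more (non-learning) pass
        from hetsnn.training import _encode

        raster = _encode(seqs[0], TrainSchedule(t_train=150.0, seed=1), 55)
        net.reset_state()
        counts = np.zeros(4)
        for t in range(raster.shape[-1]):
            out = net.forward_step(raster[None, :, :, t].astype(float), t=float(t),
                                   learn_layer=0)
            counts += out["learner"].sum(axis=(1, 2))
        top1, top2 = np.argsort(counts)[::-1][:2]
        assert cos(W[top1], W[top2]) < 0.5
        match = {}
        for k in (top1, top2):
            cv = max(cos(W[k], tpl) for tpl in v_templates)
            ch = max(cos(W[k], tpl) for tpl in h_templates)
            match[k] = ("v", cv) if cv > ch else ("h", ch)
            assert match[k][1] > 0.7
        assert match[top1][0] != match[top2][0]  # one vertical, one horizontal

    def test_no_two_kernels_identical_after_training(self):
        """Cross-depth competition keeps kernels from converging onto the
        same pattern (pairwise cosine <= 0.95)."""
        seqs = _two_pattern_sequences(6)
        cfg = NetworkConfig(input_shape=(16, 32),
                           layers=[ConvLayerSpec(kernel=(3, 3), depth=4, stride=2)],
                           mopm_sections=[], seed=3)
        net = build_network(cfg)
        layerwise_train(net, seqs, TrainSchedule(t_train=250.0, seed=9))
        W = net.layers[0].W_learn[:, 0].reshape(4, -1)
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        sim = Wn @ Wn.T
        assert np.max(sim[~np.eye(4, dtype=bool)]) <= 0.95

    def test_empty_dataset_rejected(self):
        net = build_network(_config())
        with pytest.raises(ValueError):
            layerwise_train(net, [], TrainSchedule())


class TestFeatures:
    def test_zero_sequence_zero_features(self):
        net = build_network(_config())
        sample = SequenceSample(np.zeros((3, 16, 16)), 0, 0, 0)
        f = extract_rate_features(net, sample, TrainSchedule(t_train=30.0))
        assert f.shape == (net.feature_dim,) and not f.any()

    def test_bounded_by_refractory_ceiling(self):
        net = build_network(_config())
        sample = SequenceSample(np.ones((3, 16, 16)), 0, 0, 0)
        f = extract_rate_features(net, sample, TrainSchedule(t_train=50.0))
        # both memory types have r = 10 ms -> at most 100 Hz
        assert f.max() <= 1000.0 / 10.0 + 1e-9

    def test_independent_of_preceding_sequence(self):
        """Neuron-state reset makes features order-independent."""
        net = build_network(_config())
        sched = TrainSchedule(t_train=40.0, seed=2)
        target = _moving_bar_sequences(1)[0]
        f1 = extract_rate_features(net, target, sched, seed=77)
        extract_rate_features(net, SequenceSample(np.ones((3, 16, 16)), 0, 0, 0), sched)
        f2 = extract_rate_features(net, target, sched, seed=77)
        assert np.array_equal(f1, f2)


class TestReadout:
    SECTIONS = [("class", 2), ("motion", 2)]

    def _separable(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.column_stack([rng.integers(0, 2, n), rng.integers(0, 2, n)])
        feats = np.hstack([
            np.eye(2)[labels[:, 0]] * 3.0,
            np.eye(2)[labels[:, 1]] * 3.0,
        ]) + 0.1 * rng.standard_normal((n, 4))
        return feats, labels

    def test_separable_features_perfect_fit(self):
        feats, labels = self._separable()
        model = train_readout(feats, labels, self.SECTIONS, epochs=200, seed=1)
        assert np.array_equal(predict_readout(model, feats), labels)

    def test_loss_non_increasing_full_batch(self):
        feats, labels = self._separable(seed=3)
        losses = []
        for epochs in (0, 20, 60, 150):
            m = train_readout(feats, labels, self.SECTIONS, lr=0.05,
                              epochs=epochs, batch_size=len(feats), seed=2)
            losses.append(bce_loss(m, feats, labels))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_planted_model_sign_recovery(self):
        """A planted linear rule is recovered with >= 95% weight-sign
        agreement."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((600, 20))
        w = rng.standard_normal(20)
        y = (X @ w > 0).astype(int)
        model = train_readout(X, np.column_stack([y]), [("s", 2)],
                              lr=0.3, epochs=300, batch_size=32, seed=0)
        diff = model.W[:-1, 1] - model.W[:-1, 0]  # score difference direction
        assert (np.sign(diff) == np.sign(w)).mean() >= 0.95

    def test_sections_independent(self):
        """Permuting section-2 units never changes section-1 predictions."""
        feats, labels = self._separable(seed=6)
        model = train_readout(feats, labels, self.SECTIONS, epochs=100, seed=1)
        pred = predict_readout(model, feats)
        shuffled = model.W.copy()
        shuffled[:, [2, 3]] = shuffled[:, [3, 2]]
        m2 = ReadoutModel(W=shuffled, sections=model.sections, mu=model.mu, sd=model.sd)
        pred2 = predict_readout(m2, feats)
        assert np.array_equal(pred[:, 0], pred2[:, 0])
        assert not np.array_equal(pred[:, 1], pred2[:, 1])

    def test_bad_label_block_rejected(self):
        feats = np.zeros((4, 4))
        with pytest.raises(ValueError):
            train_readout(feats, np.array([[0, 5]] * 4), self.SECTIONS)
        with pytest.raises(ValueError):
            train_readout(feats, np.array([[0]] * 4), self.SECTIONS)
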