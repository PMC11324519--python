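"""Neural primitives (losses, gradients) and the classification branches."""

import json

import numpy as np
import pytest

from mgeclass import nn
from mgeclass.classify import (
    AggregatorModel,
    MarkerBranchModel,
    SequenceBranchConfig,
    SequenceBranchModel,
    aggregate_scores,
    one_hot,
    score_sequence_branch,
    train_aggregator,
    train_marker_branch,
)
from mgeclass.features import FEATURE_REGISTRY
from mgeclass.records import SequenceRecord


class TestLosses:
    def test_focal_gamma_zero_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, 40)
        lf, gf = nn.focal_loss(logits, labels, gamma=0.0)
        lc, gc = nn.cross_entropy(logits, labels)
        assert lf == pytest.approx(lc, abs=1e-6)
        assert np.abs(gf - gc).max() < 1e-6

    def test_focal_downweights_easy_examples(self):
        logits = np.array([[6.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
        labels = np.array([0, 0])
        # per-example focal losses: easy example is suppressed much more
        l_easy, _ = nn.focal_loss(logits[:1], labels[:1], gamma=2.0)
        c_easy, _ = nn.cross_entropy(logits[:1], labels[:1])
        l_hard, _ = nn.focal_loss(logits[1:], labels[1:], gamma=2.0)
        c_hard, _ = nn.cross_entropy(logits[1:], labels[1:])
        assert l_easy / c_easy < l_hard / c_hard

    def test_gradient_centralization_zero_row_mean(self):
        rng = np.random.default_rng(1)
        g = nn.centralize_gradient(rng.normal(size=(6, 9)))
        assert np.abs(g.mean(axis=1)).max() < 1e-6
        v = rng.normal(size=7)
        assert np.allclose(nn.centralize_gradient(v), v)  # vectors untouched

    def test_supcon_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        z, _ = nn.l2_normalize(rng.normal(size=(7, 4)))
        labels = rng.integers(0, 3, 7)
        _, dz = nn.supcon_loss(z, labels, 0.1)
        eps = 1e-6
        for i, j in [(0, 0), (3, 2), (6, 1)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (nn.supcon_loss(zp, labels, 0.1)[0] - nn.supcon_loss(zm, labels, 0.1)[0]) / (2 * eps)
            assert num == pytest.approx(dz[i, j], abs=1e-6)

    def test_conv_stack_gradients(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv1D(4, 3, 5, 2, rng)
        pool = nn.PatchAttentionPool(conv.out_length(40), 3, 4, 2, 6, rng)
        dense = nn.Dense(6, 2, rng)
        x = rng.normal(size=(2, 40, 4))

        def forward():
            return dense.forward(pool.forward(conv.forward(x))).sum()

        forward()
        for p in conv.params + pool.params + dense.params:
            p.grad[...] = 0
        dx = conv.backward(pool.backward(dense.backward(np.ones((2, 2)))))
        eps = 1e-6
        W = conv.W
        W.value[1, 2, 0] += eps
        up = forward()
        W.value[1, 2, 0] -= 2 * eps
        down = forward()
        W.value[1, 2, 0] += eps
        assert (up - down) / (2 * eps) == pytest.approx(W.grad[1, 2, 0], abs=1e-6)
        x[0, 13, 2] += eps
        up = forward()
        x[0, 13, 2] -= 2 * eps
        down = forward()
        assert (up - down) / (2 * eps) == pytest.approx(dx[0, 13, 2], abs=1e-6)


class TestOneHot:
    def test_acgt_identity(self):
        assert np.array_equal(one_hot("ACGT", 4), np.eye(4))

    def test_n_is_zero_row(self):
        m = one_hot("AN", 2)
        assert np.array_equal(m, [[1, 0, 0, 0], [0, 0, 0, 0]])

    def test_right_padding(self):
        m = one_hot("AC", 4)
        assert np.array_equal(m[2:], np.zeros((2, 4)))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            one_hot("", 4)


class TestMarkerBranch:
    def test_separable_fixture_high_accuracy(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 25))
        y = rng.integers(0, 3, 300)
        X[:, 0] = y * 2.0 + rng.normal(0, 0.05, 300)  # separable by construction
        model = train_marker_branch(X, y, FEATURE_REGISTRY, seed=0)
        acc = (model.predict(X).argmax(1) == y).mean()
        assert acc >= 0.99

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(600, 25))
        y = rng.integers(0, 3, 600)  # labels independent of features
        model = train_marker_branch(X[:400], y[:400], FEATURE_REGISTRY, seed=0)
        acc = (model.predict(X[400:]).argmax(1) == y[400:]).mean()
        assert abs(acc - 1 / 3) < 0.1

    def test_missing_class_is_error(self):
        X = np.zeros((10, 25))
        with pytest.raises(ValueError, match="virus"):
            train_marker_branch(X, [0, 1] * 5, FEATURE_REGISTRY, seed=0)

    def test_simplex_and_registry_guard(self, trained_stack):
        mm = trained_stack["marker"]
        scores = mm.predict(trained_stack["X"])
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
        with pytest.raises(ValueError, match="registry"):
            mm.predict(np.zeros((2, 7)))

    def test_save_load_round_trip(self, trained_stack, tmp_path):
        mm = trained_stack["marker"]
        p = tmp_path / "marker.json"
        mm.save(p)
        back = MarkerBranchModel.load(p)
        assert np.allclose(back.predict(trained_stack["X"]), mm.predict(trained_stack["X"]))


class TestSequenceBranch:
    def test_window_tiling_identity(self, trained_stack):
        sm = trained_stack["sequence"]
        W = sm.config.window
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=W))
        one = score_sequence_branch(sm, SequenceRecord(id="a", seq=seq))
        two = score_sequence_branch(sm, SequenceRecord(id="b", seq=seq + seq))
        assert np.allclose(one, two, atol=1e-9)
        assert one.sum() == pytest.approx(1.0, abs=1e-9)

    def test_composition_classes_learnable(self, trained_stack, small_corpus, marker_db):
        # the tiny session model should beat chance comfortably on its corpus
        sm = trained_stack["sequence"]
        y = trained_stack["y"]
        records, _, _ = small_corpus
        X = np.stack([one_hot(r.seq, sm.config.window) for r in records])
        acc = (sm.predict_windows(X).argmax(1) == y).mean()
        assert acc >= 0.8

    def test_save_load_round_trip(self, trained_stack, tmp_path, small_corpus):
        sm = trained_stack["sequence"]
        records, _, _ = small_corpus
        X = np.stack([one_hot(r.seq, sm.config.window) for r in records[:4]])
        p = tmp_path / "seq.json"
        sm.save(p)
        back = SequenceBranchModel.load(p)
        assert np.allclose(back.predict_windows(X), sm.predict_windows(X), atol=1e-12)

    def test_single_class_batch_warns_and_skips(self):
        X = np.zeros((8, 64, 4))
        y = np.array([0] * 8)
        config = SequenceBranchConfig(
            window=64, channels=4, n_layers=2, n_patches=4, patch_size=2,
            dim=8, proj_dim=4, contrastive_epochs=1, classifier_epochs=1,
            batch_size=8,
        )
        with pytest.warns(UserWarning, match="single-class"):
            from mgeclass.classify import train_sequence_branch
            train_sequence_branch(X, y, config, seed=0)


class TestAggregator:
    def test_weight_parameterization(self, trained_stack):
        am = trained_stack["aggregator"]
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        w_m, w_s = am.weights(grid)
        assert w_m[0] == 0.0  # exactly zero at frequency 0
        assert np.all(np.diff(w_m) >= 0)  # non-decreasing
        assert np.all(w_s > 0)

    def test_zero_frequency_uses_sequence_branch_only(self, trained_stack):
        am = trained_stack["aggregator"]
        seq_scores = np.array([[0.1, 0.2, 0.7]])
        for marker_scores in ([0.9, 0.05, 0.05], [0.0, 1.0, 0.0]):
            out = am.forward(seq_scores, np.array([marker_scores]), np.array([0.0]))
            ref = am.forward(seq_scores, np.array([[1/3, 1/3, 1/3]]), np.array([0.0]))
            assert np.allclose(out, ref, atol=1e-12)

    def test_identical_branch_scores_preserve_argmax(self, trained_stack):
        am = trained_stack["aggregator"]
        s = np.array([[0.05, 0.15, 0.8]])
        out = aggregate_scores(s, s, 0.5, am)
        assert out.argmax() == 2
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_frequency_out_of_range_is_error(self, trained_stack):
        am = trained_stack["aggregator"]
        s = np.array([[0.3, 0.3, 0.4]])
        with pytest.raises(ValueError):
            am.forward(s, s, np.array([1.2]))

    def test_save_load_round_trip(self, trained_stack, tmp_path):
        am = trained_stack["aggregator"]
        p = tmp_path / "agg.json"
        am.save(p)
        back = AggregatorModel.load(p)
        s = np.array([[0.2, 0.3, 0.5]])
        assert np.allclose(back.forward(s, s, np.array([0.4])),
                           am.forward(s, s, np.array([0.4])))


class TestDeterminism:
    def test_marker_branch_bit_reproducible(self, annotated_corpus, trained_stack):
        X, y = trained_stack["X"], trained_stack["y"]
        a = train_marker_branch(X, y, FEATURE_REGISTRY, seed=3)
        b = train_marker_branch(X, y, FEATURE_REGISTRY, seed=3)
        assert a.booster.save_raw("json") == b.booster.save_raw("json")

    def test_aggregator_bit_reproducible(self, trained_stack):
        X, y, freqs = trained_stack["X"], trained_stack["y"], trained_stack["freqs"]
        ms = trained_stack["marker"].predict(X)
        rng = np.random.default_rng(0)
        ss = rng.dirichlet([1, 1, 1], size=len(y))
        a = train_aggregator(ss, ms, freqs, y, seed=9, epochs=50)
        b = train_aggregator(ss, ms, freqs, y, seed=9, epochs=50)
        assert json.dumps(nn_state(a)) == json.dumps(nn_state(b))


def nn_state(model):
    return {p.name: p.value.tolist() for p in model.params}
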