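"""Window segmentation, majority labels, confidence-resolved frame expansion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cefhar as ch
from cefhar import nn
from cefhar.sliding_window import (
    WindowClassifier,
    predict_sw,
    segment,
    train_window_classifier,
    window_label,
)


def _sample(labels, seed=0):
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    return ch.AccelSample(
        frames=rng.normal(size=(len(labels), 3)),
        labels=labels,
        subject_id="a",
        sample_id=f"a-{seed}",
    )


class TestSegment:
    def test_250_frames_spec_10_5(self):
        wins = segment(_sample(np.zeros(250)), ch.WindowSpec(10, 5))
        assert len(wins) == 49
        assert [w[0] for w in wins] == list(range(0, 245, 5))

    def test_250_frames_spec_40_20_leaves_tail_uncovered(self):
        # floor((250 - 40) / 20) + 1 = 11 full windows; frames 240..249 are
        # not coverable by any full window
        wins = segment(_sample(np.zeros(250)), ch.WindowSpec(40, 20))
        assert len(wins) == 11
        assert [w[0] for w in wins] == list(range(0, 201, 20))
        assert max(w[0] for w in wins) + 40 == 240

    def test_window_equal_to_length(self):
        wins = segment(_sample(np.zeros(20)), ch.WindowSpec(20, 10))
        assert len(wins) == 1

    def test_too_short_sample_rejected(self):
        with pytest.raises(ValueError):
            segment(_sample(np.zeros(9)), ch.WindowSpec(10, 5))

    @settings(derandomize=True, max_examples=60)
    @given(
        T=st.integers(10, 300),
        size=st.integers(2, 60),
        overlap=st.integers(0, 59),
    )
    def test_window_count_formula(self, T, size, overlap):
        if overlap >= size or T < size:
            return
        spec = ch.WindowSpec(size, overlap)
        wins = segment(_sample(np.zeros(T)), spec)
        assert len(wins) == (T - size) // spec.stride + 1
        for start, frames, labels in wins:
            assert frames.shape == (size, 3)
            assert len(labels) == size
            assert start + size <= T


class TestWindowSpecValidation:
    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            ch.WindowSpec(10, 10)
        with pytest.raises(ValueError):
            ch.WindowSpec(10, -1)

    def test_canonical_specs(self):
        assert [(s.size, s.overlap, s.stride) for s in ch.CANONICAL_WINDOW_SPECS] == [
            (10, 5, 5), (20, 10, 10), (40, 20, 20)
        ]


class TestWindowLabel:
    def test_unanimity(self):
        assert window_label(np.full(8, 3)) == 3

    def test_plurality(self):
        assert window_label(np.array([0] * 6 + [6] * 4)) == 0

    def test_tie_breaks_to_lowest_index(self):
        assert window_label(np.array([1] * 5 + [2] * 5)) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_label(np.array([], dtype=int))


class _ScriptedClassifier:
    """Stands in for a trained window classifier: fixed per-window probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, windows):
        assert len(windows) == len(self.probs)
        return self.probs


class TestPredictSw:
    def test_tiling_windows_expand_plainly(self):
        # stride == size: every frame covered exactly once
        spec = ch.WindowSpec(5, 0)
        sample = _sample(np.zeros(20))
        probs = np.eye(7)[[1, 2, 3, 4]]
        out = predict_sw(_ScriptedClassifier(probs), sample, spec)
        np.testing.assert_array_equal(out, np.repeat([1, 2, 3, 4], 5))

    def test_higher_confidence_window_wins(self):
        spec = ch.WindowSpec(10, 5)
        sample = _sample(np.zeros(15))
        probs = np.zeros((2, 7))
        probs[0, 2] = 0.9
        probs[1, 5] = 0.6
        out = predict_sw(_ScriptedClassifier(probs), sample, spec)
        # overlap frames 5..9 go to window 0 (confidence 0.9 beats 0.6)
        np.testing.assert_array_equal(out[:10], np.full(10, 2))
        np.testing.assert_array_equal(out[10:], np.full(5, 5))

    def test_matches_brute_force_coverage_oracle(self):
        spec = ch.WindowSpec(10, 5)
        T = 30
        sample = _sample(np.zeros(T))
        rng = np.random.default_rng(8)
        n_win = (T - spec.size) // spec.stride + 1
        probs = rng.dirichlet(np.ones(7), size=n_win)
        out = predict_sw(_ScriptedClassifier(probs), sample, spec)

        starts = list(range(0, T - spec.size + 1, spec.stride))
        for t in range(T):
            best_conf, best_cls = -1.0, None
            for wi, start in enumerate(starts):
                if start <= t < start + spec.size:
                    conf = probs[wi].max()
                    if conf > best_conf:
                        best_conf, best_cls = conf, int(probs[wi].argmax())
            if best_cls is None:
                continue  # uncovered: handled by nearest-fill below
            assert out[t] == best_cls

    def test_uncovered_tail_inherits_nearest(self):
        spec = ch.WindowSpec(40, 20)
        sample = _sample(np.zeros(250))
        n_win = (250 - 40) // 20 + 1
        probs = np.eye(7)[np.arange(n_win) % 7]
        out = predict_sw(_ScriptedClassifier(probs), sample, spec)
        assert len(out) == 250
        np.testing.assert_array_equal(out[240:], out[239])

    def test_perfect_classifier_reconstructs_quantized_truth(self):
        # stride == size with ground-truth window labels reproduces the
        # majority-quantized label sequence exactly
        spec = ch.WindowSpec(5, 0)
        labels = np.repeat([0, 6, 6, 3, 0, 0], 5)[:30]
        sample = _sample(labels)
        wins = segment(sample, spec)
        probs = np.eye(7)[[window_label(w[2]) for w in wins]]
        out = predict_sw(_ScriptedClassifier(probs), sample, spec)
        expected = np.concatenate(
            [np.full(spec.size, window_label(w[2])) for w in wins]
        )
        np.testing.assert_array_equal(out, expected)


class TestWindowClassifierTraining:
    def _toy_windows_dataset(self):
        # four length-10 recordings, one window each, distinct labels
        samples = []
        rng = np.random.default_rng(9)
        for i, lab in enumerate([0, 2, 4, 6]):
            base = np.zeros((10, 3)) + lab  # trivially separable means
            samples.append(
                ch.AccelSample(
                    frames=base + 0.01 * rng.normal(size=(10, 3)),
                    labels=np.full(10, lab),
                    subject_id="a",
                    sample_id=f"a-{i}",
                )
            )
        return ch.Dataset(samples=samples)

    def test_memorizes_four_windows(self):
        ds = self._toy_windows_dataset()
        spec = ch.WindowSpec(10, 5)
        cfg = ch.ModelConfig(
            kernel_sizes=(3, 5), filters=8, n_blocks=1, reduction=4,
            seq_len=10, layer_norm="feature_map",
        )
        tc = ch.TrainConfig(epochs=150, learning_rate=3e-3, batch_size=4, seed=0)
        clf = train_window_classifier(ds, spec, cfg, tc)
        x = np.stack([s.frames.T for s in ds])
        probs = clf.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        acc = (probs.argmax(axis=1) == [0, 2, 4, 6]).mean()
        assert acc >= 0.99
        assert len(clf.history) == 150
        assert clf.history[-1] < clf.history[0]

    def test_training_is_seed_deterministic(self):
        ds = self._toy_windows_dataset()
        spec = ch.WindowSpec(10, 5)
        cfg = ch.ModelConfig(
            kernel_sizes=(3,), filters=8, n_blocks=1, reduction=4,
            seq_len=10, layer_norm="feature_map",
        )
        tc = ch.TrainConfig(epochs=5, batch_size=4, seed=12)
        h1 = train_window_classifier(ds, spec, cfg, tc).history
        h2 = train_window_classifier(ds, spec, cfg, tc).history
        assert h1 == h2
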