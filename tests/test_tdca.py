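"""TDCA references, projectors, augmentation, fitting and classification."""

import numpy as np
import pytest

import aobci
from aobci import tdca

from oracles import tdca_bruteforce_predict

FS = 500.0
FREQS = [4.6154, 5.4545, 7.5, 6.6667]


def _toy_instance(seed, n_ch=3, n_p=50, fs=60.0, freqs=(6.0, 8.0, 10.0, 12.0),
                  k_train=3, k_test=8, snr=1.0):
    """Random sinusoid-plus-noise trials for 4 classes."""
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_p + 1) / fs
    mix = rng.standard_normal((n_ch, 1))
    phases = rng.uniform(0, 2 * np.pi, size=4)

    def trial(cls):
        sig = np.sin(2 * np.pi * freqs[cls - 1] * t + phases[cls - 1])
        return snr * mix * sig + rng.standard_normal((n_ch, n_p))

    train_x, train_y = [], []
    for c in (1, 2, 3, 4):
        for _ in range(k_train):
            train_x.append(trial(c))
            train_y.append(c)
    test_x = [trial(rng.integers(1, 5)) for _ in range(k_test)]
    return train_x, np.array(train_y), test_x, freqs, fs


def _epochs_from_trials(trials, labels, fs=FS):
    data = np.stack(trials)
    return aobci.EpochSet(
        data=data, labels=labels, fs=fs, window=(0.0, data.shape[2] / fs),
        channel_names=[f"c{i}" for i in range(data.shape[1])],
    )


class TestReferences:
    def test_row_structure_and_first_sample(self):
        refs = tdca.build_references(FREQS, FS, 1500)
        y = refs.Y[1]
        assert y.shape == (4, 1500)
        f = FREQS[0]
        assert y[0, 0] == pytest.approx(np.sin(2 * np.pi * f / FS))
        assert y[1, 0] == pytest.approx(np.cos(2 * np.pi * f / FS))
        assert y[2, 0] == pytest.approx(np.sin(4 * np.pi * f / FS))

    def test_quarter_rate_closed_form(self):
        fs = 40.0
        refs = tdca.build_references([10.0, 5.0, 4.0, 2.0], fs, 8)
        # f = fs/4: sin(2 pi f t) at t = k/fs is the periodic {1, 0, -1, 0} pattern
        np.testing.assert_allclose(
            refs.Y[1][0], [1, 0, -1, 0, 1, 0, -1, 0], atol=1e-12
        )


class TestProjection:
    def test_projector_identities(self):
        refs = tdca.build_references(FREQS, FS, 300)
        proj = tdca.orthogonal_projection(refs)
        for i in refs.classes:
            p = proj.matrix(i)
            np.testing.assert_allclose(p, p.T, atol=1e-10)
            np.testing.assert_allclose(p @ p, p, atol=1e-10)
            assert np.trace(p) == pytest.approx(4.0, abs=1e-8)

    def test_row_space_preserved(self):
        refs = tdca.build_references(FREQS, FS, 300)
        proj = tdca.orthogonal_projection(refs)
        for i in refs.classes:
            np.testing.assert_allclose(
                proj.project(refs.Y[i], i), refs.Y[i], atol=1e-9
            )

    def test_rank_deficient_rejected(self):
        refs = tdca.build_references(FREQS, FS, 100)
        refs.Y[1][1] = refs.Y[1][0]  # duplicate row
        with pytest.raises(ValueError):
            tdca.orthogonal_projection(refs)


class TestAugment:
    def test_zero_delay_shape(self):
        refs = tdca.build_references(FREQS, FS, 200)
        proj = tdca.orthogonal_projection(refs)
        x = np.random.default_rng(0).standard_normal((8, 200))
        out = tdca.augment(x, 0, proj, 1)
        assert out.shape == (8, 400)
        np.testing.assert_array_equal(out[:, :200], x)

    def test_reference_space_fixed_point(self):
        refs = tdca.build_references(FREQS, FS, 200)
        proj = tdca.orthogonal_projection(refs)
        x = refs.Y[2][:2]  # rows inside class-2 reference space
        out = tdca.augment(x, 0, proj, 2)
        np.testing.assert_allclose(out[:, 200:], x, atol=1e-9)

    def test_delay_stacking(self):
        refs = tdca.build_references(FREQS, FS, 10)
        proj = tdca.orthogonal_projection(refs)
        x = np.arange(10.0)[None, :]
        out = tdca.augment(x, 2, proj, 1)
        assert out.shape == (3, 20)
        np.testing.assert_array_equal(out[1, :9], x[0, 1:])
        assert out[1, 9] == 0.0  # zero-padded tail

    def test_excessive_delay_rejected(self):
        refs = tdca.build_references(FREQS, FS, 10)
        proj = tdca.orthogonal_projection(refs)
        with pytest.raises(ValueError):
            tdca.augment(np.zeros((2, 10)), 10, proj, 1)


class TestFitClassify:
    def test_separable_classes_perfect_training_accuracy(self):
        train_x, train_y, _, freqs, fs = _toy_instance(0, snr=50.0)
        epochs = _epochs_from_trials(train_x, train_y, fs)
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        model = tdca.fit(epochs, refs)
        pred = tdca.predict(epochs, model, refs)
        np.testing.assert_array_equal(pred, train_y)

    def test_eigenvalues_non_increasing(self):
        train_x, train_y, _, freqs, fs = _toy_instance(1)
        epochs = _epochs_from_trials(train_x, train_y, fs)
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        model = tdca.fit(epochs, refs)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_template_trial_correlates_perfectly(self):
        train_x, train_y, _, freqs, fs = _toy_instance(2, snr=5.0)
        epochs = _epochs_from_trials(train_x, train_y, fs)
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        model = tdca.fit(epochs, refs)
        # feed the class-2 mean trial back in
        mean2 = epochs.data[train_y == 2].mean(axis=0)
        label, rho = tdca.classify(mean2, model, refs)
        assert label == 2
        assert rho[1] == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_labels(self):
        train_x, train_y, test_x, freqs, fs = _toy_instance(3, snr=1.5)
        epochs = _epochs_from_trials(train_x, train_y, fs)
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        model = tdca.fit(epochs, refs)
        base = [tdca.classify(x, model, refs)[0] for x in test_x]

        scaled = _epochs_from_trials([7.3 * x for x in train_x], train_y, fs)
        model_s = tdca.fit(scaled, refs)
        rescored = [tdca.classify(7.3 * x, model_s, refs)[0] for x in test_x]
        assert base == rescored

    def test_too_few_trials_per_class_rejected(self):
        train_x, train_y, _, freqs, fs = _toy_instance(4)
        keep = np.ones(len(train_y), dtype=bool)
        keep[np.flatnonzero(train_y == 1)[1:]] = False  # one trial for class 1
        epochs = _epochs_from_trials(
            [x for x, k in zip(train_x, keep) if k], train_y[keep], fs
        )
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        with pytest.raises(ValueError):
            tdca.fit(epochs, refs)

    def test_zero_variance_feature_rho_zero(self):
        train_x, train_y, _, freqs, fs = _toy_instance(5, snr=2.0)
        epochs = _epochs_from_trials(train_x, train_y, fs)
        refs = tdca.build_references(freqs, fs, epochs.n_samples)
        model = tdca.fit(epochs, refs)
        label, rho = tdca.classify(np.zeros_like(train_x[0]), model, refs)
        np.testing.assert_array_equal(rho, 0.0)
        assert label == 1  # tie broken to the smallest class index

    def test_matches_bruteforce_on_toy_instances(self):
        """Dense-eig + explicit-correlation oracle agrees label-for-label."""
        for seed in range(10):
            train_x, train_y, test_x, freqs, fs = _toy_instance(seed)
            expected = tdca_bruteforce_predict(train_x, train_y, test_x, freqs, fs)
            epochs = _epochs_from_trials(train_x, train_y, fs)
            refs = tdca.build_references(freqs, fs, epochs.n_samples)
            model = tdca.fit(epochs, refs)
            got = np.array([tdca.classify(x, model, refs)[0] for x in test_x])
            np.testing.assert_array_equal(got, expected)


class TestPreprocessForDecoding:
    def test_channel_count_and_crop(self, paradigms, tiny_plan, gen_config):
        epochs, _ = aobci.simulate_session(tiny_plan, paradigms, gen_config, 1)
        out = tdca.preprocess_for_decoding(epochs, 3.0)
        assert out.channel_names == tdca.DECODING_CHANNELS
        assert out.n_channels == 8
        assert out.n_samples == 1500

    @pytest.mark.parametrize("seg,n_p", [(1.0, 500), (2.0, 1000), (3.0, 1500)])
    def test_segment_lengths(self, paradigms, tiny_plan, gen_config, seg, n_p):
        epochs, _ = aobci.simulate_session(tiny_plan, paradigms, gen_config, 1)
        assert tdca.preprocess_for_decoding(epochs, seg).n_samples == n_p

    def test_in_band_tone_passes(self):
        fs = 500.0
        t = np.arange(-400, 2000) / fs
        tone = np.sin(2 * np.pi * 20.0 * t)
        data = np.tile(tone, (1, 8, 1))
        ep = aobci.EpochSet(data=data, labels=[1], fs=fs, window=(-0.8, 4.0),
                            channel_names=tdca.DECODING_CHANNELS)
        out = tdca.preprocess_for_decoding(ep, 3.0)
        mid = out.data[0, 0, 200:1300]
        assert np.abs(mid).max() == pytest.approx(1.0, abs=0.02)

    def test_missing_channel_raises(self):
        ep = aobci.EpochSet(data=np.zeros((1, 2, 100)), labels=[1], fs=500.0,
                            window=(0.0, 0.2), channel_names=["Oz", "O1"])
        with pytest.raises(KeyError):
            tdca.preprocess_for_decoding(ep, 0.1)


def test_model_serialization_roundtrip(tmp_path):
    train_x, train_y, test_x, freqs, fs = _toy_instance(6)
    epochs = _epochs_from_trials(train_x, train_y, fs)
    refs = tdca.build_references(freqs, fs, epochs.n_samples)
    model = tdca.fit(epochs, refs)
    model.save(tmp_path / "model")
    back = tdca.TDCAModel.load(tmp_path / "model")
    np.testing.assert_array_equal(back.W, model.W)
    for c in model.templates:
        np.testing.assert_array_equal(back.templates[c], model.templates[c])
    assert back.n_components == model.n_components


def test_confusion_matrix_rows_sum_to_class_counts():
    true = np.array([1, 1, 2, 3, 4, 4, 4])
    pred = np.array([1, 2, 2, 3, 4, 1, 4])
    cm = tdca.confusion_matrix(true, pred)
    np.testing.assert_array_equal(cm.sum(axis=1), [2, 1, 1, 3])
    assert cm.sum() == len(true)
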