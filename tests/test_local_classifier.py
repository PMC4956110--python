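"""Architecture arithmetic, network correctness, and the training protocol."""

import numpy as np
import pytest

from songscribe.annotations import Annotation, Note
from songscribe.architecture import (
    ArchitectureSpec,
    InvalidArchitectureError,
    LayerSpec,
    UnknownArrangementError,
    build_architecture,
    receptive_field_ms,
)
from songscribe.classifier import (
    NOT_TRAINABLE,
    TrainConfig,
    class_priors,
    derive_frame_labels,
    predict_frame_scores,
    train_ensemble,
)
from songscribe.nnet import Network, initialize_parameters
from songscribe.signal_features import (
    NormalizationStats,
    Spectrogram,
    SpectrogramParams,
)


class TestArchitecture:
    def test_narrow_window_shape_trace(self):
        arch = build_architecture("BD_LC_GS", 8)
        assert arch.n_outputs == 8
        assert arch.input_width == 96
        expected = [(112, 96), (108, 92), (108, 92), (54, 46), (50, 42), (50, 42),
                    (25, 21), (22, 18), (22, 18), (11, 9), (1, 1), (1, 1)]
        assert arch.shape_trace() == expected

    def test_fourth_layer_filter_width_is_nine(self):
        arch = build_architecture("BD_LC_GS", 8)
        conv4 = [l for l in arch.layers if l.kind == "convolution"][-1]
        assert conv4.filter_width == 9
        assert conv4.filter_height == 11
        assert conv4.channels == 240

    def test_subdivided_arrangements_have_3n_plus_1_outputs(self):
        assert build_architecture("LC_BDGS", 8).n_outputs == 25
        assert build_architecture("LCGS_BDGS", 8).n_outputs == 25
        assert build_architecture("LC_BDGS", 5).n_outputs == 16

    def test_inserted_layer_width_is_25_on_wide_window(self):
        arch = build_architecture("LCGS_BDGS", 8)
        assert arch.input_width == 288
        inserted = [l for l in arch.layers if l.inserted]
        assert len(inserted) == 1 and inserted[0].filter_width == 25
        # the fourth conv emits width 25 on the 288-frame input
        trace = arch.shape_trace()
        assert trace[-3] == (1, 25)

    def test_receptive_fields_in_ms(self):
        assert receptive_field_ms(96) == pytest.approx(111.0)
        assert receptive_field_ms(288) == pytest.approx(303.0)

    def test_unknown_arrangement_rejected(self):
        with pytest.raises(UnknownArrangementError):
            build_architecture("GS_FIRST", 8)

    def test_non_composing_layer_stack_rejected(self):
        layers = (LayerSpec("convolution", 4, 5, 5, activation="relu"),
                  LayerSpec("softmax_convolution", 3, 1, 1, activation="softmax"))
        with pytest.raises(InvalidArchitectureError):
            ArchitectureSpec("BD_LC_GS", 112, 96, 3, layers, 3)

    def test_temporal_stride_is_eight(self):
        assert build_architecture("LC_BDGS", 4).temporal_stride == 8


class TestFrameLabels:
    def test_equal_thirds_of_a_12_frame_note(self):
        ann = Annotation([Note(10, 22, "A")], 30)
        lab = derive_frame_labels(ann, "LC_BDGS", ["A", "B"])
        assert list(lab[10:14]) == [0] * 4
        assert list(lab[14:18]) == [1] * 4
        assert list(lab[18:22]) == [2] * 4
        assert lab[0] == 6 and lab[25] == 6  # silence class = 3n

    def test_floor_split_of_11_frames(self):
        ann = Annotation([Note(0, 11, "A")], 11)
        lab = derive_frame_labels(ann, "LCGS_BDGS", ["A"])
        assert list(lab) == [0] * 3 + [1] * 4 + [2] * 4

    def test_all_silence_annotation(self):
        lab = derive_frame_labels(Annotation([], 5), "LC_BDGS", ["A", "B"])
        assert list(lab) == [6] * 5

    def test_bd_arrangement_marks_silence_not_trainable(self):
        ann = Annotation([Note(2, 5, "B")], 8)
        lab = derive_frame_labels(ann, "BD_LC_GS", ["A", "B"])
        assert list(lab) == [NOT_TRAINABLE] * 2 + [1] * 3 + [NOT_TRAINABLE] * 3


class TestInitialization:
    def test_he_scaling_of_first_conv(self):
        net = initialize_parameters(build_architecture("BD_LC_GS", 8), seed=0)
        w = net.layers[0].W
        assert w.shape == (16, 25)
        assert w.std() == pytest.approx(np.sqrt(2 / 25), rel=0.05)

    def test_biases_zero_and_seed_deterministic(self):
        arch = build_architecture("LC_BDGS", 4)
        n1, n2 = Network(arch, seed=7), Network(arch, seed=7)
        for p1, p2 in zip(n1.parameters(), n2.parameters()):
            assert np.array_equal(p1, p2)
        for layer in n1.layers:
            if hasattr(layer, "b"):
                assert np.all(layer.b == 0)
        n3 = Network(arch, seed=8)
        assert not np.array_equal(n1.layers[0].W, n3.layers[0].W)


def tiny_arch():
    layers = (
        LayerSpec("convolution", 2, 3, 3, activation="relu"),
        LayerSpec("cccp", 2, 1, 1, activation="relu"),
        LayerSpec("maxpool", 0, 2, 2, stride=(2, 2)),
        LayerSpec("convolution", 4, 3, 3, activation="relu"),
        LayerSpec("softmax_convolution", 3, 1, 1, activation="softmax"),
    )
    return ArchitectureSpec("BD_LC_GS", 8, 8, 3, layers, 3)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        net = Network(tiny_arch(), seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 8, 8))
        labels = np.array([1])
        net.zero_grad()
        net.loss_and_grad(x, labels)
        grads = [g.copy() for g in net.gradients()]
        eps = 1e-6
        for p, g in zip(net.parameters(), grads):
            for _ in range(min(p.size, 12)):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp, _ = net.loss_and_grad(x, labels)
                p[idx] = old - eps
                lm, _ = net.loss_and_grad(x, labels)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) > 1e-8 or abs(g[idx]) > 1e-8:
                    assert abs(num - g[idx]) <= 1e-4 * max(abs(num), abs(g[idx]))


class TestDensePrediction:
    def test_dense_equals_per_window_evaluation(self):
        arch = build_architecture("LC_BDGS", 2)
        net = Network(arch, seed=1)
        rng = np.random.default_rng(0)
        t = 37
        x = rng.normal(size=(1, 112, arch.input_width + t - 1)).astype(np.float32)
        dense = net.predict_dense(x)
        wins = np.stack(
            [net.predict_strided(x[:, :, s : s + arch.input_width])[:, 0] for s in range(t)],
            axis=1,
        )
        assert np.abs(dense - wins).max() < 1e-5

    def test_columns_are_probability_vectors(self):
        arch = build_architecture("BD_LC_GS", 3)
        net = Network(arch, seed=2)
        x = np.random.default_rng(0).normal(size=(1, 112, 200)).astype(np.float32)
        dense = net.predict_dense(x)
        assert np.allclose(dense.sum(axis=0), 1.0, atol=1e-5)
        assert dense.min() >= 0


@pytest.fixture(scope="module")
def trained_setup():
    """A small ensemble trained on spectrally separable synthetic classes."""
    from songscribe.signal_features import (
        align_to_frame_grid,
        apply_normalization,
        compute_spectrogram,
        envelope_from_spectrogram,
        fit_normalization,
    )
    from songscribe.synthetic import default_config, generate_dataset

    params = SpectrogramParams()
    cfg = default_config(n_classes=3, seed=5, total_minutes=0.25)
    ds = generate_dataset(cfg)
    classes = [c.label for c in cfg.classes]
    prep = []
    for wave, ann in ds:
        spec = compute_spectrogram(wave, params)
        prep.append((spec, align_to_frame_grid(ann, params, spec.n_frames)))
    stats = fit_normalization([s for s, _ in prep])
    arch = build_architecture("LC_BDGS", 3)
    data = [
        (apply_normalization(s, stats), derive_frame_labels(a, "LC_BDGS", classes))
        for s, a in prep
    ]
    tc = TrainConfig.scaled(seed=0, lr_candidates=(0.004,), lr_probe_iterations=3,
                            max_iterations=45, minibatch_seconds=3.0, eval_interval=15,
                            patience=1, halvings=1)
    ens = train_ensemble(data, arch, tc, stats, classes)
    return ens, data, prep, stats


class TestTraining:
    def test_ensemble_has_three_members_sharing_architecture(self, trained_setup):
        ens, *_ = trained_setup
        assert len(ens.members) == 3
        assert all(m.arch is ens.architecture or m.arch == ens.architecture
                   for m in ens.members)

    def test_learns_beyond_majority_baseline(self, trained_setup):
        """Per-frame accuracy beats the majority class by a wide margin on
        spectrally separable classes."""
        ens, data, *_ = trained_setup
        correct = total = 0
        majority = {}
        for spec, labels in data:
            sm = predict_frame_scores(ens, spec, dense=False)
            pred = sm.scores.argmax(axis=0)
            mask = labels >= 0
            correct += int((pred[mask] == labels[mask]).sum())
            total += int(mask.sum())
            for v in labels[mask]:
                majority[v] = majority.get(v, 0) + 1
        acc = correct / total
        base = max(majority.values()) / total
        assert acc >= base + 0.30

    def test_scores_sum_to_one_and_cover_every_frame(self, trained_setup):
        ens, data, *_ = trained_setup
        spec, _ = data[0]
        sm = predict_frame_scores(ens, spec)
        assert sm.scores.shape == (ens.architecture.n_outputs, spec.n_frames)
        assert np.allclose(sm.scores.sum(axis=0), 1.0, atol=1e-5)

    def test_constant_input_gives_constant_scores(self, trained_setup):
        ens, *_ = trained_setup
        params = SpectrogramParams()
        flat = Spectrogram(values=np.zeros((112, 150)), params=params, normalized=True)
        sm = predict_frame_scores(ens, flat)
        assert np.allclose(sm.scores, sm.scores[:, :1], atol=1e-5)

    def test_unnormalized_input_rejected(self, trained_setup):
        ens, _, prep, _ = trained_setup
        with pytest.raises(ValueError):
            predict_frame_scores(ens, prep[0][0])

    def test_class_priors_are_frame_frequencies(self):
        labs = [np.array([0, 0, 1, 3, 3, 3, NOT_TRAINABLE])]
        pri = class_priors(labs, 4)
        assert pri == pytest.approx([2 / 6, 1 / 6, 1e-6, 3 / 6], rel=1e-3)
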