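"""Network engine: shape audits, parameter counts, gradients, training."""

import numpy as np
import pytest

from eegtriage.nn import (
    Model,
    NetworkSpec,
    TrainConfig,
    build_feature_network,
    build_lstm_network,
    build_sfn,
    build_stft_network,
    build_tmn,
    compute_topographic_maps,
    predict_scores,
    topomap_to_network_input,
    train_network,
)
from eegtriage.nn.layers import (
    AvgPool1D, BatchNorm, Concat, Conv1D, Conv2D, Dense, Dropout, Flatten,
    GlobalAvgPool, LeakyReLU, MaxPool1D, MaxPool2D, ReLU, Softmax, Subtract,
)
from eegtriage.nn.layers_lstm import LSTM


class TestParameterAudits:
    def test_single_dense_layer_count(self):
        spec = NetworkSpec(input_shape=(10,))
        spec.add("fc", Dense(3))
        assert spec.count_parameters() == 33

    def test_feature_network_layer_arithmetic(self):
        spec = build_feature_network(100)
        by_name = {r["name"]: r["params"] for r in spec.layer_summary()}
        assert by_name["fc500"] == 100 * 500 + 500
        assert by_name["bn1"] == 1000
        assert by_name["fc100"] == 500 * 100 + 100
        assert by_name["fc3"] == 303
        assert spec.count_parameters() == sum(by_name.values()) == 102103

    def test_tmn_first_conv_is_448(self):
        by_name = {r["name"]: r["params"] for r in build_tmn().layer_summary()}
        assert by_name["conv1"] == 6 * 64 + 64 == 448

    def test_lstm_classifier_head_is_771(self):
        by_name = {
            r["name"]: r["params"] for r in build_lstm_network().layer_summary()
        }
        assert by_name["fc3"] == 256 * 3 + 3 == 771

    def test_stft_network_audited_total(self):
        spec = build_stft_network()
        # forced by the audited shapes: two k=1 convs on 38 channels, one on
        # the 4902-channel flattened transform, FC(100) on 8320, FC(3)
        assert spec.count_parameters() == 1_148_691

    def test_sfn_audited_total(self):
        assert build_sfn().count_parameters() == 7_880_963

    def test_counts_are_seed_and_instance_free(self):
        spec = build_feature_network(50)
        n = spec.count_parameters()
        total = sum(
            arr.size for _, key, arr in Model(spec, seed=9).trainable_items()
        )
        assert total == n


class TestShapeAudits:
    def test_stft_stage_and_concat_shapes(self):
        shapes = build_stft_network().audit_shapes()
        assert shapes["stft"] == (38, 129, 559)
        assert shapes["cat_all"] == (8320, 559)
        assert shapes["fc3"] == (3,)

    def test_all_architectures_compose_to_three_classes(self):
        specs = [
            build_feature_network(1406), build_tmn(), build_stft_network(),
            build_lstm_network(), build_sfn(),
        ]
        for spec in specs:
            assert spec.audit_shapes()[spec.output] == (3,)

    def test_lstm_pooling_length_recurrence(self):
        shapes = build_lstm_network().audit_shapes()
        # three stride-2 'same' pools: 18000 -> 9000 -> 4500 -> 2250
        assert shapes["pool1"][-1] == 9000
        assert shapes["pool2"][-1] == 4500
        assert shapes["pool3"][-1] == 2250

    def test_layer_totals_logged_for_reference(self):
        # drawing-convention-dependent; recorded, not asserted against print
        assert build_stft_network().n_layers() >= 15
        assert build_sfn().n_layers() > 400

    def test_inconsistent_graph_rejected(self):
        spec = NetworkSpec(input_shape=(4, 10))
        spec.add("fc", Dense(3))
        spec.add("bad", Concat(), ["fc", "input"])
        with pytest.raises(ValueError, match="bad"):
            spec.audit_shapes()

    def test_sfn_unknown_montage_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            build_sfn(montage_pairs=(("FP1", "XX"),))


class TestSerialization:
    @pytest.mark.parametrize("builder,kw", [
        (build_feature_network, {"input_dim": 77}),
        (build_stft_network, {}),
        (build_lstm_network, {}),
        (build_tmn, {}),
    ])
    def test_spec_round_trips_through_dict(self, builder, kw):
        spec = builder(**kw)
        clone = NetworkSpec.from_dict(spec.to_dict())
        assert clone.to_dict() == spec.to_dict()
        assert clone.count_parameters() == spec.count_parameters()

    def test_spec_round_trips_through_json(self, tmp_path):
        spec = build_feature_network(12)
        spec.to_json(tmp_path / "spec.json")
        clone = NetworkSpec.from_json(tmp_path / "spec.json")
        assert clone.to_dict() == spec.to_dict()


def _num_grad(f, arr, idx, eps=1e-6):
    arr[idx] += eps
    up = f()
    arr[idx] -= 2 * eps
    down = f()
    arr[idx] += eps
    return (up - down) / (2 * eps)


class TestGradients:
    """Finite-difference checks for every trainable/structural layer."""

    @pytest.mark.parametrize("layer,shape", [
        (Dense(4), (6,)),
        (BatchNorm(), (5,)),
        (Conv1D(3, 5, 2), (2, 17)),
        (Conv1D(2, 1, 1), (3, 4, 9)),       # image input, k=1 along time
        (Conv2D(3, (3, 3), (2, 2)), (2, 9, 11)),
        (MaxPool1D(3, 2), (2, 13)),
        (MaxPool2D((3, 3), (2, 2)), (2, 8, 9)),
        (AvgPool1D(4, 2), (2, 12)),
        (GlobalAvgPool(), (3, 7)),
        (Flatten(), (2, 3, 5)),
        (LSTM(4), (3, 6)),
        (LeakyReLU(0.01), (4,)),
    ])
    def test_layer_backward_matches_finite_differences(self, layer, shape):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3,) + shape)
        params = layer.init_params([shape], rng)
        w_out = rng.standard_normal(layer.out_shape([shape]))
        # batch-norm backward differentiates the batch statistics, which only
        # enter the forward pass in training mode
        training = isinstance(layer, BatchNorm)

        def objective():
            y, _ = layer.forward([x], params, training=training)
            return float((y * w_out).sum())

        y, cache = layer.forward([x], params, training=training)
        dxs, dparams = layer.backward(np.broadcast_to(w_out, y.shape).copy(),
                                      cache, params)
        # input gradient
        i = tuple(np.unravel_index(1, x.shape))
        assert _num_grad(objective, x, i) == pytest.approx(dxs[0][i], abs=1e-4)
        # parameter gradients
        for key, g in dparams.items():
            j = tuple(0 for _ in params[key].shape)
            assert _num_grad(objective, params[key], j) == pytest.approx(
                g[j], abs=1e-4
            )

    def test_subtract_backward(self):
        layer = Subtract()
        a, b = np.ones((2, 3)), np.ones((2, 3))
        y, cache = layer.forward([a, b], {})
        dxs, _ = layer.backward(np.full((2, 3), 2.0), cache, {})
        assert np.all(dxs[0] == 2.0) and np.all(dxs[1] == -2.0)


class TestForwardContracts:
    def test_softmax_rows_sum_to_one(self):
        m = Model(build_feature_network(20), seed=0)
        out = m.predict_proba(np.random.default_rng(0).standard_normal((7, 20)))
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_zero_input_gives_uniform_softmax(self):
        m = Model(build_tmn(), seed=1)
        out, _ = m.forward(np.zeros((1, 6, 134, 134)))
        assert np.allclose(out, 1 / 3, atol=1e-12)

    def test_stft_network_forward_emits_three_scores(self):
        m = Model(build_stft_network(), seed=2)
        out, _ = m.forward(np.random.default_rng(2).standard_normal((1, 19, 18000)))
        assert out.shape == (1, 3)
        assert out.sum() == pytest.approx(1.0)

    def test_sfn_identical_pair_members_give_zero_difference(self):
        spec = build_sfn()
        m = Model(spec, seed=3)
        # tie the FP1 and F7 path weights together and feed every channel the
        # same signal: the FP1-F7 bipolar difference must vanish exactly
        for node, params in m.params.items():
            if node.startswith("FP1."):
                twin = "F7." + node.split(".", 1)[1]
                for key in params:
                    m.params[twin][key] = params[key].copy()
        x = np.tile(np.random.default_rng(3).standard_normal(18000), (19, 1))
        _, acts = m.forward(x[None])
        diff_nodes = [n.name for n in spec.nodes if n.name.startswith("diff.")]
        assert len(diff_nodes) == 18
        assert np.abs(acts["diff.FP1-F7"]).max() < 1e-9

    def test_batch_order_invariance(self):
        m = Model(build_feature_network(15), seed=4)
        X = np.random.default_rng(4).standard_normal((6, 15))
        out = m.predict_proba(X)
        perm = np.array([3, 1, 5, 0, 2, 4])
        assert np.allclose(m.predict_proba(X[perm]), out[perm])


class TestTopographicMaps:
    def test_tensor_shape_and_disc_support(self, normal_segment):
        maps = compute_topographic_maps(normal_segment)
        assert maps.shape == (134, 134, 6)
        grid = np.linspace(-1, 1, 134)
        gx, gy = np.meshgrid(grid, grid)
        assert np.all(maps[gx**2 + gy**2 > 1.0] == 0.0)
        assert np.all(np.isfinite(maps))
        assert topomap_to_network_input(maps).shape == (6, 134, 134)

    def test_interpolation_exact_at_electrodes(self, normal_segment):
        from eegtriage.channels import CANONICAL_19, SCALP_POSITIONS
        from eegtriage.features import band_psd_array

        maps = compute_topographic_maps(normal_segment)
        _, rel = band_psd_array(normal_segment.data, normal_segment.fs)
        grid = np.linspace(-1, 1, 134)
        for ci, ch in enumerate(CANONICAL_19):
            x, y = SCALP_POSITIONS[ch]
            ix = np.argmin(np.abs(grid - x))
            iy = np.argmin(np.abs(grid - y))
            # nearest pixel within the grid pitch of the exact node value
            assert maps[iy, ix, 2] == pytest.approx(rel[ci, 2], abs=0.05)

    def test_occipital_alpha_peaks_at_the_back(self):
        from tests.conftest import FS, SEG_SAMPLES, make_segment

        rng = np.random.default_rng(5)
        t = np.arange(SEG_SAMPLES) / FS
        data = rng.standard_normal((19, SEG_SAMPLES)) * 0.5
        data[8] += 30 * np.sin(2 * np.pi * 10 * t)  # O1
        data[9] += 30 * np.sin(2 * np.pi * 10 * t)  # O2
        maps = compute_topographic_maps(make_segment(data))
        alpha = maps[:, :, 2]
        iy, ix = np.unravel_index(np.argmax(alpha), alpha.shape)
        assert iy < 40  # occipital = strongly negative y = low row index

    def test_coincident_positions_rejected(self, normal_segment):
        from eegtriage.channels import SCALP_POSITIONS

        bad = dict(SCALP_POSITIONS)
        bad["FP1"] = bad["FP2"]
        with pytest.raises(ValueError, match="coincident"):
            compute_topographic_maps(normal_segment, positions=bad)


class TestShallowPresets:
    def test_presets_expose_fit_predict_proba_interface(self):
        from eegtriage.nn import SHALLOW_PRESETS

        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 8))
        y = np.repeat(["Normal", "TBI", "Stroke"], 20)
        X[:20, 0] += 3; X[20:40, 1] += 3; X[40:, 2] += 3
        for name, factory in SHALLOW_PRESETS.items():
            clf = factory()
            clf.fit(X, y)
            proba = clf.predict_proba(X)
            assert proba.shape == (60, 3), name
            assert np.allclose(proba.sum(axis=1), 1.0), name


class TestTraining:
    def test_memorizes_small_separable_problem(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 10))
        y = np.repeat(["Normal", "TBI", "Stroke"], 20)
        X[:20, 0] += 4; X[20:40, 1] += 4; X[40:, 2] += 4
        spec = build_feature_network(10)
        tr = train_network(spec, X, y, TrainConfig(max_epochs=60, seed=0,
                                                   standardize=True,
                                                   patience=60, holdout=0.2))
        pred = np.argmax(predict_scores(tr, X), axis=1)
        truth = np.array([tr.classes.index(c) for c in y])
        assert (pred == truth).mean() > 0.9

    def test_fixed_seed_reproduces_loss_history(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 8))
        y = np.repeat(["Normal", "TBI"], 20)
        cfg = TrainConfig(max_epochs=5, seed=3, holdout=0.25)
        a = train_network(build_feature_network(8), X, y, cfg)
        b = train_network(build_feature_network(8), X, y, cfg)
        assert a.history == b.history

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            train_network(build_feature_network(5), np.zeros((10, 6)),
                          ["Normal"] * 10)

    def test_divergence_aborts_with_diagnostic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4)) * 1e6
        y = np.repeat(["Normal", "TBI"], 15)
        spec = NetworkSpec(input_shape=(4,))
        spec.add("fc", Dense(3))
        spec.add("sm", Softmax())
        with pytest.raises(FloatingPointError, match="diverged"):
            # Adam updates are lr-bounded, so only an overflowing rate
            # produces non-finite logits
            train_network(spec, X**3, y,
                          TrainConfig(learning_rate=1e300, max_epochs=3,
                                      holdout=0.2, seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(holdout=1.5)
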