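import numpy as np
import pytest

from rcmpm import nn
from rcmpm.contact_geometry import ContactMap
from rcmpm.graph_builder import ContactGraph, build_contact_graph
from rcmpm.io_formats import ScoreMatrix
from rcmpm.model import (
    ModelConfig,
    Prediction,
    TrainExample,
    TrainingDiverged,
    forward_trace,
    gcn_forward,
    init_params,
    load_checkpoint,
    loss,
    minmax_normalize,
    outer_concat,
    predict,
    resnet1d_forward,
    resnet2d_forward,
    save_checkpoint,
    train,
)
from tests.conftest import random_contact_map, random_graph


def empty_graph(L: int) -> ContactGraph:
    return build_contact_graph(ScoreMatrix(np.zeros((L, L))), edge_threshold=0.5)


def tiny_config(**kw) -> ModelConfig:
    base = dict(n=4, blocks_1d=1, blocks_2d=1, width_2d=6, epochs=1, seed=3)
    base.update(kw)
    return ModelConfig(**base)


class TestMinmaxNormalize:
    def test_linear_column(self):
        out = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        assert not minmax_normalize(np.array([[3.0], [3.0]])).any()

    def test_output_range(self, rng):
        out = minmax_normalize(rng.normal(size=(9, 5)))
        assert np.allclose(out.min(axis=0), 0)
        assert np.allclose(out.max(axis=0), 1)


class TestGcnForward:
    def test_identity_graph_collapses_to_normalized_input(self, rng):
        L = 6
        cfg = tiny_config(n=26)
        params = init_params(cfg)
        params["gcn.w0"] = nn.parameter(np.eye(26))
        params["gcn.w1"] = nn.parameter(np.eye(26))
        x_seq = rng.normal(size=(L, 26))
        out = gcn_forward(empty_graph(L), x_seq, params)
        # A~ = I: two layers reduce to ReLU(minmax(...)) twice; the first
        # min-max already lands in [0, 1], so the result is minmax(x_seq)
        assert np.allclose(out, minmax_normalize(x_seq))

    def test_identical_nodes_get_identical_embeddings(self, rng):
        cfg = tiny_config()
        params = init_params(cfg)
        row = rng.normal(size=26)
        x_seq = np.vstack([row, row])
        full = build_contact_graph(ScoreMatrix(np.ones((2, 2))), 0.5)
        out = gcn_forward(full, x_seq, params)
        assert np.allclose(out[0], out[1])

    def test_output_nonnegative(self, rng):
        params = init_params(tiny_config())
        out = gcn_forward(random_graph(8, rng), rng.normal(size=(8, 26)), params)
        assert out.min() >= 0

    def test_permutation_equivariance(self, rng):
        L = 9
        cfg = tiny_config()
        params = init_params(cfg)
        x_seq = rng.normal(size=(L, 26))
        graph = random_graph(L, rng)
        perm = rng.permutation(L)
        permuted_graph = ContactGraph(
            adjacency=graph.adjacency[np.ix_(perm, perm)],
            weights=graph.weights[np.ix_(perm, perm)],
        )
        out = gcn_forward(graph, x_seq, params)
        out_perm = gcn_forward(permuted_graph, x_seq[perm], params)
        assert np.allclose(out_perm, out[perm], atol=1e-10)


class TestResnet1d:
    def test_zero_weights_pure_skip(self, rng):
        # equal channel counts: n = 26 keeps identity skips everywhere
        cfg = tiny_config(n=26, blocks_1d=3)
        params = init_params(cfg)
        for key, p in params.items():
            if key.startswith("res1d"):
                p.data[:] = 0.0
        x_seq = rng.normal(size=(7, 26))
        assert np.allclose(resnet1d_forward(x_seq, params, cfg), x_seq)

    def test_length_preserved(self, rng):
        cfg = tiny_config(blocks_1d=3)
        out = resnet1d_forward(rng.normal(size=(7, 26)), init_params(cfg), cfg)
        assert out.shape == (7, cfg.n)

    def test_two_block_stack_composes_single_blocks(self, rng):
        cfg2 = tiny_config(n=26, blocks_1d=2, seed=9)
        params2 = init_params(cfg2)
        x = rng.normal(size=(6, 26))
        out2 = resnet1d_forward(x, params2, cfg2)
        # apply block 0 then block 1 sequentially through 1-block configs
        cfg1 = tiny_config(n=26, blocks_1d=1, seed=9)
        p_first = {k: v for k, v in params2.items() if not k.startswith("res1d.1")}
        p_second = {
            k.replace("res1d.1", "res1d.0"): v
            for k, v in params2.items()
            if not k.startswith("res1d.0")
        }
        mid = resnet1d_forward(x, p_first, cfg1)
        assert np.allclose(resnet1d_forward(mid, p_second, cfg1), out2)


class TestOuterConcat:
    def test_hand_unrolled_l2(self):
        x_1d = np.array([[1.0], [2.0]])
        x_gcn = np.array([[3.0], [4.0]])
        x_pair = np.arange(20, dtype=float).reshape(2, 2, 5)
        out = outer_concat(x_gcn, x_1d, x_pair)
        # entry (0, 1): [row_0 of (1d|gcn), row_1 of (1d|gcn), pair_01]
        assert np.allclose(out[0, 1, :4], [1, 3, 2, 4])
        assert np.allclose(out[0, 1, 4:], x_pair[0, 1])

    def test_shape(self, rng):
        out = outer_concat(
            rng.normal(size=(5, 4)), rng.normal(size=(5, 4)),
            rng.normal(size=(5, 5, 5)),
        )
        assert out.shape == (5, 5, 21)

    def test_swapping_ij_swaps_residue_blocks(self, rng):
        n, L = 3, 4
        x_pair = rng.normal(size=(L, L, 5))
        x_pair = (x_pair + x_pair.transpose(1, 0, 2)) / 2
        out = outer_concat(rng.normal(size=(L, n)), rng.normal(size=(L, n)), x_pair)
        for i in range(L):
            for j in range(L):
                assert np.allclose(out[i, j, : 2 * n], out[j, i, 2 * n : 4 * n])
                assert np.allclose(out[i, j, 4 * n :], out[j, i, 4 * n :])


class TestResnet2d:
    def test_zero_blocks_act_as_identity(self, rng):
        cfg = tiny_config()
        params = init_params(cfg)
        for key, p in params.items():
            if key.startswith("res2d.0."):
                p.data[:] = 0.0
        x2d = rng.normal(size=(5, 5, 4 * cfg.n + 5))
        got = resnet2d_forward(x2d, params, cfg)
        # manually: entry conv then head conv
        entry = nn.conv2d(
            nn.constant(x2d), params["res2d.entry.w"], params["res2d.entry.b"]
        )
        expected = nn.conv2d(entry, params["res2d.head.w"], params["res2d.head.b"]).data
        assert np.allclose(got, expected)

    def test_logit_shape(self, rng):
        cfg = tiny_config()
        x2d = rng.normal(size=(9, 9, 4 * cfg.n + 5))
        assert resnet2d_forward(x2d, init_params(cfg), cfg).shape == (9, 9, 2)

    def test_finite_on_random_input(self, rng):
        cfg = tiny_config(blocks_2d=3)
        x2d = rng.normal(size=(6, 6, 4 * cfg.n + 5))
        assert np.isfinite(resnet2d_forward(x2d, init_params(cfg), cfg)).all()


class TestShapeChain:
    @pytest.mark.parametrize("L", [8, 30, 61])
    @pytest.mark.parametrize("n", [4, 32])
    def test_forward_trace_shapes(self, rng, L, n):
        cfg = tiny_config(n=n)
        params = init_params(cfg)
        trace = forward_trace(
            params, cfg, random_graph(L, rng),
            rng.normal(size=(L, 26)), rng.normal(size=(L, L, 5)),
        )
        assert trace.x_gcn.shape == (L, n)
        assert trace.x_1dresnet.shape == (L, n)
        assert trace.x_1dfinal.shape == (L, 2 * n)
        assert trace.integrate_gcn.shape == (L, L, 4 * n)
        assert trace.x_2dinput.shape == (L, L, 4 * n + 5)
        assert trace.x_2dresnet.shape == (L, L, cfg.width_2d)
        assert trace.logits.shape == (L, L, 2)


class TestPredictAndLoss:
    def test_zero_logits_give_half_probability(self, rng):
        cfg = tiny_config()
        params = init_params(cfg)
        for key in ("res2d.head.w", "res2d.head.b"):
            params[key].data[:] = 0.0
        pred = predict(params, cfg, random_graph(4, rng),
                       rng.normal(size=(4, 26)), rng.normal(size=(4, 4, 5)))
        assert np.allclose(pred.probs, 0.5)

    def test_class_probabilities_sum_to_one_and_map_symmetric(self, rng):
        cfg = tiny_config()
        pred = predict(init_params(cfg), cfg, random_graph(6, rng),
                       rng.normal(size=(6, 26)), rng.normal(size=(6, 6, 5)))
        assert np.abs(pred.class_probs.sum(axis=-1) - 1).max() < 1e-6
        assert np.array_equal(pred.probs, pred.probs.T)

    def test_perfect_prediction_zero_loss(self, rng):
        truth = random_contact_map(5, rng)
        t = truth.labels.astype(float)
        pred = Prediction(probs=t, class_probs=np.stack([1 - t, t], axis=-1))
        assert loss(pred, truth) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_on_all_contacts_is_ln2(self):
        truth = ContactMap(np.ones((2, 2), dtype=np.int8))
        class_probs = np.full((2, 2, 2), 0.5)
        assert loss(class_probs, truth) == pytest.approx(np.log(2), abs=1e-12)

    def test_loss_invariant_under_joint_transposition(self, rng):
        truth = random_contact_map(6, rng)
        class_probs = rng.random((6, 6, 2))
        class_probs /= class_probs.sum(axis=-1, keepdims=True)
        assert loss(class_probs, truth) == pytest.approx(
            loss(class_probs.transpose(1, 0, 2), truth), abs=1e-12
        )


def make_examples(rng, n_proteins=2, L=14):
    examples = []
    for _ in range(n_proteins):
        truth = random_contact_map(L, rng)
        examples.append(
            TrainExample(
                x_seq=rng.normal(size=(L, 26)),
                x_pair=rng.normal(size=(L, L, 5)),
                graph=random_graph(L, rng),
                truth=truth,
            )
        )
    return examples


class TestTraining:
    def test_seeded_runs_bit_identical(self, rng):
        examples = make_examples(rng)
        cfg = tiny_config(epochs=3, seed=7)
        h1 = train(examples, cfg).loss_history
        h2 = train(examples, cfg).loss_history
        assert h1 == h2

    def test_loss_decreases_on_synthetic_proteins(self):
        from rcmpm.pipeline import featurize_protein
        from rcmpm.synthetic_data import GeneratorConfig, make_dataset

        gen = GeneratorConfig(n_proteins=5, L_range=(30, 30), seed=2)
        cfg = ModelConfig.desk(epochs=50, seed=2)
        dataset = [featurize_protein(p, cfg) for p in make_dataset(gen)]
        result = train(dataset, cfg)
        assert result.loss_history[-1] < result.loss_history[0]

    def test_zero_learning_rate_keeps_parameters(self, rng):
        examples = make_examples(rng, n_proteins=1)
        cfg = tiny_config(epochs=2, learning_rate=0.0, seed=5)
        before = {k: v.data.copy() for k, v in init_params(cfg).items()}
        result = train(examples, cfg)
        for key, value in before.items():
            assert np.array_equal(result.params[key].data, value)

    def test_divergence_raises(self, rng):
        examples = make_examples(rng, n_proteins=1)
        cfg = tiny_config(epochs=2, seed=5)
        params = init_params(cfg)
        params["res2d.head.b"].data[:] = np.inf
        with pytest.raises(TrainingDiverged):
            train(examples, cfg, params=params)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = tiny_config()
        params = init_params(cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(params, cfg, path)
        loaded_params, loaded_cfg = load_checkpoint(path)
        assert loaded_cfg == cfg
        for key, p in params.items():
            assert np.array_equal(loaded_params[key].data, p.data)


class TestGradientCheck:
    def test_autodiff_matches_finite_differences(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(5))
        L = 8
        x_seq = rng.normal(size=(L, 26))
        x_pair = rng.normal(size=(L, L, 5))
        graph = random_graph(L, rng)
        truth = random_contact_map(L, rng)
        targets = np.stack(
            [1.0 - truth.labels, truth.labels.astype(float)], axis=-1
        )
        from rcmpm.model import _forward

        def objective():
            acts = _forward(params, cfg, graph.propagation, x_seq, x_pair)
            return nn.softmax_cross_entropy(acts["logits"], targets)

        obj = objective()
        obj.backward()
        eps = 1e-6
        for name, p in params.items():
            flat = int(rng.integers(p.data.size))
            idx = np.unravel_index(flat, p.data.shape)
            analytic = p.grad[idx]
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = objective().data
            p.data[idx] = orig - eps
            lm = objective().data
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            rel = abs(analytic - fd) / max(abs(fd), abs(analytic), 1e-8)
            assert rel < 1e-4, f"{name}: autodiff {analytic} vs FD {fd}"
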