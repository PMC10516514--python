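"""Network layers against naive-loop oracles, shapes, and wiring."""

import numpy as np
import pytest

from pepmhc import autodiff as ad
from pepmhc.data import VOCABULARY, MHCAllele
from pepmhc.model import Model, ModelConfig

# ---------------------------------------------------------------------------
# independent naive-loop oracles
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gate_oracle(X, W, V, b, c):
    """Per-position loop: sigmoid(W_i x_i + b_i) * (V_i x_i + c_i)."""
    L, d = X.shape
    out = np.zeros_like(X, dtype=np.float64)
    for i in range(L):
        out[i] = sigmoid(W[i] @ X[i] + b[i]) * (V[i] @ X[i] + c[i])
    return out


def kernels_oracle(Y, U):
    """Explicit matrix product K_i = relu(U_i Y) per kernel."""
    H = U.shape[0]
    return np.stack([np.maximum(U[i].astype(np.float64) @ Y, 0.0) for i in range(H)])


def bicl_oracle(X, Y, model, branch):
    """Triple-loop sliding-window convolution with per-size zero padding."""
    cfg = model.config
    L, d = X.shape
    J = cfg.conv_width
    chunks = []
    for k, H in cfg.kernel_spec.items():
        U = model.params[f"bicl{branch}.U{k}"].data
        bias = model.params[f"bicl{branch}.b{k}"].data
        K = kernels_oracle(Y, U)
        pad = (k - 9) // 2
        Xp = np.vstack([np.zeros((pad, d)), X, np.zeros((pad, d))])
        C = np.zeros((H, J))
        for i in range(H):
            for j in range(J):
                window = Xp[j : j + k]
                C[i, j] = max(float(np.sum(K[i] * window)) + bias[i], 0.0)
        chunks.append(C)
    return np.vstack(chunks)


def head_oracle(C0, model):
    """Per-position matmuls, eval-mode normalization, max, dot, sigmoid."""
    cfg = model.config
    J = cfg.conv_width
    Z = C0.T.astype(np.float64)  # (J, channels)
    for n in range(1, len(cfg.fc_dims) + 1):
        W = model.params[f"fc{n}.W"].data
        gamma = model.params[f"bn_fc{n}.gamma"].data
        beta = model.params[f"bn_fc{n}.beta"].data
        mu = model.bn_state[f"bn_fc{n}.mean"]
        var = model.bn_state[f"bn_fc{n}.var"]
        nxt = np.zeros((J, W.shape[1]))
        for j in range(J):
            z = W.T @ Z[j]
            z = gamma * (z - mu) / np.sqrt(var + 1e-5) + beta
            nxt[j] = np.maximum(z, 0.0)
        Z = nxt
    g = Z.max(axis=0)
    return float(sigmoid(g @ model.params["out.w"].data[:, 0] + model.params["out.b"].data[0]))


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

N_INSTANCES = 100


class TestLayerOracles:
    def test_position_gate_matches_loop(self, small_model, rng):
        L, d = small_model.config.model_length, small_model.config.embed_dim
        W = small_model.params["gate.W"].data
        V = small_model.params["gate.V"].data
        # randomize biases too so the oracle sees generic parameters
        small_model.params["gate.b"].data = rng.normal(size=(L, d)).astype(ad.DTYPE)
        small_model.params["gate.c"].data = rng.normal(size=(L, d)).astype(ad.DTYPE)
        b = small_model.params["gate.b"].data
        c = small_model.params["gate.c"].data
        for _ in range(N_INSTANCES):
            X = rng.normal(size=(L, d))
            np.testing.assert_allclose(
                small_model.position_gate(X), gate_oracle(X, W, V, b, c), atol=1e-5
            )

    def test_gate_closed_form_cases(self, small_model):
        cfg = small_model.config
        L, d = cfg.model_length, cfg.embed_dim
        eye = np.tile(np.eye(d), (L, 1, 1))
        small_model.params["gate.W"].data = np.zeros((L, d, d), dtype=ad.DTYPE)
        small_model.params["gate.V"].data = eye.astype(ad.DTYPE)
        small_model.params["gate.b"].data = np.zeros((L, d), dtype=ad.DTYPE)
        small_model.params["gate.c"].data = np.zeros((L, d), dtype=ad.DTYPE)
        X = np.random.default_rng(3).normal(size=(L, d))
        # zero gate logits: sigmoid(0) = 0.5 scales X
        np.testing.assert_allclose(small_model.position_gate(X), 0.5 * X, atol=1e-6)
        # saturated gate (+30 bias) passes X through
        small_model.params["gate.b"].data = np.full((L, d), 30.0, dtype=ad.DTYPE)
        np.testing.assert_allclose(small_model.position_gate(X), X, atol=1e-6)

    def test_generate_kernels_matches_product(self, small_model, rng):
        d = small_model.config.embed_dim
        for _ in range(N_INSTANCES):
            Y = rng.normal(size=(34, d))
            ours = small_model.generate_kernels(Y)
            for k, H in small_model.config.kernel_spec.items():
                U = small_model.params[f"bicl2.U{k}"].data
                np.testing.assert_allclose(ours[k], kernels_oracle(Y, U), atol=1e-5)

    def test_zero_U_gives_zero_kernels(self, small_model, rng):
        for k in small_model.config.kernel_spec:
            small_model.params[f"bicl2.U{k}"].data[:] = 0.0
        out = small_model.generate_kernels(np.abs(rng.normal(size=(34, small_model.config.embed_dim))))
        assert all(np.all(v == 0) for v in out.values())

    def test_kernels_depend_on_pseudo_sequence(self, small_model, rng):
        d = small_model.config.embed_dim
        Y1, Y2 = rng.normal(size=(34, d)), rng.normal(size=(34, d))
        k = next(iter(small_model.config.kernel_spec))
        assert not np.allclose(
            small_model.generate_kernels(Y1)[k], small_model.generate_kernels(Y2)[k]
        )

    def test_bicl_matches_sliding_window_loop(self, small_model, rng):
        cfg = small_model.config
        L, d = cfg.model_length, cfg.embed_dim
        for _ in range(N_INSTANCES):
            X = rng.normal(size=(L, d))
            Y = rng.normal(size=(34, d))
            ours = small_model.bicl_forward(X, Y)
            np.testing.assert_allclose(ours, bicl_oracle(X, Y, small_model, 2), atol=1e-5)

    def test_bicl_zero_kernels_negative_bias(self, small_model, rng):
        for k in small_model.config.kernel_spec:
            small_model.params[f"bicl2.U{k}"].data[:] = 0.0
            small_model.params[f"bicl2.b{k}"].data[:] = -1.0
        out = small_model.bicl_forward(
            rng.normal(size=(15, small_model.config.embed_dim)),
            rng.normal(size=(34, small_model.config.embed_dim)),
        )
        assert np.all(out == 0)

    def test_resbicl_matches_composition(self, small_model, rng):
        cfg = small_model.config
        X = rng.normal(size=(cfg.model_length, cfg.embed_dim))
        Y = rng.normal(size=(34, cfg.embed_dim))
        Xg = small_model.position_gate(X)
        C1 = bicl_oracle(X, Y, small_model, 1)
        C2 = bicl_oracle(Xg, Y, small_model, 2)
        # fresh model: eval-mode normalization has identity statistics
        expected = np.maximum(C1 / np.sqrt(1 + 1e-5) + C2 / np.sqrt(1 + 1e-5), 0.0)
        np.testing.assert_allclose(small_model.resbicl_forward(X, Y), expected, atol=1e-5)

    def test_head_matches_loop(self, small_model, rng):
        cfg = small_model.config
        d0 = cfg.total_kernels
        for _ in range(N_INSTANCES):
            C0 = rng.normal(size=(d0, cfg.conv_width))
            assert small_model.head_forward(C0) == pytest.approx(
                head_oracle(C0, small_model), abs=1e-5
            )

    def test_head_closed_form(self, small_model):
        cfg = small_model.config
        for n in range(1, len(cfg.fc_dims) + 1):
            small_model.params[f"fc{n}.W"].data[:] = 0.0
        small_model.params["out.w"].data[:] = 0.0
        C0 = np.zeros((cfg.total_kernels, cfg.conv_width))
        assert small_model.head_forward(C0) == pytest.approx(0.5, abs=1e-7)
        small_model.params["out.b"].data[:] = 30.0
        assert small_model.head_forward(C0) == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_identity_table_returns_indicator_rows(self, small_config):
        model = Model(small_config, seed=0)
        d = small_config.embed_dim
        model.params["embedding"].data = np.eye(VOCABULARY.size, d, dtype=ad.DTYPE)
        out = model.embed(np.array([1, 3, 0]))
        np.testing.assert_array_equal(out, np.eye(VOCABULARY.size, d)[[1, 3, 0]])

    def test_all_pad_with_zero_pad_row_is_zero(self, small_model):
        small_model.params["embedding"].data[0] = 0.0
        out = small_model.embed(np.zeros(15, dtype=int))
        assert np.all(out == 0)

    def test_out_of_range_index(self, small_model):
        with pytest.raises(IndexError):
            small_model.embed(np.array([21]))

    def test_one_hot_mode(self):
        model = Model(ModelConfig(embedding_mode="one_hot", kernel_spec={9: 2}, fc_dims=[4]))
        assert model.config.embed_dim == VOCABULARY.size
        np.testing.assert_array_equal(model.params["embedding"].data, np.eye(21))
        assert not model.params["embedding"].requires_grad


# ---------------------------------------------------------------------------
# full forward: shapes, determinism, wiring
# ---------------------------------------------------------------------------

def random_pairs(rng, n, lengths=(9, 11, 15)):
    pep = np.zeros((n, 15), dtype=np.int64)
    for i in range(n):
        length = lengths[i % len(lengths)]
        pep[i, :length] = rng.integers(1, 21, length)
    pseudo = rng.integers(1, 21, (n, 34))
    # a few shared alleles so grouping paths are exercised
    pseudo[1::3] = pseudo[0]
    return pep, pseudo


class TestForward:
    def test_default_shape_chain(self):
        model = Model(ModelConfig(), seed=0)
        rng = np.random.default_rng(0)
        X = model.embed(rng.integers(1, 21, 15))
        Y = model.embed(rng.integers(1, 21, 34))
        assert X.shape == (15, 16) and Y.shape == (34, 16)
        assert model.position_gate(X).shape == (15, 16)
        kernels = model.generate_kernels(Y)
        assert {k: v.shape for k, v in kernels.items()} == {
            9: (128, 9, 16), 11: (64, 11, 16), 13: (32, 13, 16)
        }
        assert model.bicl_forward(X, Y).shape == (224, 7)
        assert model.resbicl_forward(X, Y).shape == (224, 7)

    def test_parameter_count_in_expected_envelope(self):
        assert 2e5 <= Model(ModelConfig(), seed=0).n_parameters() <= 4e5

    def test_output_in_unit_interval_and_deterministic(self, small_model, rng):
        pep, pseudo = random_pairs(rng, 12)
        y1 = small_model.forward_batch(pep, pseudo).data
        y2 = small_model.forward_batch(pep, pseudo).data
        assert np.all((y1 > 0) & (y1 < 1))
        np.testing.assert_array_equal(y1, y2)

    def test_eval_prediction_invariant_to_batch_order(self, small_model, rng):
        pep, pseudo = random_pairs(rng, 16)
        base = small_model.forward_batch(pep, pseudo).data
        perm = rng.permutation(16)
        shuffled = small_model.forward_batch(pep[perm], pseudo[perm]).data
        np.testing.assert_allclose(shuffled, base[perm], atol=1e-6)

    def test_single_matches_batched(self, small_model, rng):
        pep, pseudo = random_pairs(rng, 6)
        batched = small_model.forward_batch(pep, pseudo).data
        singles = [
            small_model.forward_batch(pep[i : i + 1], pseudo[i : i + 1]).data[0]
            for i in range(6)
        ]
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_forward_accepts_domain_objects(self, small_model):
        allele = MHCAllele("X", "A" * 34)
        y = small_model.forward("ACDEFGHIK", allele)
        assert 0 < y < 1

    def test_gradient_reaches_every_parameter(self, small_config, rng):
        model = Model(small_config, seed=2)
        pep, pseudo = random_pairs(rng, 8)
        yhat = model.forward_batch(pep, pseudo, training=True, rng=rng)
        target = ad.Tensor(rng.random(8))
        diff = yhat - target
        loss = ad.mean(ad.mul(diff, diff))
        model.zero_grad()
        loss.backward()
        for name, p in model.trainable().items():
            assert p.grad is not None and not np.allclose(p.grad, 0), name

    def test_no_residual_leaves_first_branch_untouched(self, small_config, rng):
        cfg = ModelConfig(**{**small_config.__dict__, "use_residual": False, "use_gate": False})
        model = Model(cfg, seed=2)
        pep, pseudo = random_pairs(rng, 8)
        yhat = model.forward_batch(pep, pseudo, training=True, rng=rng)
        loss = ad.mean(ad.mul(yhat, yhat))
        model.zero_grad()
        loss.backward()
        for k in cfg.kernel_spec:
            assert model.params[f"bicl1.U{k}"].grad is None
            assert model.params[f"bicl2.U{k}"].grad is not None

    def test_kernel_permutation_is_pure_rewiring(self, small_model, rng):
        """Permuting kernels within a size class (with matching BN and
        first-FC rows) must leave predictions unchanged."""
        model = small_model
        cfg = model.config
        pep, pseudo = random_pairs(rng, 5)
        base = model.forward_batch(pep, pseudo).data
        k = 9
        H = cfg.kernel_spec[k]
        perm = rng.permutation(H)
        chan = np.arange(cfg.total_kernels)
        chan[:H] = perm  # size-9 block sits first in the concatenation
        for branch in (1, 2):
            model.params[f"bicl{branch}.U{k}"].data = model.params[f"bicl{branch}.U{k}"].data[perm]
            model.params[f"bicl{branch}.b{k}"].data = model.params[f"bicl{branch}.b{k}"].data[perm]
            for suffix in ("gamma", "beta"):
                p = model.params[f"bn_bicl{branch}.{suffix}"]
                p.data = p.data[chan]
            for suffix in ("mean", "var"):
                s = model.bn_state[f"bn_bicl{branch}.{suffix}"]
                model.bn_state[f"bn_bicl{branch}.{suffix}"] = s[chan]
        model.params["fc1.W"].data = model.params["fc1.W"].data[chan]
        np.testing.assert_allclose(model.forward_batch(pep, pseudo).data, base, atol=1e-6)


class TestSerialization:
    def test_save_load_bit_stable(self, small_model, rng, tmp_path):
        pep, pseudo = random_pairs(rng, 4)
        base = small_model.forward_batch(pep, pseudo).data
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = Model.load(path)
        np.testing.assert_array_equal(loaded.forward_batch(pep, pseudo).data, base)

    def test_invalid_kernel_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_spec={8: 4})
        with pytest.raises(ValueError):
            ModelConfig(kernel_spec={7: 4})
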