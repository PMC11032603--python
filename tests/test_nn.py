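"""Finite-difference checks and behavioral tests for the autograd engine."""

import numpy as np
import pytest

from mirtarget.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    MultiheadSelfAttention,
    Tensor,
    TransformerEncoderLayer,
    concat,
    conv2d,
    embedding,
    softmax,
)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def assert_grad_matches(build_loss, tensors: dict[str, Tensor], tol: float = 1e-6):
    loss = build_loss()
    loss.backward()
    for name, t in tensors.items():
        ng = numeric_grad(lambda: float(build_loss().data), t.data)
        assert t.grad is not None, name
        np.testing.assert_allclose(t.grad, ng, rtol=tol, atol=tol, err_msg=name)
        t.grad = None


@pytest.fixture()
def gen():
    return np.random.default_rng(7)


class TestElementwiseOps:
    def test_arithmetic_chain_gradient(self, gen):
        a = Tensor(gen.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(gen.standard_normal((4,)), requires_grad=True)

        def loss():
            return (((a * b - a.abs()).relu() + (a * 0.3).sigmoid()).sum()
                    * (b.pow(2.0).sum() + 1.0))

        assert_grad_matches(loss, {"a": a, "b": b}, tol=1e-5)

    def test_log_exp_mean_gradient(self, gen):
        a = Tensor(np.abs(gen.standard_normal((2, 5))) + 0.5, requires_grad=True)

        def loss():
            return (a.log() + (-a).exp()).mean() * 3.0

        assert_grad_matches(loss, {"a": a})

    def test_broadcast_unreduction(self, gen):
        a = Tensor(gen.standard_normal((2, 3, 4)), requires_grad=True)
        b = Tensor(gen.standard_normal((1, 3, 1)), requires_grad=True)
        ((a + b) * (a - b)).sum().backward()
        assert a.grad.shape == a.shape and b.grad.shape == b.shape
        np.testing.assert_allclose(b.grad, (-2 * b.data * 8).reshape(b.shape), rtol=1e-5)


class TestStructuralOps:
    def test_matmul_batched_gradient(self, gen):
        a = Tensor(gen.standard_normal((2, 3, 4)), requires_grad=True)
        b = Tensor(gen.standard_normal((4, 5)), requires_grad=True)
        w = gen.standard_normal((2, 3, 5))

        def loss():
            return ((a @ b) * Tensor(w)).sum()

        assert_grad_matches(loss, {"a": a, "b": b})

    def test_softmax_gradient_and_rows_sum_to_one(self, gen):
        a = Tensor(gen.standard_normal((2, 3, 5)), requires_grad=True)
        y = softmax(a, axis=-1)
        np.testing.assert_allclose(y.data.sum(axis=-1), 1.0, rtol=1e-12)
        w = gen.standard_normal(y.shape)

        def loss():
            return (softmax(a, axis=-1) * Tensor(w)).sum()

        assert_grad_matches(loss, {"a": a})

    def test_getitem_concat_reshape_transpose_gradient(self, gen):
        a = Tensor(gen.standard_normal((3, 6)), requires_grad=True)
        w = gen.standard_normal((3, 6))

        def loss():
            left, right = a[:, :2], a[:, 2:]
            joined = concat([right, left], axis=1)
            return (joined.reshape(2, 9).transpose(1, 0).reshape(3, 6) * Tensor(w)).sum()

        assert_grad_matches(loss, {"a": a})

    def test_embedding_scatter_gradient(self, gen):
        table = Tensor(gen.standard_normal((5, 3)), requires_grad=True)
        idx = np.array([[0, 2, 2], [4, 0, 1]])
        w = gen.standard_normal((2, 3, 3))
        (embedding(table, idx) * Tensor(w)).sum().backward()
        # row 2 is used twice: gradient is the sum of both occurrences
        np.testing.assert_allclose(table.grad[2], w[0, 1] + w[0, 2], rtol=1e-12)
        np.testing.assert_allclose(table.grad[3], 0.0)


class TestConv2d:
    def test_gradient_matches_finite_differences(self, gen):
        x = Tensor(gen.standard_normal((2, 4, 5, 3)), requires_grad=True)
        w = Tensor(gen.standard_normal((3, 3, 3, 2)) * 0.4, requires_grad=True)
        b = Tensor(gen.standard_normal(2) * 0.1, requires_grad=True)
        proj = gen.standard_normal((2, 4, 5, 2))

        def loss():
            return (conv2d(x, w, b, 1) * Tensor(proj)).sum()

        assert_grad_matches(loss, {"x": x, "w": w, "b": b}, tol=1e-5)

    def test_matches_direct_convolution_sum(self, gen):
        # independent scalar-loop evaluation of one output position
        x = gen.standard_normal((1, 6, 7, 2))
        w = gen.standard_normal((3, 3, 2, 1))
        out = conv2d(Tensor(x), Tensor(w), None, 1).data
        i, j = 3, 4
        acc = 0.0
        for u in range(3):
            for v in range(3):
                for c in range(2):
                    acc += x[0, i + u - 1, j + v - 1, c] * w[u, v, c, 0]
        assert out[0, i, j, 0] == pytest.approx(acc, rel=1e-10)

    @pytest.mark.parametrize("m,n,ks", [(1, 1, 3), (2, 9, 5), (7, 3, 9)])
    def test_spatial_shape_preserved(self, gen, m, n, ks):
        layer = Conv2d(4, 2, ks, gen, dtype=np.float64)
        out = layer(Tensor(gen.standard_normal((1, m, n, 4))))
        assert out.shape == (1, m, n, 2)


class TestLayers:
    def test_layernorm_normalizes_and_backprops(self, gen):
        ln = LayerNorm(6, dtype=np.float64)
        x = Tensor(gen.standard_normal((2, 3, 6)), requires_grad=True)
        y = ln(x)
        np.testing.assert_allclose(y.data.mean(axis=-1), 0.0, atol=1e-7)
        np.testing.assert_allclose(y.data.std(axis=-1), 1.0, atol=1e-3)
        w = gen.standard_normal(y.shape)

        def loss():
            return (ln(x) * Tensor(w)).sum()

        assert_grad_matches(loss, {"x": x, "ln.w": ln.weight, "ln.b": ln.bias}, tol=1e-5)

    def test_batchnorm_train_vs_eval(self, gen):
        bn = BatchNorm2d(3, dtype=np.float64)
        x = Tensor(gen.standard_normal((4, 2, 2, 3)) * 2 + 1)
        y = bn(x)
        np.testing.assert_allclose(y.data.mean(axis=(0, 1, 2)), 0.0, atol=1e-10)
        bn.eval()
        y2 = bn(x)
        assert not np.allclose(y.data, y2.data)  # running stats, not batch stats
        y3 = bn(x)
        np.testing.assert_array_equal(y2.data, y3.data)  # eval is deterministic

    def test_attention_and_encoder_layer_backprop(self, gen):
        layer = TransformerEncoderLayer(8, 2, 16, 0.0, gen, dtype=np.float64)
        x = Tensor(gen.standard_normal((2, 5, 8)), requires_grad=True)
        w = gen.standard_normal((2, 5, 8))

        def loss():
            return (layer(x) * Tensor(w)).sum()

        loss_val = loss()
        loss_val.backward()
        ng = numeric_grad(lambda: float(loss().data), x.data)
        np.testing.assert_allclose(x.grad, ng, rtol=1e-5, atol=1e-5)

    def test_state_dict_roundtrip(self, gen):
        layer = TransformerEncoderLayer(8, 1, 16, 0.0, gen)
        other = TransformerEncoderLayer(8, 1, 16, 0.0, np.random.default_rng(123))
        other.load_state_dict(layer.state_dict())
        x = np.random.default_rng(0).standard_normal((1, 4, 8)).astype(np.float32)
        np.testing.assert_array_equal(layer(Tensor(x)).data, other(Tensor(x)).data)


class TestAdam:
    def test_converges_on_quadratic(self):
        target = np.array([1.5, -2.0, 0.5])
        x = Tensor(np.zeros(3), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            ((x - Tensor(target)).pow(2.0)).sum().backward()
            opt.step()
        np.testing.assert_allclose(x.data, target, atol=1e-3)
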