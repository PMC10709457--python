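import numpy as np
import pytest

from matchgraph import autodiff as ad
from matchgraph.autodiff import Tensor
from matchgraph.nn import (
    AdamOptimizer,
    BiGCNLayer,
    LSTMCell,
    Parameters,
    row_normalize,
    run_lstm,
)


class TestRowNormalize:
    def test_row_divided_by_its_sum(self):
        out = row_normalize(np.array([[1, 1, 0], [0, 0, 0], [1, 0, 0]]))
        assert np.allclose(out[0], [0.5, 0.5, 0.0])
        assert np.allclose(out[2], [1.0, 0.0, 0.0])

    def test_all_zero_matrix_unchanged(self):
        assert not row_normalize(np.zeros((4, 4))).any()

    def test_nonzero_rows_sum_to_one(self, rng):
        for _ in range(50):
            a = (rng.random((8, 8)) < 0.3).astype(int)
            out = row_normalize(a)
            for i in range(8):
                s = out[i].sum()
                assert s == 0.0 or abs(s - 1.0) < 1e-9


class TestLSTM:
    def _cell(self, rng, d_in=3, d_h=4):
        params = Parameters()
        return LSTMCell(params, "lstm", d_in, d_h, rng), params

    def test_single_token_sequence(self, rng):
        cell, _ = self._cell(rng)
        out = cell.run(Tensor(rng.normal(size=(1, 3))))
        assert out.data.shape == (1, 4)
        assert np.isfinite(out.data).all()

    def test_hidden_states_bounded_by_gating(self, rng):
        # h = sigmoid(.) * tanh(.), so every coordinate lies in (-1, 1)
        cell, _ = self._cell(rng)
        out = cell.run(Tensor(rng.normal(size=(9, 3)) * 5))
        assert (np.abs(out.data) < 1.0).all()

    def test_bidirectional_concatenates_both_directions(self, rng):
        fwd, params = self._cell(rng)
        bwd = LSTMCell(params, "lstm_b", 3, 4, rng)
        xs = Tensor(rng.normal(size=(5, 3)))
        h = run_lstm(fwd, bwd, xs)
        assert h.data.shape == (5, 8)
        assert np.allclose(h.data[:, :4], fwd.run(xs).data)
        assert np.allclose(h.data[:, 4:], bwd.run(xs, reverse=True).data)

    def test_reverse_direction_conditions_on_future(self, rng):
        cell, _ = self._cell(rng)
        xs = rng.normal(size=(6, 3))
        base = cell.run(Tensor(xs), reverse=True).data
        xs2 = xs.copy()
        xs2[5] += 1.0  # perturb the last token
        pert = cell.run(Tensor(xs2), reverse=True).data
        assert not np.allclose(base[0], pert[0])  # reaches position 0 backward
        fwd_base = cell.run(Tensor(xs)).data
        fwd_pert = cell.run(Tensor(xs2)).data
        assert np.allclose(fwd_base[0], fwd_pert[0])  # but not forward

    def test_eval_forward_is_deterministic(self, rng):
        cell, _ = self._cell(rng)
        xs = rng.normal(size=(4, 3))
        a = cell.run(Tensor(xs)).data
        b = cell.run(Tensor(xs)).data
        assert np.array_equal(a, b)


class TestBiGCNLayer:
    def _layer(self, rng, d_h=6, **kw):
        params = Parameters()
        return BiGCNLayer(params, "gcn", d_h, rng, **kw), params

    def test_zero_adjacency_reduces_to_layer_norm(self, rng):
        layer, _ = self._layer(rng)
        h = Tensor(rng.normal(size=(5, 6)))
        zero = Tensor(np.zeros((5, 5)))
        out = layer.forward(h, zero, zero)
        assert np.array_equal(out.data, ad.layer_norm(h).data)

    def test_scalar_hand_trace(self, rng):
        # L=1, d_h=1, self-loop, all weights 1, h=[[2]]:
        # Q_out = Q_in = relu(1*2*1) = 2; fused = relu([2,2]@[1,1]^T) = 4;
        # residual input = 2 + 4 = 6
        layer, params = self._layer(rng, d_h=1)
        for t in params.values():
            t.data = np.ones_like(t.data)
        h = Tensor(np.array([[2.0]]))
        loop = Tensor(np.array([[1.0]]))
        q_out, q_in = layer.branches(h, loop, loop)
        assert abs(q_out.data.item() - 2.0) < 1e-6
        assert abs(q_in.data.item() - 2.0) < 1e-6
        pre = layer.prenorm(h, loop, loop)
        assert abs(pre.data.item() - 6.0) < 1e-6

    def test_single_gcn_uses_forward_branch_only(self, rng):
        layer, params = self._layer(rng, single_gcn=True)
        assert "gcn.w_in" not in params
        assert params["gcn.w_o"].data.shape == (6, 6)
        h = Tensor(rng.normal(size=(3, 6)))
        a = Tensor(row_normalize((rng.random((3, 3)) < 0.4).astype(int)))
        out = layer.forward(h, a, a)
        assert out.data.shape == (3, 6)

    def test_no_residual_drops_identity_path(self, rng):
        layer, _ = self._layer(rng)
        h = Tensor(rng.normal(size=(4, 6)))
        zero = Tensor(np.zeros((4, 4)))
        out = layer.forward(h, zero, zero, no_residual=True)
        # with a zero graph and no residual the pre-norm input is all zero
        assert np.allclose(out.data, 0.0)

    def test_shape_mismatch_names_both_shapes(self, rng):
        layer, _ = self._layer(rng)
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(4, 6\)"):
            layer.forward(Tensor(rng.normal(size=(4, 6))),
                          Tensor(np.zeros((3, 3))), Tensor(np.zeros((3, 3))))

    def test_gradients_flow_through_layer(self, rng):
        layer, params = self._layer(rng)
        h = Tensor(rng.normal(size=(4, 6)))
        a = Tensor(row_normalize(np.eye(4)))
        out = layer.forward(h, a, a)
        ad.sum_squares(out).backward()
        assert params["gcn.w_out"].grad is not None
        assert np.isfinite(params["gcn.w_out"].grad).all()


class TestAdam:
    def test_minimizes_quadratic(self):
        params = Parameters()
        x = params.new("x", np.array([[5.0, -3.0]]))
        opt = AdamOptimizer(params, lr=0.1)
        for _ in range(300):
            params.zero_grad()
            ad.sum_squares(x).backward()
            opt.step()
        assert np.abs(x.data).max() < 1e-3

    def test_skips_parameters_without_grad(self):
        params = Parameters()
        x = params.new("x", np.ones((2, 2)))
        opt = AdamOptimizer(params)
        opt.step()
        assert np.array_equal(x.data, np.ones((2, 2)))
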