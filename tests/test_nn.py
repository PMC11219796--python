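"""Autograd primitives and the UNet++ networks.

Gradients of every hand-written primitive are checked against central
finite differences; the telescoped (interior-region) forward is checked
bit-identical to the full-box forward in eval mode.
"""

import numpy as np
import pytest

from cryoflex import nn
from cryoflex.nn import (NetworkConfig, Tensor, build_occ_network,
                         build_rmsf_network, compose_occ2rmsf,
                         load_checkpoint, no_grad, save_checkpoint)


def _num_grad(f, x, eps=1e-3, stride=1):
    """Central-difference gradient of scalar f at selected entries."""
    num = np.zeros(x.size)
    flat = x.ravel()
    for i in range(0, x.size, stride):
        xp = flat.copy(); xp[i] += eps
        xm = flat.copy(); xm[i] -= eps
        num[i] = (f(xp.reshape(x.shape)) - f(xm.reshape(x.shape))) / (2 * eps)
    return num.reshape(x.shape)


def _mse_all(t, shape):
    return nn.masked_mse(t, np.zeros(shape, np.float32),
                         np.ones(shape, bool))


class TestGradients:
    @pytest.mark.parametrize("pad", [0, 1])
    def test_conv3d_input_and_weight(self, rng, pad):
        x = rng.normal(0, 1, (2, 2, 5, 5, 5)).astype(np.float32)
        w0 = rng.normal(0, 0.5, (2 * 27, 3)).astype(np.float32)
        b0 = rng.normal(0, 0.5, 3).astype(np.float32)
        oshape = (2, 3) + (3 + 2 * pad,) * 3

        def loss_x(xa):
            return _mse_all(nn.conv3d(Tensor(xa), Tensor(w0), Tensor(b0),
                                      3, pad), oshape).item()

        xt = Tensor(x, requires_grad=True)
        out = _mse_all(nn.conv3d(xt, Tensor(w0), Tensor(b0), 3, pad), oshape)
        out.backward()
        num = _num_grad(loss_x, x, stride=7)
        idx = np.arange(0, x.size, 7)
        assert np.abs(xt.grad.ravel()[idx] - num.ravel()[idx]).max() < 2e-3

        def loss_w(wa):
            return _mse_all(nn.conv3d(Tensor(x), Tensor(wa), Tensor(b0),
                                      3, pad), oshape).item()

        wt = Tensor(w0, requires_grad=True)
        out = _mse_all(nn.conv3d(Tensor(x), wt, Tensor(b0), 3, pad), oshape)
        out.backward()
        num = _num_grad(loss_w, w0, stride=11)
        idx = np.arange(0, w0.size, 11)
        assert np.abs(wt.grad.ravel()[idx] - num.ravel()[idx]).max() < 2e-3

    @pytest.mark.parametrize("op,out_shape", [
        (nn.max_pool3d, (1, 2, 2, 2, 2)),
        (nn.upsample_trilinear, (1, 2, 8, 8, 8)),
        (lambda t: nn.upsample_region(t, 4, 0, 1, 6), (1, 2, 6, 6, 6)),
        (lambda t: nn.crop_region(t, 1, 3), (1, 2, 2, 2, 2)),
    ])
    def test_spatial_ops(self, rng, op, out_shape):
        x = rng.normal(0, 1, (1, 2, 4, 4, 4)).astype(np.float32)
        xt = Tensor(x, requires_grad=True)
        _mse_all(op(xt), out_shape).backward()
        num = _num_grad(lambda xa: _mse_all(op(Tensor(xa)), out_shape).item(), x)
        assert np.abs(xt.grad - num).max() < 2e-3

    def test_batch_norm_train_mode(self, rng):
        x = rng.normal(0, 1, (2, 3, 4, 4, 4)).astype(np.float32)
        gamma = Tensor(rng.normal(1, 0.1, 3).astype(np.float32))
        beta = Tensor(rng.normal(0, 0.1, 3).astype(np.float32))

        def f(xa):
            run = {"mean": np.zeros(3, np.float32), "var": np.ones(3, np.float32)}
            return _mse_all(nn.batch_norm(Tensor(xa), gamma, beta, run, True),
                            x.shape).item()

        xt = Tensor(x, requires_grad=True)
        run = {"mean": np.zeros(3, np.float32), "var": np.ones(3, np.float32)}
        _mse_all(nn.batch_norm(xt, gamma, beta, run, True), x.shape).backward()
        num = _num_grad(f, x, eps=1e-2, stride=5)
        idx = np.arange(0, x.size, 5)
        assert np.abs(xt.grad.ravel()[idx] - num.ravel()[idx]).max() < 2e-3

    def test_softmax_weighted_cross_entropy(self, rng):
        x = rng.normal(0, 1, (1, 2, 4, 4, 4)).astype(np.float32)
        truth = (rng.random((1, 4, 4, 4)) > 0.7).astype(np.float32)

        def f(xa):
            return nn.weighted_cross_entropy(
                nn.softmax_channels(Tensor(xa)), truth).item()

        xt = Tensor(x, requires_grad=True)
        nn.weighted_cross_entropy(nn.softmax_channels(xt), truth).backward()
        num = _num_grad(f, x, eps=1e-2)
        assert np.abs(xt.grad - num).max() < 2e-3


class TestCenterCrop:
    def test_index_arithmetic(self):
        x = np.zeros((1, 1, 40, 40, 40), np.float32)
        x[0, 0, 20, 20, 20] = 7.0
        out = nn.center_crop(Tensor(x), 10).data
        assert out[0, 0, 5, 5, 5] == 7.0

    def test_constant_and_round_trip(self, rng):
        const = nn.center_crop(Tensor(np.full((1, 1, 40, 40, 40), 2.5,
                                              np.float32)), 10).data
        assert np.all(const == 2.5)
        sub = rng.normal(size=(1, 1, 10, 10, 10)).astype(np.float32)
        embedded = np.zeros((1, 1, 40, 40, 40), np.float32)
        embedded[..., 15:25, 15:25, 15:25] = sub
        assert np.array_equal(nn.center_crop(Tensor(embedded), 10).data, sub)


def _expected_param_count(in_channels, base):
    """Independent layer-by-layer parameter count of the UNet++(L3) net.

    One 3x3x3 conv (+bias) and one batchnorm (gamma+beta) per node; node
    input channels follow the dense-skip wiring; head = two 1x1x1 convs.
    """
    ch = [base, 2 * base, 4 * base, 8 * base]
    nodes = [  # (cin, cout)
        (in_channels, ch[0]), (ch[0], ch[1]), (ch[1], ch[2]), (ch[2], ch[3]),
        (ch[0] + ch[1], ch[0]), (ch[1] + ch[2], ch[1]), (ch[2] + ch[3], ch[2]),
        (2 * ch[0] + ch[1], ch[0]), (2 * ch[1] + ch[2], ch[1]),
        (3 * ch[0] + ch[1], ch[0]),
    ]
    total = sum(cin * 27 * cout + cout + 2 * cout for cin, cout in nodes)
    total += ch[0] * ch[0] + ch[0]          # head conv 1
    total += ch[0] * 1 + 1                  # head conv 2
    return total


class TestNetworks:
    def test_parameter_count_matches_hand_count(self):
        net = build_rmsf_network(NetworkConfig(variant="dual",
                                               base_channels=16, seed=0))
        assert sum(p.data.size for p in net.parameters()) == \
            _expected_param_count(2, 16)

    def test_zero_input_finite_and_deterministic(self):
        net = build_rmsf_network(NetworkConfig(variant="cryo",
                                               base_channels=4, seed=1))
        x = np.zeros((1, 1, 40, 40, 40), np.float32)
        out1 = net.predict(x)
        out2 = net.predict(x)
        assert out1.shape == (1, 10, 10, 10)
        assert np.all(np.isfinite(out1))
        assert np.array_equal(out1, out2)

    def test_variant_channel_contract(self):
        for variant, c in [("cryo", 1), ("pdb", 1), ("pdb01", 2), ("dual", 2)]:
            net = build_rmsf_network(NetworkConfig(variant=variant, seed=0,
                                                   base_channels=4))
            assert net.config.in_channels == c
        with pytest.raises(ValueError):
            build_rmsf_network(NetworkConfig(variant="dual", in_channels=1,
                                             base_channels=4))
        net = build_rmsf_network(NetworkConfig(variant="dual", base_channels=4))
        with pytest.raises(ValueError):
            net.predict(np.zeros((1, 1, 40, 40, 40), np.float32))
        with pytest.raises(ValueError):
            net.predict(np.zeros((1, 2, 20, 20, 20), np.float32))

    def test_regional_forward_equals_full_crop(self, rng):
        """The telescoped forward must equal crop(full forward) in eval mode."""
        net = build_rmsf_network(NetworkConfig(variant="dual",
                                               base_channels=4, seed=3))
        net.eval()
        x = rng.normal(0, 1, (2, 2, 40, 40, 40)).astype(np.float32)
        with no_grad():
            full = nn.center_crop(net.backbone(Tensor(x)), 10).data
            regional = net.backbone.forward_center(Tensor(x)).data
        # equal up to float32 summation order of the convolution taps
        assert np.allclose(full, regional, atol=2e-5, rtol=1e-5)

    def test_occ_classifier_contract(self, rng):
        occ = build_occ_network(NetworkConfig(variant="occ", base_channels=2,
                                              seed=0))
        x = rng.normal(0, 1, (1, 1, 40, 40, 40)).astype(np.float32)
        probs = occ.predict_proba(x)
        assert probs.shape == (1, 2, 40, 40, 40)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        zero = occ.predict_proba(np.zeros_like(x))
        assert np.all(np.isfinite(zero))
        with pytest.raises(ValueError):
            build_occ_network(NetworkConfig(variant="occ", in_channels=2,
                                            base_channels=2))

    def test_occ2rmsf_composition_and_freezing(self, rng):
        occ = build_occ_network(NetworkConfig(variant="occ", base_channels=2,
                                              seed=0))
        with pytest.raises(RuntimeError):
            compose_occ2rmsf(occ, NetworkConfig(variant="occ2rmsf",
                                                base_channels=2))
        occ.trained = True
        two = compose_occ2rmsf(occ, NetworkConfig(variant="occ2rmsf",
                                                  base_channels=2, seed=1))
        assert two.rmsf.config.in_channels == 2  # stage 2 sees P_o, P_u
        before = [p.data.copy() for p in occ.backbone.parameters()] \
            + [occ.head.weight.data.copy()]
        x = rng.normal(0, 1, (1, 1, 40, 40, 40)).astype(np.float32)
        out = two(x)
        assert out.data.shape == (1, 1, 10, 10, 10)
        loss = nn.masked_mse(out, np.zeros((1, 1, 10, 10, 10), np.float32),
                             np.ones((1, 1, 10, 10, 10), bool))
        loss.backward()
        from cryoflex.nn import Adam
        opt = Adam(two.parameters(), lr=0.01)
        opt.step()
        after = [p.data for p in occ.backbone.parameters()] \
            + [occ.head.weight.data]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)  # stage-1 parameters bit-identical

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_rmsf_network(NetworkConfig(variant="pdb01",
                                               base_channels=2, seed=5))
        x = rng.normal(0, 1, (1, 2, 40, 40, 40)).astype(np.float32)
        out = net.predict(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path, "rmsf")
        assert back.config.variant == "pdb01"
        assert np.array_equal(back.predict(x), out)
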