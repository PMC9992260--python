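"""SE gating, residual blocks, U-Nets and sensitivity estimation."""

import numpy as np
import pytest

from dircn import nn
from dircn.kspace import fft2c, ifft2c, normalize_sensitivities
from dircn.masks import make_equidistant_mask
from dircn.nn import Tensor
from dircn.subnetworks import (
    ResXBlock,
    ResXUNet,
    SensitivityModel,
    SqueezeExcite,
    SubnetConfig,
    UNet,
    estimate_sensitivities,
)

from conftest import random_complex

TINY = SubnetConfig(base_channels=8, depth=3, cardinality=4, se_reduction=4)


def test_se_block_matches_hand_computation():
    se = SqueezeExcite(2, reduction=1)
    # tiny hand-set weights: fc1 = identity-ish, fc2 known
    se.fc1.weight = Tensor(np.array([[0.5, 0.0], [0.0, -0.25]]),
                           requires_grad=True, dtype=np.float64)
    se.fc1.bias = Tensor(np.zeros(2), requires_grad=True, dtype=np.float64)
    se.fc2.weight = Tensor(np.array([[1.0, 0.0], [0.0, 2.0]]),
                           requires_grad=True, dtype=np.float64)
    se.fc2.bias = Tensor(np.array([0.1, -0.1]), requires_grad=True, dtype=np.float64)
    x = Tensor(np.array([[[[2.0]], [[-4.0]]]]), dtype=np.float64)  # [1, 2, 1, 1]
    out = se(x).data
    # pencil-and-paper: squeeze = (2, -4); hidden = silu([1.0, 1.0])
    h = np.array([0.5 * 2.0, -0.25 * -4.0])
    h = h / (1 + np.exp(-h))  # SiLU
    pre = np.array([h[0] * 1.0 + 0.1, h[1] * 2.0 - 0.1])
    s = 1 / (1 + np.exp(-pre))
    expected = np.array([2.0 * s[0], -4.0 * s[1]])
    assert np.abs(out.ravel() - expected).max() < 1e-12


def test_se_never_amplifies_channels(rng):
    nn.seed_init(0)
    se = SqueezeExcite(8, reduction=4)
    x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
    y = se(x).data
    assert np.all(np.abs(y) <= np.abs(x.data) + 1e-7)


def test_se_sigmoid_saturation_recovers_input(rng):
    se = SqueezeExcite(4, reduction=2)
    # force pre-sigmoid output to a large constant → scale ≈ 1
    se.fc2.weight = Tensor(np.zeros_like(se.fc2.weight.data), requires_grad=True)
    se.fc2.bias = Tensor(np.full(4, 50.0, np.float32), requires_grad=True)
    x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
    assert np.abs(se(x).data - x.data).max() < 1e-6


def test_residual_block_zeroed_branch_is_identity(rng):
    nn.seed_init(0)
    block = ResXBlock(8, cardinality=4, se_reduction=4)
    block.conv3.weight = Tensor(np.zeros_like(block.conv3.weight.data),
                                requires_grad=True)
    block.conv3.bias = Tensor(np.zeros_like(block.conv3.bias.data),
                              requires_grad=True)
    x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32),
               requires_grad=True)
    y = block(x)
    assert np.array_equal(y.data, x.data)
    # gradient of a scalar loss w.r.t. x then has an exact identity component
    y.sum().backward()
    assert np.allclose(x.grad, np.ones_like(x.data))


def test_residual_block_preserves_shape(rng):
    nn.seed_init(1)
    block = ResXBlock(8, cardinality=4, se_reduction=4)
    x = Tensor(rng.standard_normal((3, 8, 7, 9)).astype(np.float32))
    assert block(x).shape == x.shape


@pytest.mark.parametrize("cls", [UNet, ResXUNet])
def test_unet_shape_and_packets(cls, rng):
    nn.seed_init(0)
    net = cls(2, 2, TINY)
    x = Tensor(rng.standard_normal((1, 2, 32, 32)).astype(np.float32))
    y, packets = net(x)
    assert y.shape == (1, 2, 32, 32)
    assert len(packets) == TINY.depth
    assert [p.shape[-1] for p in packets] == [32, 16, 8]
    assert [p.shape[1] for p in packets] == TINY.channels


def test_forward_is_deterministic(rng):
    nn.seed_init(3)
    net = ResXUNet(2, 2, TINY)
    x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
    y1, _ = net(x)
    y2, _ = net(x)
    assert np.array_equal(y1.data, y2.data)


def test_rectangular_input_padded_and_cropped(rng):
    nn.seed_init(0)
    net = UNet(2, 2, TINY)
    x = Tensor(rng.standard_normal((1, 2, 30, 22)).astype(np.float32))
    y, _ = net(x)
    assert y.shape == (1, 2, 30, 22)


def test_interconnect_packets_feed_next_network(rng):
    nn.seed_init(0)
    first = ResXUNet(2, 2, TINY)
    second = ResXUNet(2, 2, TINY, accept_interconnect=True)
    x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
    y1, packets = first(x)
    y2, _ = second(y1, packets)
    assert y2.shape == y1.shape
    with pytest.raises(ValueError):
        second(y1, None)
    with pytest.raises(ValueError):
        second(y1, packets[:2])


def test_unet_parameter_count_matches_closed_form():
    nn.seed_init(0)
    cfg = SubnetConfig(base_channels=4, depth=2, cardinality=1, se_reduction=2)
    net = UNet(2, 2, cfg)
    ch = [4, 8]

    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    def conv_in_act(cin, cout):  # conv3x3 + instance norm affine
        return conv(cin, cout, 3) + 2 * cout

    def double_block(c):
        return 2 * conv_in_act(c, c)

    expected = (
        conv_in_act(2, ch[0]) + double_block(ch[0])      # encoder level 0
        + conv_in_act(ch[0], ch[1]) + double_block(ch[1])  # encoder level 1
        + conv_in_act(ch[1], ch[0])                      # decoder up
        + conv_in_act(2 * ch[0], ch[0])                  # decoder fuse
        + double_block(ch[0])                            # decoder block
        + conv(ch[0], 2, 1)                              # head
    )
    assert net.num_parameters() == expected


def test_batch_consistency_no_cross_sample_leakage(rng):
    # coils ride the batch axis during sensitivity estimation, so stacked
    # processing must equal separate processing
    nn.seed_init(0)
    net = UNet(2, 2, TINY)
    a = rng.standard_normal((1, 2, 16, 16)).astype(np.float32)
    b = rng.standard_normal((1, 2, 16, 16)).astype(np.float32)
    both, _ = net(Tensor(np.concatenate([a, b], axis=0)))
    ya, _ = net(Tensor(a))
    yb, _ = net(Tensor(b))
    assert np.abs(both.data[0] - ya.data[0]).max() < 1e-5
    assert np.abs(both.data[1] - yb.data[0]).max() < 1e-5


def test_gradient_coverage_every_parameter(rng):
    """Every learnable parameter receives a nonzero gradient."""
    nn.seed_init(5)
    net = ResXUNet(2, 2, TINY)
    x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
    y, packets = net(x)
    loss = (y * y).sum() + sum((p * p).sum() * 0.1 for p in packets)
    loss.backward()
    for name, p in net.named_parameters():
        assert p.grad is not None, f"{name} got no gradient"
        assert np.abs(p.grad).max() > 0, f"{name} gradient identically zero"


def test_sensitivity_estimation_identity_oracle(rng):
    """Without CNN refinement the maps equal normalised low-res coil images."""
    ku = random_complex(rng, (3, 32, 32))
    mask = make_equidistant_mask(32, 4, 0.125)
    sens = estimate_sensitivities(ku, mask, model=None)
    low_res = ifft2c(ku * mask.center_only())
    expected = normalize_sensitivities(low_res)
    assert np.abs(sens - expected).max() < 1e-5


def test_sensitivity_maps_have_unit_energy_any_coil_count(rng):
    nn.seed_init(0)
    model = SensitivityModel("unet", TINY.scaled(0.5))
    mask = make_equidistant_mask(32, 4, 0.125)
    for c in (1, 2, 5):
        ku = fft2c(random_complex(rng, (c, 32, 32)))
        pair = model(ku, mask).data
        energy = (pair ** 2).sum(axis=(0, 1))
        assert np.abs(energy - 1.0).max() < 1e-4


def test_single_coil_sensitivity_is_unit_magnitude(rng):
    ku = fft2c(random_complex(rng, (1, 32, 32)))
    mask = make_equidistant_mask(32, 4, 0.125)
    sens = estimate_sensitivities(ku, mask)
    assert np.abs(np.abs(sens[0]) - 1.0).max() < 1e-4
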