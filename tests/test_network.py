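import numpy as np
import pytest

from aswnet import _autodiff as ad
from aswnet._autodiff import Tensor
from aswnet.errors import ShapeError, UnknownLayer
from aswnet.network import (AttentionGate, NetworkConfig, attention_gate,
                            build_asw_net, build_model, build_sw_net,
                            build_u_net, load_checkpoint, save_checkpoint)

SMALL = NetworkConfig(base_filters=2, init_seed=0)


@pytest.fixture(scope="module")
def batch():
    return np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)


@pytest.mark.parametrize("builder", [build_asw_net, build_sw_net, build_u_net])
def test_output_is_valid_probability_map(builder, batch):
    model = builder(SMALL)
    probs = model.forward(batch[:, 0])
    assert probs.shape == (2, 3, 32, 32)
    assert probs.min() >= 0
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


@pytest.mark.parametrize("builder", [build_asw_net, build_sw_net, build_u_net])
def test_forward_deterministic_at_fixed_seed(builder, batch):
    a = builder(SMALL).forward(batch[:, 0])
    b = builder(SMALL).forward(batch[:, 0])
    np.testing.assert_array_equal(a, b)


def test_attention_increases_parameter_count():
    asw = build_asw_net(NetworkConfig(base_filters=4))
    sw = build_sw_net(NetworkConfig(base_filters=4))
    assert asw.parameter_count > sw.parameter_count
    # the difference is exactly the three gates' parameters
    gates = sum(t.data.size
                for name in ("ag1", "ag2", "ag3")
                for t in asw.modules[name].parameters().values())
    assert asw.parameter_count - sw.parameter_count == gates


def test_sw_has_no_gates_unet_no_attention():
    sw = build_sw_net(NetworkConfig(base_filters=2))
    assert sw.gate_names == []
    with pytest.raises(UnknownLayer):
        sw.attention_maps()
    assert "ag1" not in build_u_net(SMALL).modules


def test_indivisible_input_rejected():
    model = build_asw_net(SMALL)
    with pytest.raises(ShapeError):
        model.forward(np.zeros((1, 30, 30), np.float32))


class TestAttentionGate:
    def test_coefficients_in_open_unit_interval(self, batch):
        model = build_asw_net(SMALL)
        model.forward_logits(batch, capture=True)
        maps = model.attention_maps()
        assert set(maps) == {"ag1", "ag2", "ag3"}
        for coeff in maps.values():
            assert coeff.min() > 0.0 and coeff.max() < 1.0

    def test_zero_projection_gives_half_everywhere(self):
        rng = np.random.default_rng(0)
        gate = AttentionGate(c_skip=2, c_gate=3, rng=rng)
        gate.psi.w.data[...] = 0.0
        gate.psi.b.data[...] = 0.0
        skip = Tensor(rng.random((1, 2, 8, 8)).astype(np.float32))
        g = Tensor(rng.random((1, 3, 4, 4)).astype(np.float32))
        _, coeff = gate(skip, g)
        np.testing.assert_allclose(coeff.data, 0.5, atol=1e-7)

    def test_gated_output_is_elementwise_product(self):
        rng = np.random.default_rng(1)
        gate = AttentionGate(c_skip=2, c_gate=2, rng=rng)
        skip = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]],
                                 [[5.0, 6.0], [7.0, 8.0]]]], np.float32))
        g = Tensor(rng.random((1, 2, 2, 2)).astype(np.float32))
        gated, coeff = gate(skip, g)
        np.testing.assert_allclose(gated.data, skip.data * coeff.data, atol=1e-7)

    def test_functional_form_rejects_oversized_gate(self):
        with pytest.raises(ShapeError):
            attention_gate(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 8, 8)))


def test_wrap_padding_makes_network_shift_equivariant(batch):
    """With periodic padding the whole graph commutes with translations
    by multiples of 8 -- evidence that no operation leaks position."""
    cfg = NetworkConfig(base_filters=2, init_seed=3, padding_mode="wrap",
                        use_batchnorm=False)
    model = build_asw_net(cfg)
    x = batch[:1]
    shifted = np.roll(x, shift=(8, 16), axis=(2, 3))
    out = model.forward_logits(x).data
    out_shifted = model.forward_logits(shifted).data
    np.testing.assert_allclose(np.roll(out, shift=(8, 16), axis=(2, 3)),
                               out_shifted, atol=1e-4)


def test_overfit_single_image_drops_loss_tenfold():
    """A tiny network must drive the loss below 0.1x initial in 200 steps."""
    from aswnet.io import ThreeClassLabel
    from aswnet.preprocess import (compute_class_weights, instance_to_three_class,
                                   normalize_grayscale)
    from aswnet.synthetic import SynthConfig, generate_nuclei_image
    from aswnet.training import RMSProp

    s = generate_nuclei_image(SynthConfig(image_height=64, image_width=64,
                                          n_nuclei=3, radius_range=(8, 12),
                                          rng_seed=1))
    img = normalize_grayscale(s.image).pixels.astype(np.float32)[None, None]
    tgt = instance_to_three_class(s.truth, 2).classes.astype(np.int64)[None]
    w = compute_class_weights(
        [ThreeClassLabel(tgt[0].astype(np.int8))]).as_array()
    model = build_asw_net(NetworkConfig(base_filters=4, init_seed=0))
    opt = RMSProp(model.parameters(), lr=1e-2)
    first = last = None
    for _ in range(200):
        model.zero_grad()
        loss = ad.weighted_softmax_cross_entropy(
            model.forward_logits(img, training=True), tgt, w)
        last = float(loss.data)
        first = first if first is not None else last
        loss.backward()
        opt.step()
    assert last < 0.1 * first


def test_checkpoint_round_trip(tmp_path, batch):
    model = build_asw_net(SMALL)
    before = model.forward(batch[:, 0])
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    sidecar = path.with_suffix(".npz.json")
    assert sidecar.exists()
    restored = load_checkpoint(path)
    assert restored.variant == "asw"
    assert restored.parameter_count == model.parameter_count
    np.testing.assert_array_equal(restored.forward(batch[:, 0]), before)


def test_build_model_dispatch():
    assert build_model("unet", SMALL).variant == "unet"
    with pytest.raises(ValueError):
        build_model("resnet")
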