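"""Frequency-domain cross-modal fusion attention: spectral identities,
attention-weight contracts, algebraic reductions and the dual-stream
detector around it."""
import numpy as np
import pytest

from teadet.autograd import Tensor, no_grad
from teadet.blocks import count_parameters
from teadet.ffa import (FFABlock, MultimodalDetector, SpectralFeaturePair,
                        build_multimodal, spectral_transform)


def _pair(rng, c=6, h=12, w=10, n=2):
    a = Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))
    b = Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))
    return a, b


def _spectral(rng, **kw):
    a, b = _pair(rng, **kw)
    rr, ri = spectral_transform(a)
    dr, di = spectral_transform(b)
    return a, b, SpectralFeaturePair(rr, ri, dr, di, stage="raw")


# ------------------------------------------------------------- transform
def test_constant_map_is_dc_only():
    x = np.full((1, 1, 6, 8), 2.5, dtype=np.float32)
    re, im = spectral_transform(Tensor(x))
    assert re.data[0, 0, 0, 0] == pytest.approx(2.5 * 48, rel=1e-6)
    rest = re.data.copy()
    rest[0, 0, 0, 0] = 0
    assert np.abs(rest).max() < 1e-3
    assert np.abs(im.data).max() < 1e-3


@pytest.mark.parametrize("hw", [(8, 8), (16, 16), (64, 64), (12, 20)])
def test_spectral_round_trip_below_1e5(rng, hw):
    x = Tensor(rng.normal(size=(1, 8) + hw).astype(np.float32))
    back = spectral_transform(spectral_transform(x), "inverse")
    assert np.abs(back.data - x.data).max() < 1e-5


def test_parseval_energy_identity(rng):
    x = Tensor(rng.normal(size=(1, 3, 10, 14)).astype(np.float32))
    re, im = spectral_transform(x)
    lhs = float((x.data ** 2).sum())
    rhs = float((re.data ** 2 + im.data ** 2).sum()) / (10 * 14)
    assert rhs == pytest.approx(lhs, rel=1e-4)


def test_non_finite_input_rejected():
    bad = np.full((1, 2, 4, 4), np.nan, dtype=np.float32)
    with pytest.raises(ValueError):
        spectral_transform(Tensor(bad))


# --------------------------------------------------------------- refines
def test_channel_refine_identity_limit_and_range(rng):
    _, _, pair = _spectral(rng)
    blk = FFABlock(6)
    out, _ = blk.channel_refine(pair, override=1.0)
    np.testing.assert_array_equal(out.rgb_re.data, pair.rgb_re.data)
    np.testing.assert_array_equal(out.dir_im.data, pair.dir_im.data)
    assert out.stage == "channel_refined"
    out2, (wr, wd) = blk.channel_refine(pair)
    for w in (wr, wd):
        assert ((w.data > 0) & (w.data < 1)).all()


def test_channel_refine_zeroed_mlp_halves_spectrum(rng):
    _, _, pair = _spectral(rng)
    blk = FFABlock(6)
    blk.mlp1_fc2.weight.data[:] = 0
    blk.mlp1_fc2.bias.data[:] = 0
    out, (wr, wd) = blk.channel_refine(pair)
    assert np.allclose(wr.data, 0.5) and np.allclose(wd.data, 0.5)
    np.testing.assert_allclose(out.rgb_re.data, 0.5 * pair.rgb_re.data, rtol=1e-6)
    np.testing.assert_allclose(out.dir_re.data, 0.5 * pair.dir_re.data, rtol=1e-6)


def test_frequency_refine_contract_and_closed_form(rng):
    _, _, pair = _spectral(rng)
    blk = FFABlock(6)
    refined, _ = blk.channel_refine(pair, override=1.0)
    out, (wr, wd) = blk.frequency_refine(refined)
    assert wr.shape == (2, 1, 12, 10) and wd.shape == (2, 1, 12, 10)
    assert ((wr.data > 0) & (wr.data < 1)).all()
    # zeroed second conv -> uniform 0.5 maps, half the spectrum
    blk.mlp2_conv2.weight.data[:] = 0
    blk.mlp2_conv2.bias.data[:] = 0
    out2, (wr2, _) = blk.frequency_refine(refined)
    assert np.allclose(wr2.data, 0.5)
    np.testing.assert_allclose(out2.rgb_im.data, 0.5 * refined.rgb_im.data,
                               rtol=1e-6)
    out3, _ = blk.frequency_refine(refined, override=1.0)
    np.testing.assert_array_equal(out3.rgb_re.data, refined.rgb_re.data)


def test_stage_tags_enforced(rng):
    _, _, pair = _spectral(rng)
    blk = FFABlock(6)
    with pytest.raises(ValueError):
        blk.frequency_refine(pair)  # raw pair: channel refine must come first
    refined, _ = blk.channel_refine(pair, override=1.0)
    with pytest.raises(ValueError):
        blk.channel_refine(refined)


def test_phase_invariant_through_attention(rng):
    """Real positive weights rescale complex spectra: phase untouched."""
    _, _, pair = _spectral(rng)
    blk = FFABlock(6)
    out, _ = blk.channel_refine(pair)
    out, _ = blk.frequency_refine(out)
    ph_in = np.angle(pair.rgb_re.data + 1j * pair.rgb_im.data)
    ph_out = np.angle(out.rgb_re.data + 1j * out.rgb_im.data)
    mag = np.hypot(pair.rgb_re.data, pair.rgb_im.data)
    m = mag > 1e-3
    d = np.abs(np.angle(np.exp(1j * (ph_in - ph_out))))
    assert d[m].max() < 1e-4


# --------------------------------------------------------------- forward
def test_ffa_forward_shape_and_dtype_preserving(rng):
    a, b = _pair(rng, c=8, h=16, w=16)
    blk = FFABlock(8)
    o1, o2 = blk(a, b)
    assert o1.shape == a.shape and o2.shape == b.shape
    assert o1.data.dtype == np.float32
    assert np.isfinite(o1.data).all() and np.isfinite(o2.data).all()


def test_zero_input_biasfree_gives_zero_output():
    blk = FFABlock(4, enhance_norm_act=False)
    for enh in (blk.enh_rgb, blk.enh_dir):
        for m in enh:
            m.conv.bias.data[:] = 0
    z = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
    o1, o2 = blk(z, z)
    assert np.abs(o1.data).max() == 0 and np.abs(o2.data).max() == 0


def test_unit_weights_identity_convs_reduce_to_cross_addition(rng):
    c = 5
    blk = FFABlock(c, enhance_norm_act=False)
    eye = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
    for enh in (blk.enh_rgb, blk.enh_dir):
        for m in enh:
            m.conv.weight.data = eye.copy()
            m.conv.bias.data[:] = 0
    a, b = _pair(rng, c=c, h=10, w=8)
    o1, o2 = blk(a, b, channel_override=1.0, spectral_override=1.0)
    assert np.abs(o1.data - (a.data + b.data)).max() < 1e-5
    assert np.abs(o2.data - (a.data + b.data)).max() < 1e-5


def test_gradient_reaches_every_ffa_parameter(rng):
    a = Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32))
    blk = FFABlock(6)
    o1, o2 = blk(a, b)
    (o1.sum() + o2.sum()).backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.isfinite(p.grad).all(), name
    assert a.grad is not None


def test_shape_mismatch_rejected(rng):
    blk = FFABlock(4)
    with pytest.raises(ValueError):
        blk(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)),
            Tensor(np.zeros((1, 4, 8, 6), dtype=np.float32)))


# ------------------------------------------------------------ multimodal
@pytest.fixture(scope="module")
def mm_pair():
    return build_multimodal(use_ffa=True), build_multimodal(use_ffa=False)


def test_summation_fusion_symmetric_case(mm_pair):
    _, noffa = mm_pair
    # tie the two backbones' weights
    sd = {n: p for n, p in noffa.named_parameters()}
    for n, p in sd.items():
        if n.startswith("backbone_rgb."):
            sd["backbone_dir." + n[len("backbone_rgb."):]].data = p.data.copy()
    x = np.random.default_rng(0).normal(
        size=(1, 3, 64, 64)).astype(np.float32) * 0.1
    noffa.eval()
    with no_grad():
        bps = noffa.multimodal_forward(x, x)
        # single-stream feature of the rgb backbone
        r = Tensor(x)
        singles = []
        for k, (a, b) in enumerate(MultimodalDetector.STAGE_SLICES):
            for i in range(a, b):
                r = noffa.backbone_rgb[i](r)
            singles.append(r)
    for bp, s in zip(bps, singles):
        np.testing.assert_allclose(bp.data, 2 * s.data, rtol=1e-4, atol=1e-5)


def test_pyramid_stride_contract(mm_pair):
    mm, _ = mm_pair
    mm.eval()
    z = np.zeros((1, 3, 128, 128), dtype=np.float32)
    with no_grad():
        bp3, bp4, bp5 = mm.multimodal_forward(z, z)
    assert bp3.shape[-2:] == (16, 16)
    assert bp4.shape[-2:] == (8, 8)
    assert bp5.shape[-2:] == (4, 4)
    with no_grad():
        outs = mm(z, z)
    assert [o.shape[-1] for o in outs] == [16, 8, 4]


def test_without_ffa_strictly_fewer_parameters(mm_pair):
    mm, noffa = mm_pair
    assert count_parameters(noffa, "fused") < count_parameters(mm, "fused")
    assert count_parameters(noffa, "train") < count_parameters(mm, "train")


def test_misaligned_streams_rejected(mm_pair):
    mm, _ = mm_pair
    with pytest.raises(ValueError):
        mm.multimodal_forward(np.zeros((1, 3, 64, 64), dtype=np.float32),
                              np.zeros((1, 3, 32, 32), dtype=np.float32))
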