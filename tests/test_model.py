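"""Architecture contracts: tokenization, attention, decoding, shapes."""

import numpy as np
import pytest

from dynamap.autodiff import Tensor
from dynamap.model import (ModelConfig, PatchEmbed, SpatioTemporalModel,
                           _sincos_time_encoding)
from dynamap.objective import composite_loss


def tiny_cfg(**kw):
    base = dict(patch_size=4, embed_dim=16, n_heads=2, depth=1,
                attn_dropout=0.0, encoder_dropout=0.0,
                encoder_mode="space_time", n_networks=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def test_token_count_for_divisible_grid(rng):
    cfg = tiny_cfg(patch_size=5)
    pe = PatchEmbed(cfg, (20, 20, 20), 10, np.random.default_rng(0))
    seq = pe(rng.standard_normal((20, 20, 20, 10)))
    assert seq.grid_shape == (4, 4, 4)
    assert seq.tokens.shape == (10, 64, 16)


def test_non_divisible_grid_is_padded(rng):
    cfg = tiny_cfg(patch_size=5)
    pe = PatchEmbed(cfg, (21, 21, 21), 2, np.random.default_rng(0))
    seq = pe(rng.standard_normal((21, 21, 21, 2)))
    assert seq.grid_shape == (5, 5, 5)
    assert seq.tokens.shape == (2, 125, 16)


def test_identical_frames_give_identical_tokens_without_pos_embed(rng):
    cfg = tiny_cfg()
    pe = PatchEmbed(cfg, (8, 8, 8), 3, np.random.default_rng(0))
    pe.pos_embed.data[:] = 0.0
    frame = rng.standard_normal((8, 8, 8))
    data = np.repeat(frame[..., None], 3, axis=3)
    seq = pe(data)
    assert np.array_equal(seq.tokens.data[0], seq.tokens.data[1])
    assert np.array_equal(seq.tokens.data[0], seq.tokens.data[2])


@pytest.mark.parametrize("mode", ["space_time", "sequential"])
def test_attention_rows_sum_to_one(rng, mode):
    cfg = tiny_cfg(encoder_mode=mode)
    model = SpatioTemporalModel(cfg, (8, 8, 8), 3)
    model.forward(rng.standard_normal((8, 8, 8, 3)))
    blocks = (model.blocks if mode == "space_time"
              else model.temporal_blocks + model.spatial_blocks)
    for blk in blocks:
        attn = blk.attn.last_attention
        assert attn is not None
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-5)


@pytest.mark.parametrize("mode", ["space_time", "sequential"])
def test_zeroed_output_projections_make_encoder_identity(rng, mode):
    cfg = tiny_cfg(encoder_mode=mode)
    model = SpatioTemporalModel(cfg, (8, 8, 8), 2)
    blocks = (model.blocks if mode == "space_time"
              else model.temporal_blocks + model.spatial_blocks)
    for blk in blocks:
        blk.attn.out.weight.data[:] = 0.0
        blk.attn.out.bias.data[:] = 0.0
        blk.fc2.weight.data[:] = 0.0
        blk.fc2.bias.data[:] = 0.0
    seq = model.patch_embed(rng.standard_normal((8, 8, 8, 2)))
    out = model.encode(seq, rng=None)
    assert np.array_equal(out.tokens.data, seq.tokens.data)


def test_space_time_attention_is_permutation_equivariant(rng):
    """Permuting tokens together with their positional embeddings permutes
    the encoder output identically (3-token toy)."""
    cfg = tiny_cfg()
    model = SpatioTemporalModel(cfg, (4, 4, 16), 1)   # grid 1x1x4 -> 4 tokens
    x = rng.standard_normal((4, 4, 16, 1))
    seq = model.patch_embed(x)
    base = model.encode(seq, rng=None).tokens.data[0]
    perm = [2, 0, 3, 1]
    from dynamap.model import TokenSequence
    permuted = TokenSequence(
        tokens=Tensor(seq.tokens.data[:, perm, :]),
        grid_shape=seq.grid_shape, spatial_shape=seq.spatial_shape,
    )
    out_perm = model.encode(permuted, rng=None).tokens.data[0]
    assert np.allclose(out_perm, base[perm], atol=1e-5)


def test_sequential_single_frame_attention_weight_is_one(rng):
    cfg = tiny_cfg(encoder_mode="sequential")
    model = SpatioTemporalModel(cfg, (8, 8, 8), 1)
    model.forward(rng.standard_normal((8, 8, 8, 1)))
    attn = model.temporal_blocks[0].attn.last_attention
    assert attn.shape[-1] == 1
    assert np.allclose(attn, 1.0)


@pytest.mark.parametrize("mode", ["space_time", "sequential"])
@pytest.mark.parametrize("shape", [(16, 16, 16), (13, 10, 11)])
def test_end_to_end_shape_contract(rng, mode, shape):
    cfg = tiny_cfg(encoder_mode=mode)
    model = SpatioTemporalModel(cfg, shape, 3)
    dm = model.predict(rng.standard_normal(shape + (3,)))
    assert dm.data.shape == (2,) + shape + (3,)
    assert np.all(np.isfinite(dm.data))


def test_eval_forward_is_deterministic(rng):
    cfg = tiny_cfg(attn_dropout=0.4, encoder_dropout=0.3)
    model = SpatioTemporalModel(cfg, (8, 8, 8), 2)
    x = rng.standard_normal((8, 8, 8, 2))
    a = model.predict(x).data
    b = model.predict(x).data
    assert np.array_equal(a, b)


def test_time_encoding_disambiguates_identical_frames(rng):
    cfg = tiny_cfg()
    model = SpatioTemporalModel(cfg, (8, 8, 8), 2)
    frame = rng.standard_normal((8, 8, 8))
    data = np.repeat(frame[..., None], 2, axis=3)
    dm = model.predict(data)
    assert not np.allclose(dm.data[..., 0], dm.data[..., 1])


def test_sincos_encoding_distinguishes_indices():
    e0 = _sincos_time_encoding(0, 16)
    e1 = _sincos_time_encoding(1, 16)
    assert e0.shape == (16,)
    assert not np.allclose(e0, e1)


@pytest.mark.parametrize("mode", ["space_time", "sequential"])
def test_every_parameter_receives_gradient(rng, mode):
    cfg = tiny_cfg(encoder_mode=mode)
    model = SpatioTemporalModel(cfg, (8, 8, 8), 2)
    x = rng.standard_normal((8, 8, 8, 2))
    prior = rng.standard_normal((2, 8, 8, 8, 2))
    pred = model.forward(x, rng=np.random.default_rng(0))
    loss = composite_loss(prior.astype(np.float32), pred)
    loss.backward()
    for name, p in model.parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.any(p.grad != 0), f"zero gradient for {name}"


def test_embed_dim_head_divisibility_enforced():
    with pytest.raises(ValueError):
        tiny_cfg(embed_dim=15, n_heads=2)
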