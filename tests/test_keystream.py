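"""Keystream generator: key handling, an independent step-by-step
oracle, determinism, uniformity and key sensitivity."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from medicrypt import (
    EncryptionKey,
    GeneratorConfig,
    forward_pass,
    generate,
    init_generator,
    keystreams_for_key,
    split_key,
)

EPS = 2.0 ** -32


# ---------------------------------------------------------------------------
# key parsing / splitting
# ---------------------------------------------------------------------------

def test_key_parsing_and_halves():
    k = EncryptionKey.from_hex("0123456789ABCDEF")
    assert k.raw == 0x0123456789ABCDEF
    assert k.half_init == 0x01234567
    assert k.half_cubic == 0x89ABCDEF
    assert (k.half_init << 32) | k.half_cubic == k.raw
    assert EncryptionKey.from_hex("0x0123456789abcdef").raw == k.raw


@pytest.mark.parametrize("bad", ["", "123", "0123456789ABCDEFF", "g123456789abcdef"])
def test_malformed_hex_rejected(bad):
    with pytest.raises(ValueError):
        EncryptionKey.from_hex(bad)


def test_split_key_mapping():
    lo, hi = split_key(EncryptionKey(0))
    assert lo == hi == 0.5 / 2 ** 32
    lo, hi = split_key(EncryptionKey(0xFFFFFFFFFFFFFFFF))
    assert lo == hi == (2 ** 32 - 0.5) / 2 ** 32
    lo, _ = split_key(EncryptionKey(0x8000000000000000))
    assert lo == (2 ** 31 + 0.5) / 2 ** 32
    # strictly inside (0, 1) for the extreme keys
    assert 0.0 < lo < 1.0


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_shapes_and_determinism(key):
    cfg = GeneratorConfig(nhl=5)
    s1, s2 = init_generator(key, cfg), init_generator(key, cfg)
    shapes = [w.shape for w in s1.W]
    assert shapes == [(1, 1), (5, 1), (5, 5), (4, 5)]
    assert [b.shape for b in s1.B] == [(1,), (5,), (5,), (4,)]
    assert [p.shape for p in s1.P] == [(1,), (5,), (5,), (4,)]
    for a, b in zip(s1.W + s1.B + s1.P, s2.W + s2.B + s2.P):
        np.testing.assert_array_equal(a, b)
    assert s1.iter_count == cfg.r_min


def test_p_matrices_respect_control_ranges(key):
    cfg = GeneratorConfig()  # (logistic, pwlcm, lts, pwlcm)
    st = init_generator(key, cfg)
    assert np.all((st.P[0] >= 3.58) & (st.P[0] <= 4.0))
    assert np.all((st.P[1] > 0.0) & (st.P[1] < 0.5))
    assert np.all((st.P[2] > 0.0) & (st.P[2] < 4.0))
    assert np.all((st.P[3] > 0.0) & (st.P[3] < 0.5))


def test_one_bit_key_change_alters_parameters(key):
    st = init_generator(key)
    st2 = init_generator(key.flip_bit(0))  # cubic half: parameter matrices move
    assert any(
        not np.array_equal(a, b) for a, b in zip(st.W + st.B, st2.W + st2.B)
    )


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(nhl=0)
    with pytest.raises(ValueError):
        GeneratorConfig(r_min=0)
    with pytest.raises(ValueError):
        GeneratorConfig(r_min=9, r_max=8)
    with pytest.raises(ValueError):
        GeneratorConfig(layer_maps=("logistic", "pwlcm", "lts", "tent"))


# ---------------------------------------------------------------------------
# independent oracle: replay the generator rules from scratch
# ---------------------------------------------------------------------------

def _clamp(v):
    if v <= 0.0:
        return EPS
    if v >= 1.0:
        return 1.0 - EPS
    return v


def _oracle_step(map_id, g, t):
    if map_id == "logistic":
        out = g * t * (1.0 - t)
    elif map_id == "pwlcm":
        tt = 1.0 - t if t >= 0.5 else t
        out = tt / g if tt < g else (tt - g) / (0.5 - g)
    elif map_id == "lts":
        half = t / 2.0 if t < 0.5 else (1.0 - t) / 2.0
        out = (g * t * (1.0 - t) + (4.0 - g) * half) % 1.0
    else:  # cubic
        out = g * t * (1.0 - t * t)
    return _clamp(out)


def _oracle_streams(key, cfg, n):
    """Recompute the generator from the key with local arithmetic only."""
    u_init = (key.half_init + 0.5) / 2 ** 32
    t = (key.half_cubic + 0.5) / 2 ** 32
    draws = []
    nhl = cfg.nhl
    need = (1 + nhl + nhl * nhl + 4 * nhl) + 2 * (1 + nhl + nhl + 4)
    for i in range(cfg.warmup + need):
        t = _oracle_step("cubic", 2.59, t)
        if i >= cfg.warmup:
            draws.append(t)
    it = iter(draws)

    def take(shape):
        size = int(np.prod(shape))
        return np.array([next(it) for _ in range(size)]).reshape(shape)

    W = [take((1, 1)), take((nhl, 1)), take((nhl, nhl)), take((4, nhl))]
    B = [take((1,)), take((nhl,)), take((nhl,)), take((4,))]
    ranges = {"logistic": (3.58, 4.0), "pwlcm": (0.0, 0.5), "lts": (0.0, 4.0)}
    P = []
    for layer, shape in enumerate([(1,), (nhl,), (nhl,), (4,)]):
        lo, hi = ranges[cfg.layer_maps[layer]]
        P.append(lo + take(shape) * (hi - lo))

    outs = np.empty((4, n))
    s0 = u_init
    r = cfg.r_min
    for i in range(n):
        x = [s0]
        layer_out = None
        for layer in range(4):
            layer_out = []
            for j in range(W[layer].shape[0]):
                acc = 0.0
                for kk in range(W[layer].shape[1]):
                    acc += W[layer][j, kk] * x[kk]
                a = acc + B[layer][j]
                a -= math.floor(a)
                tt = a if a > 0.0 else EPS
                for _ in range(r):
                    tt = _oracle_step(cfg.layer_maps[layer], P[layer][j], tt)
                layer_out.append(tt)
            if layer == 0:
                s0_next = layer_out[0]
            x = layer_out
        outs[:, i] = layer_out
        r = cfg.r_min + int(math.floor(layer_out[3] * (cfg.r_max - cfg.r_min + 1)))
        s0 = s0_next
    return outs


def test_generate_matches_independent_oracle(key):
    cfg = GeneratorConfig(nhl=3)
    n = 8
    raw = _oracle_streams(key, cfg, n)
    ks = generate(init_generator(key, cfg), n)
    np.testing.assert_array_equal(ks.raw_w, raw[0])
    np.testing.assert_array_equal(ks.z, raw[3])
    np.testing.assert_array_equal(
        ks.x, np.minimum(np.floor(raw[1] * 256), 255).astype(np.uint8)
    )
    np.testing.assert_array_equal(
        ks.y, np.minimum(np.floor(raw[2] * 256), 255).astype(np.uint8)
    )


def test_forward_pass_reference_agrees_with_generate(key):
    """The compiled hot path is bit-identical to the pure-Python pass."""
    cfg = GeneratorConfig()
    st_ref, st_gen = init_generator(key, cfg), init_generator(key, cfg)
    ks = generate(st_gen, 16)
    ref = np.array([forward_pass(st_ref) for _ in range(16)]).T
    np.testing.assert_array_equal(ks.raw_w, ref[0])
    np.testing.assert_array_equal(ks.z, ref[3])
    assert st_gen.iter_count == st_ref.iter_count


def test_outputs_in_unit_interval_and_passes_differ(key):
    st = init_generator(key)
    outs = np.array([forward_pass(st) for _ in range(100)])
    assert np.all((outs > 0.0) & (outs < 1.0))
    # consecutive passes virtually never repeat an output vector
    assert np.all(np.any(outs[1:] != outs[:-1], axis=1))


# ---------------------------------------------------------------------------
# stream contracts
# ---------------------------------------------------------------------------

def test_generate_empty_and_negative(key):
    ks = generate(init_generator(key), 0)
    assert len(ks) == 0 and ks.x.size == ks.z.size == 0
    with pytest.raises(ValueError):
        generate(init_generator(key), -1)


def test_streams_reproducible_and_length_exact(key):
    a = keystreams_for_key(key, 1000)
    b = keystreams_for_key(key, 1000)
    assert a.x.size == a.y.size == a.w.size == a.raw_w.size == 1000
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.raw_w, b.raw_w)


def test_byte_stream_chi_square_uniform(key):
    """256-bin chi-square on 2^16 bytes at significance 0.01."""
    ks = keystreams_for_key(key, 1 << 16)
    counts = np.bincount(ks.x, minlength=256)
    expected = ks.x.size / 256
    stat = float(((counts - expected) ** 2 / expected).sum())
    assert stat < chi2.ppf(0.99, 255)


def test_byte_stream_entropy(key):
    """Empirical entropy of each byte stream over 2^16 draws >= 7.97 bits."""
    ks = keystreams_for_key(key, 1 << 16)
    for stream in (ks.w, ks.x, ks.y):
        p = np.bincount(stream, minlength=256) / stream.size
        p = p[p > 0]
        assert -(p * np.log2(p)).sum() >= 7.97


@pytest.mark.parametrize("bit", [0, 13, 31, 32, 50, 63])
def test_key_sensitivity_single_bit(key, bit):
    """Any single flipped key bit changes >= 99% of stream-x bytes."""
    n = 10_000
    a = keystreams_for_key(key, n)
    b = keystreams_for_key(key.flip_bit(bit), n)
    assert np.mean(a.x != b.x) >= 0.99
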