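"""Neural-network-structured heterogeneous chaotic keystream generator.

A 64-bit key drives a small four-layer network (one input neuron, two
hidden layers of ``nhl`` neurons, four output neurons) in which every
neuron's transfer function is a chaotic map applied repeatedly. A cubic
map, seeded from the second key half and warmed up, fills the weight
(W0-W3), bias (B0-B3) and control-parameter (P0-P3) matrices; the first
key half seeds the input neuron's state. Each forward pass emits four
unit-interval outputs:

* ``w`` — drives pixel-position scrambling (permutation targets),
* ``x`` — drives pixel substitution,
* ``y`` — drives per-pixel bit scrambling,
* ``z`` — feeds back into the generator: the per-neuron transfer-function
  iteration count for the next pass is ``r_min + floor(z * (r_max - r_min + 1))``.

The sequential pass-to-pass recurrence cannot be vectorized, so the
production path compiles the loop with numba; ``forward_pass`` keeps a
pure-Python reference semantics against which the compiled kernel is
held bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import maps
from .maps import EPS, MapParams, control_range

__all__ = [
    "EncryptionKey",
    "GeneratorConfig",
    "GeneratorState",
    "Keystreams",
    "split_key",
    "init_generator",
    "forward_pass",
    "generate",
]

_TWO32 = 2.0 ** 32
_MAP_CODES = {"logistic": 0, "pwlcm": 1, "lts": 2, "cubic": 3}

# Output layer uses PWLCM: it is the one map whose invariant density is
# uniform with full support on (0, 1), so quantized output bytes are
# unbiased. A logistic output layer demonstrably skews the byte
# histogram (its attractor for G < 4 does not even cover (0, 1)).
DEFAULT_LAYER_MAPS = ("logistic", "pwlcm", "lts", "pwlcm")


@dataclass(frozen=True)
class EncryptionKey:
    """A 64-bit encryption key, handled as two 32-bit halves.

    The first (most significant) half seeds the network's input state;
    the second half seeds the cubic map that fills the parameter
    matrices.
    """

    raw: int

    def __post_init__(self) -> None:
        if not 0 <= self.raw < 2 ** 64:
            raise ValueError("key must be a 64-bit unsigned value")

    @classmethod
    def from_hex(cls, text: str) -> "EncryptionKey":
        s = text.strip().lower().removeprefix("0x")
        if len(s) != 16 or any(c not in "0123456789abcdef" for c in s):
            raise ValueError(
                f"key must be exactly 16 hexadecimal characters, got {text!r}"
            )
        return cls(int(s, 16))

    @property
    def half_init(self) -> int:
        """First 32 bits — input-state seed."""
        return self.raw >> 32

    @property
    def half_cubic(self) -> int:
        """Last 32 bits — cubic-map seed."""
        return self.raw & 0xFFFFFFFF

    def hex(self) -> str:
        return f"{self.raw:016x}"

    def flip_bit(self, bit: int) -> "EncryptionKey":
        """A new key with bit *bit* (0 = least significant) flipped."""
        if not 0 <= bit < 64:
            raise ValueError("bit index must be in [0, 64)")
        return EncryptionKey(self.raw ^ (1 << bit))


def _unit_from_u32(h: int) -> float:
    # (h + 0.5) / 2^32 keeps the value strictly inside (0, 1); exact 0
    # is absorbing for all four maps.
    return (h + 0.5) / _TWO32


def split_key(key: EncryptionKey) -> tuple[float, float]:
    """Map the two 32-bit key halves to unit-interval seeds.

    Each half ``h`` becomes ``(h + 0.5) / 2**32`` — strictly inside
    (0, 1) for every 32-bit value.
    """
    return _unit_from_u32(key.half_init), _unit_from_u32(key.half_cubic)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable shape and iteration parameters of the generator.

    nhl
        Width of the two hidden layers. Any value >= 1.
    warmup
        Cubic-map warm-up iterations discarded before parameter filling.
    r_min, r_max
        Bounds on the per-neuron transfer-function iteration count; the
        count each pass is ``r_min + floor(z * (r_max - r_min + 1))``.
        Fewer than ~3 chaotic iterations leak the pre-activation's
        residual non-uniformity into the output bytes, so r_min
        defaults to 4 (measurably unbiased, with margin).
    layer_maps
        Chaotic map per layer (input, hidden 1, hidden 2, output). The
        maps alternate by default so adjacent layers differ.
    """

    nhl: int = 8
    warmup: int = 50
    r_max: int = 16
    r_min: int = 4
    layer_maps: tuple[str, str, str, str] = DEFAULT_LAYER_MAPS
    mol: int = 4  # fixed output width: w, x, y, z

    def __post_init__(self) -> None:
        if self.mol != 4:
            raise ValueError("the output layer is fixed at 4 neurons")
        if self.nhl < 1 or self.warmup < 0 or self.r_max < 1:
            raise ValueError("need nhl >= 1, warmup >= 0, r_max >= 1")
        if not 1 <= self.r_min <= self.r_max:
            raise ValueError("need 1 <= r_min <= r_max")
        if len(self.layer_maps) != 4:
            raise ValueError("layer_maps must name a map for each of 4 layers")
        for m in self.layer_maps:
            if m not in _MAP_CODES:
                raise ValueError(f"unknown map {m!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kw = {k: d[k] for k in ("nhl", "warmup", "r_max", "r_min") if k in d}
        if "layer_maps" in d:
            kw["layer_maps"] = tuple(d["layer_maps"])
        return cls(**kw)


@dataclass
class GeneratorState:
    """All mutable and immutable state of an initialized generator."""

    config: GeneratorConfig
    # weights: W0 (1,1), W1 (nhl,1), W2 (nhl,nhl), W3 (4,nhl)
    W: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    # biases and per-neuron controls, one vector per layer
    B: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    P: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    neuron_states: list[np.ndarray]
    iter_count: int = 1

    def copy(self) -> "GeneratorState":
        return GeneratorState(
            config=self.config,
            W=self.W,
            B=self.B,
            P=self.P,
            neuron_states=[s.copy() for s in self.neuron_states],
            iter_count=self.iter_count,
        )


def init_generator(key: EncryptionKey, cfg: GeneratorConfig | None = None) -> GeneratorState:
    """Build a generator state from a key.

    A cubic map (lambda = 2.59) is seeded from the key's second half,
    iterated ``cfg.warmup`` times with outputs discarded, and the
    subsequent trajectory fills, in fixed row-major order, W0, W1, W2,
    W3, then B0-B3, then P0-P3. Raw unit values destined for a P matrix
    are rescaled affinely into the control range of that layer's map.
    The input neuron's state comes from the key's first half and the
    iteration count starts at 1.
    """
    cfg = cfg or GeneratorConfig()
    u_init, u_cubic = split_key(key)
    nhl, mol = cfg.nhl, cfg.mol

    shapes_w = [(1, 1), (nhl, 1), (nhl, nhl), (mol, nhl)]
    sizes_bp = [1, nhl, nhl, mol]
    n_draw = sum(r * c for r, c in shapes_w) + 2 * sum(sizes_bp)
    stream = iter(
        maps.iterate(
            MapParams("cubic", maps.CUBIC_LAMBDA),
            u_cubic,
            cfg.warmup + n_draw,
            discard=cfg.warmup,
        )
    )

    def draw(n: int) -> np.ndarray:
        return np.array([next(stream) for _ in range(n)], dtype=np.float64)

    W = tuple(draw(r * c).reshape(r, c) for r, c in shapes_w)
    B = tuple(draw(n) for n in sizes_bp)
    P = []
    for layer, n in enumerate(sizes_bp):
        lo, hi = control_range(cfg.layer_maps[layer])
        P.append(lo + draw(n) * (hi - lo))
    neuron_states = [np.full(n, u_init, dtype=np.float64) for n in sizes_bp]
    return GeneratorState(
        config=cfg,
        W=W,
        B=B,
        P=tuple(P),
        neuron_states=neuron_states,
        iter_count=cfg.r_min,
    )


def _layer_outputs(
    weights: np.ndarray,
    bias: np.ndarray,
    controls: np.ndarray,
    map_id: str,
    inputs: np.ndarray,
    r: int,
) -> np.ndarray:
    """Reference per-layer rule: a = (w.x + b) mod 1, then r map steps.

    The weighted sum is accumulated with a naive left-to-right loop so
    the compiled kernel can reproduce it bit-for-bit.
    """
    stepper = maps._STEPPERS[map_id]
    out = np.empty(weights.shape[0], dtype=np.float64)
    for j in range(weights.shape[0]):
        acc = 0.0
        for k in range(weights.shape[1]):
            acc += weights[j, k] * inputs[k]
        a = acc + bias[j]
        a -= math.floor(a)
        t = a if a > 0.0 else EPS
        g = controls[j]
        for _ in range(r):
            t = stepper(t, g)
        out[j] = t
    return out


def forward_pass(state: GeneratorState) -> np.ndarray:
    """One pass through the network; returns the 4 outputs (w, x, y, z).

    Mutates *state*: neuron states become the new layer outputs and the
    iteration count is refreshed from the z output.
    """
    cfg = state.config
    r = state.iter_count
    x = state.neuron_states[0][:1]
    outs = []
    for layer in range(4):
        x = _layer_outputs(
            state.W[layer],
            state.B[layer],
            state.P[layer],
            cfg.layer_maps[layer],
            x,
            r,
        )
        outs.append(x)
    for layer in range(4):
        state.neuron_states[layer] = outs[layer]
    z = outs[3][3]
    state.iter_count = cfg.r_min + int(math.floor(z * (cfg.r_max - cfg.r_min + 1)))
    return outs[3].copy()


@dataclass(frozen=True)
class Keystreams:
    """The byte/index streams emitted by *n* forward passes."""

    w: np.ndarray  # uint8 bytes from the w output
    x: np.ndarray  # uint8 bytes from the x output (substitution)
    y: np.ndarray  # uint8 bytes from the y output (bit scrambling)
    z: np.ndarray  # raw unit-interval z outputs (iteration control)
    raw_w: np.ndarray  # raw unit-interval w outputs (index generation)

    def __len__(self) -> int:
        return self.w.size


def _quantize_bytes(u: np.ndarray) -> np.ndarray:
    # floor(u * 256), clamped; u < 1 so the clamp is defensive only
    return np.minimum(np.floor(u * 256.0), 255.0).astype(np.uint8)


def generate(state: GeneratorState, n: int) -> Keystreams:
    """Run *n* forward passes and collect all four output streams.

    Advances *state* in place; two calls continue the same trajectory.
    Deterministic for a fixed (key, config).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    raw = _run_passes(state, n)
    return Keystreams(
        w=_quantize_bytes(raw[0]),
        x=_quantize_bytes(raw[1]),
        y=_quantize_bytes(raw[2]),
        z=raw[3].copy(),
        raw_w=raw[0],
    )


def keystreams_for_key(
    key: EncryptionKey, n: int, cfg: GeneratorConfig | None = None
) -> Keystreams:
    """Convenience: initialize from *key* and generate *n* stream entries."""
    return generate(init_generator(key, cfg), n)


# ---------------------------------------------------------------------------
# compiled hot path
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised indirectly through generate()
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pack_state(state: GeneratorState):
    cfg = state.config
    codes = np.array([_MAP_CODES[m] for m in cfg.layer_maps], dtype=np.int64)
    return codes


if _HAVE_NUMBA:

    @njit(cache=False)
    def _step_nb(code: int, g: float, t: float) -> float:
        if code == 0:  # logistic
            out = g * t * (1.0 - t)
        elif code == 1:  # pwlcm
            tt = 1.0 - t if t >= 0.5 else t
            out = tt / g if tt < g else (tt - g) / (0.5 - g)
        elif code == 2:  # lts
            if t < 0.5:
                out = g * t * (1.0 - t) + (4.0 - g) * t / 2.0
            else:
                out = g * t * (1.0 - t) + (4.0 - g) * (1.0 - t) / 2.0
            out -= math.floor(out)
        else:  # cubic
            out = g * t * (1.0 - t * t)
        if out <= 0.0:
            return EPS
        if out >= 1.0:
            return 1.0 - EPS
        return out

    @njit(cache=False)
    def _passes_nb(W0, W1, W2, W3, B, P, codes, states, r0, r_min, r_max, n, raw):
        nhl = W1.shape[0]
        s0 = states[0]
        r = r0
        o0 = np.empty(1)
        o1 = np.empty(nhl)
        o2 = np.empty(nhl)
        o3 = np.empty(4)
        for i in range(n):
            # input layer (single neuron, self-recurrent)
            a = W0[0, 0] * s0 + B[0][0]
            a -= math.floor(a)
            t = a if a > 0.0 else EPS
            for _ in range(r):
                t = _step_nb(codes[0], P[0][0], t)
            o0[0] = t
            # hidden layer 1
            for j in range(nhl):
                acc = W1[j, 0] * o0[0]
                a = acc + B[1][j]
                a -= math.floor(a)
                t = a if a > 0.0 else EPS
                for _ in range(r):
                    t = _step_nb(codes[1], P[1][j], t)
                o1[j] = t
            # hidden layer 2
            for j in range(nhl):
                acc = 0.0
                for k in range(nhl):
                    acc += W2[j, k] * o1[k]
                a = acc + B[2][j]
                a -= math.floor(a)
                t = a if a > 0.0 else EPS
                for _ in range(r):
                    t = _step_nb(codes[2], P[2][j], t)
                o2[j] = t
            # output layer
            for j in range(4):
                acc = 0.0
                for k in range(nhl):
                    acc += W3[j, k] * o2[k]
                a = acc + B[3][j]
                a -= math.floor(a)
                t = a if a > 0.0 else EPS
                for _ in range(r):
                    t = _step_nb(codes[3], P[3][j], t)
                o3[j] = t
            raw[0, i] = o3[0]
            raw[1, i] = o3[1]
            raw[2, i] = o3[2]
            raw[3, i] = o3[3]
            r = r_min + int(math.floor(o3[3] * (r_max - r_min + 1)))
            s0 = o0[0]
        states_out = np.empty(1 + nhl + nhl + 4)
        states_out[0] = s0
        states_out[1 : 1 + nhl] = o1
        states_out[1 + nhl : 1 + 2 * nhl] = o2
        states_out[1 + 2 * nhl :] = o3
        return r, states_out


def _run_passes(state: GeneratorState, n: int) -> np.ndarray:
    """n forward passes; returns raw outputs, shape (4, n). Mutates state."""
    raw = np.empty((4, n), dtype=np.float64)
    if n == 0:
        return raw
    cfg = state.config
    if _HAVE_NUMBA:
        codes = _pack_state(state)
        W0, W1, W2, W3 = state.W
        B = tuple(np.ascontiguousarray(b) for b in state.B)
        P = tuple(np.ascontiguousarray(p) for p in state.P)
        states = np.array([state.neuron_states[0][0]])
        r_new, packed = _passes_nb(
            W0, W1, W2, W3, B, P, codes, states, state.iter_count,
            cfg.r_min, cfg.r_max, n, raw,
        )
        nhl = cfg.nhl
        state.neuron_states = [
            packed[:1].copy(),
            packed[1 : 1 + nhl].copy(),
            packed[1 + nhl : 1 + 2 * nhl].copy(),
            packed[1 + 2 * nhl :].copy(),
        ]
        state.iter_count = int(r_new)
    else:
        for i in range(n):
            raw[:, i] = forward_pass(state)
    return raw
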