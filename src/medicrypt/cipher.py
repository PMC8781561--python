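"""Two-stage chaotic image cipher: P-box permutation, then SP-box.

Encryption of an 8-bit grayscale image runs two keyed stages driven by
the keystream generator:

1. **P-box** — a position permutation. For each linear position ``t`` in
   scan order, a keystream value picks a target ``floor(u_t * N*M)`` and
   the two positions are swapped. Applied as sequential swaps the plan
   is a bijection by construction, and replaying the swaps in reverse
   order inverts it exactly.

2. **SP-box** — a per-pixel substitution plus bit permutation. The pixel
   is XORed with a key byte ``kx``, then its 8 bits are read as four
   2-bit groups, encoded as DNA bases under one of the 8 canonical
   Watson-Crick rules (selected by ``ky mod 8``), each base is replaced
   by its complement (A<->T, C<->G), the 4-base string is rotated left
   by ``(ky >> 3) mod 4``, and the bases are decoded back to bits under
   the same rule. Every (kx, ky) variant is a bijection on bytes, so
   decryption is exact.

The substitution is stateless (no ciphertext chaining), which bounds
error propagation: one corrupted ciphertext pixel damages exactly one
plaintext pixel.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .keystream import (
    EncryptionKey,
    GeneratorConfig,
    Keystreams,
    generate,
    init_generator,
)

__all__ = [
    "CipherConfig",
    "PermutationPlan",
    "DNA_RULES",
    "build_permutation",
    "apply_permutation",
    "sp_box_pixel",
    "encrypt_image",
    "decrypt_image",
    "load_image",
    "save_image",
]


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError("image must hold 8-bit integer intensities")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


# ---------------------------------------------------------------------------
# P-box
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationPlan:
    """An ordered swap list realizing the P-box for an N x M image.

    Step ``t`` swaps linear position ``t`` with ``targets[t]``. The
    composed mapping is a bijection on ``{0, ..., N*M - 1}``.
    """

    shape: tuple[int, int]
    targets: np.ndarray  # int64, length N*M

    def __post_init__(self) -> None:
        n = self.shape[0] * self.shape[1]
        if self.targets.size != n:
            raise ValueError("plan length must equal the pixel count")

    @property
    def swaps(self) -> list[tuple[int, int]]:
        return [(t, int(tg)) for t, tg in enumerate(self.targets)]

    def as_mapping(self) -> np.ndarray:
        """The composed permutation: entry i is where position i ends up."""
        n = self.targets.size
        pos = np.arange(n)
        for t in range(n):
            tg = self.targets[t]
            pos[t], pos[tg] = pos[tg], pos[t]
        # pos[j] = original position now sitting at j; invert
        out = np.empty(n, dtype=np.int64)
        out[pos] = np.arange(n)
        return out


def build_permutation(raw_w: np.ndarray, n_rows: int, m_cols: int) -> PermutationPlan:
    """Derive the swap plan from the raw unit-interval ``w`` stream.

    Needs at least ``N*M`` stream values; value ``u_t`` yields the
    target ``floor(u_t * N*M)`` for source position ``t``.
    """
    n = n_rows * m_cols
    raw_w = np.asarray(raw_w, dtype=np.float64)
    if raw_w.size < n:
        raise ValueError(f"keystream exhausted: need {n} values, have {raw_w.size}")
    targets = np.floor(raw_w[:n] * n).astype(np.int64)
    np.clip(targets, 0, n - 1, out=targets)  # defensive: u < 1 already
    return PermutationPlan(shape=(n_rows, m_cols), targets=targets)


def _apply_swaps_py(flat: np.ndarray, targets: np.ndarray, inverse: bool) -> None:
    rng = range(targets.size - 1, -1, -1) if inverse else range(targets.size)
    for t in rng:
        tg = targets[t]
        flat[t], flat[tg] = flat[tg], flat[t]


try:  # pragma: no cover - dispatch detail
    from numba import njit

    @njit(cache=False)
    def _apply_swaps_nb(flat, targets, inverse):  # pragma: no cover
        n = targets.size
        if inverse:
            for i in range(n):
                t = n - 1 - i
                tg = targets[t]
                tmp = flat[t]
                flat[t] = flat[tg]
                flat[tg] = tmp
        else:
            for t in range(n):
                tg = targets[t]
                tmp = flat[t]
                flat[t] = flat[tg]
                flat[tg] = tmp

    _apply_swaps = _apply_swaps_nb
except ImportError:  # pragma: no cover
    _apply_swaps = _apply_swaps_py


def apply_permutation(
    img: np.ndarray, plan: PermutationPlan, inverse: bool = False
) -> np.ndarray:
    """Scramble (or unscramble) pixel positions according to *plan*.

    Forward applies the swaps in order; inverse replays them backwards.
    The intensity histogram is untouched either way.
    """
    arr = _as_image(img)
    if arr.shape != plan.shape:
        raise ValueError(f"plan built for {plan.shape}, image is {arr.shape}")
    flat = arr.reshape(-1).copy()
    _apply_swaps(flat, plan.targets, inverse)
    return flat.reshape(arr.shape)


# ---------------------------------------------------------------------------
# SP-box
# ---------------------------------------------------------------------------

# The 8 base->2-bit assignments compatible with Watson-Crick pairing:
# bases are coded A=0, C=1, G=2, T=3 so complementation (A<->T, C<->G)
# is ``3 - code``; a rule maps each 2-bit value v to a base enc[v] with
# enc[3 - v] == 3 - enc[v].
DNA_RULES: tuple[tuple[int, int, int, int], ...] = (
    (0, 1, 2, 3),  # A C G T
    (0, 2, 1, 3),  # A G C T
    (1, 0, 3, 2),  # C A T G
    (2, 0, 3, 1),  # G A T C
    (1, 3, 0, 2),  # C T A G
    (2, 3, 0, 1),  # G T A C
    (3, 1, 2, 0),  # T C G A
    (3, 2, 1, 0),  # T G C A
)


def _dna_transform(byte: int, rule: int, rot: int) -> int:
    enc = DNA_RULES[rule]
    dec = {b: v for v, b in enumerate(enc)}
    groups = [(byte >> 6) & 3, (byte >> 4) & 3, (byte >> 2) & 3, byte & 3]
    bases = [3 - enc[v] for v in groups]          # encode + complement
    bases = bases[rot:] + bases[:rot]             # rotate left
    bits = [dec[b] for b in bases]                # decode, same rule
    return (bits[0] << 6) | (bits[1] << 4) | (bits[2] << 2) | bits[3]


def _build_dna_tables() -> tuple[np.ndarray, np.ndarray]:
    fwd = np.empty((32, 256), dtype=np.uint8)
    inv = np.empty((32, 256), dtype=np.uint8)
    for ky_low in range(32):
        rule, rot = ky_low & 7, (ky_low >> 3) & 3
        for c in range(256):
            fwd[ky_low, c] = _dna_transform(c, rule, rot)
        inv[ky_low, fwd[ky_low]] = np.arange(256, dtype=np.uint8)
    return fwd, inv


_DNA_FWD, _DNA_INV = _build_dna_tables()


def sp_box_pixel(p: int, kx: int, ky: int, inverse: bool = False) -> int:
    """Substitute one pixel with key bytes *kx* (XOR) and *ky* (DNA stage).

    ``ky mod 8`` selects the DNA rule and ``(ky >> 3) mod 4`` the base
    rotation. Total and exactly invertible on bytes.
    """
    for v in (p, kx, ky):
        if not 0 <= v <= 255:
            raise ValueError("pixel and key bytes must lie in [0, 255]")
    if inverse:
        return int(_DNA_INV[ky & 31, p]) ^ kx
    return int(_DNA_FWD[ky & 31, p ^ kx])


def _sp_box_array(flat: np.ndarray, kx: np.ndarray, ky: np.ndarray,
                  inverse: bool) -> np.ndarray:
    if inverse:
        return _DNA_INV[ky & 31, flat] ^ kx
    return _DNA_FWD[ky & 31, flat ^ kx]


# ---------------------------------------------------------------------------
# full cipher
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CipherConfig:
    """Cipher-wide configuration; currently the generator's knobs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_toml(cls, path: str | Path) -> "CipherConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        gen = GeneratorConfig.from_dict(data.get("generator", data))
        return cls(generator=gen)


def _streams_for(img: np.ndarray, key: EncryptionKey, cfg: CipherConfig) -> Keystreams:
    state = init_generator(key, cfg.generator)
    return generate(state, img.size)


def encrypt_image(
    img: np.ndarray, key: EncryptionKey, cfg: CipherConfig | None = None
) -> np.ndarray:
    """Encrypt an 8-bit grayscale image: P-box, then per-pixel SP-box."""
    cfg = cfg or CipherConfig()
    arr = _as_image(img)
    ks = _streams_for(arr, key, cfg)
    plan = build_permutation(ks.raw_w, *arr.shape)
    permuted = apply_permutation(arr, plan)
    flat = _sp_box_array(permuted.reshape(-1), ks.x, ks.y, inverse=False)
    return flat.reshape(arr.shape)


def decrypt_image(
    img: np.ndarray, key: EncryptionKey, cfg: CipherConfig | None = None
) -> np.ndarray:
    """Exact inverse of :func:`encrypt_image` under the same key/config."""
    cfg = cfg or CipherConfig()
    arr = _as_image(img)
    ks = _streams_for(arr, key, cfg)
    flat = _sp_box_array(arr.reshape(-1), ks.x, ks.y, inverse=True)
    plan = build_permutation(ks.raw_w, *arr.shape)
    return apply_permutation(flat.reshape(arr.shape), plan, inverse=True)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

_LOSSY = {".jpg", ".jpeg", ".webp"}


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as 8-bit grayscale (color converted by luma)."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        return np.asarray(im, dtype=np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image losslessly (PNG/BMP/TIFF)."""
    path = Path(path)
    if path.suffix.lower() in _LOSSY:
        raise ValueError(
            f"refusing lossy output format {path.suffix!r}; use PNG, BMP or TIFF"
        )
    Image.fromarray(_as_image(img), mode="L").save(path)
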