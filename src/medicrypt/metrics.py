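"""Statistical security evaluation of (plaintext, ciphertext) pairs.

The suite bundles the standard cipher-quality statistics — MSE and PSNR
between the pair, Shannon entropy of the ciphertext histogram,
adjacent-pixel Pearson correlation, and GLCM (gray-level co-occurrence
matrix) energy and contrast — plus a salt-and-pepper noise-attack trial.

A strong 8-bit ciphertext approaches entropy 8 bits, |correlation|
near 0, GLCM energy near ``1 / levels**2`` and GLCM contrast near the
i.i.d.-uniform expectation (10.5 at 8 levels); MSE against the plaintext
is large and PSNR correspondingly small.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .cipher import CipherConfig, decrypt_image, encrypt_image
from .keystream import EncryptionKey

__all__ = [
    "GlcmSpec",
    "SecurityReport",
    "mse",
    "psnr",
    "shannon_entropy",
    "adjacent_correlation",
    "glcm_features",
    "security_report",
    "salt_pepper",
    "noise_attack_trial",
]


def _pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity difference between two equal-size images."""
    a, b = _pair(a, b)
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.mean(d * d))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, ``10*log10(255^2 / MSE)``.

    Identical images (MSE 0) return ``inf``.
    """
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 / err)


def shannon_entropy(img: np.ndarray) -> float:
    """Shannon entropy in bits of the 256-level intensity histogram."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("image must be non-empty")
    counts = np.bincount(arr.reshape(-1).astype(np.int64), minlength=256)
    p = counts[counts > 0] / arr.size
    return float(-np.sum(p * np.log2(p)))


_DIRECTIONS = ("horizontal", "vertical", "diagonal")


def adjacent_correlation(img: np.ndarray, direction: str = "horizontal") -> float:
    """Pearson correlation of all adjacent pixel pairs along *direction*.

    Returns NaN for a constant image (undefined correlation).
    """
    arr = np.asarray(img, dtype=np.float64)
    if direction == "horizontal":
        if arr.shape[1] < 2:
            raise ValueError("need at least 2 columns")
        x, y = arr[:, :-1], arr[:, 1:]
    elif direction == "vertical":
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        x, y = arr[:-1, :], arr[1:, :]
    elif direction == "diagonal":
        if min(arr.shape) < 2:
            raise ValueError("need at least 2 rows and columns")
        x, y = arr[:-1, :-1], arr[1:, 1:]
    else:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    x, y = x.reshape(-1), y.reshape(-1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class GlcmSpec:
    """Quantization and neighbor offset for the co-occurrence matrix.

    Defaults — 8 gray levels, one pixel to the right, unsymmetric,
    normalized — put an ideal ciphertext at energy ~1/64 and contrast
    ~10.5.
    """

    levels: int = 8
    offset: tuple[int, int] = (0, 1)  # (row step, column step)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 quantization levels")
        if self.offset == (0, 0):
            raise ValueError("offset must be nonzero")


def glcm_matrix(img: np.ndarray, spec: GlcmSpec = GlcmSpec()) -> np.ndarray:
    """The normalized co-occurrence matrix P(i, j) for *spec*."""
    arr = np.asarray(img)
    dr, dc = spec.offset
    if arr.shape[0] <= abs(dr) or arr.shape[1] <= abs(dc):
        raise ValueError("image is not larger than the GLCM offset")
    q = (arr.astype(np.int64) * spec.levels) // 256
    rows = slice(max(0, -dr), arr.shape[0] - max(0, dr))
    cols = slice(max(0, -dc), arr.shape[1] - max(0, dc))
    i = q[rows, cols]
    j = q[rows.start + dr : rows.stop + dr, cols.start + dc : cols.stop + dc]
    counts = np.bincount(
        (i * spec.levels + j).reshape(-1), minlength=spec.levels ** 2
    )
    return counts.reshape(spec.levels, spec.levels) / counts.sum()


def glcm_features(img: np.ndarray, spec: GlcmSpec = GlcmSpec()) -> tuple[float, float]:
    """(energy, contrast) of the normalized co-occurrence matrix.

    Energy is ``sum P(i,j)^2``; contrast is ``sum (i-j)^2 P(i,j)``.
    """
    p = glcm_matrix(img, spec)
    idx = np.arange(spec.levels)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float(np.sum(p * p)), float(np.sum(diff2 * p))


@dataclass
class SecurityReport:
    """The metric bundle for one (plaintext, ciphertext) pair."""

    mse: float
    psnr_db: float
    entropy_bits: float
    correlation: dict[str, float]
    energy: float
    contrast: float
    elapsed_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SecurityReport":
        return cls(**json.loads(text))


def security_report(
    plain: np.ndarray, cipher: np.ndarray, glcm: GlcmSpec = GlcmSpec()
) -> SecurityReport:
    """Bundle all metrics: MSE/PSNR between the pair, the rest on the
    ciphertext. Wall-clock time of the evaluation is informational only."""
    plain, cipher = _pair(plain, cipher)
    t0 = time.perf_counter()
    energy, contrast = glcm_features(cipher, glcm)
    report = SecurityReport(
        mse=mse(plain, cipher),
        psnr_db=psnr(plain, cipher),
        entropy_bits=shannon_entropy(cipher),
        correlation={
            "h": adjacent_correlation(cipher, "horizontal"),
            "v": adjacent_correlation(cipher, "vertical"),
            "d": adjacent_correlation(cipher, "diagonal"),
        },
        energy=energy,
        contrast=contrast,
    )
    report.elapsed_s = time.perf_counter() - t0
    return report


def salt_pepper(img: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Corrupt each pixel independently to 0 or 255 with probability *density*."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    arr = np.asarray(img).copy()
    rng = np.random.default_rng(seed)
    hit = rng.random(arr.shape) < density
    grains = rng.integers(0, 2, size=arr.shape).astype(arr.dtype) * 255
    arr[hit] = grains[hit]
    return arr


def noise_attack_trial(
    img: np.ndarray,
    key: EncryptionKey,
    density: float,
    seed: int,
    cfg: CipherConfig | None = None,
) -> dict[str, float]:
    """Encrypt, corrupt the ciphertext with salt-and-pepper noise, decrypt.

    Because the SP-box is stateless per pixel and the P-box is a pure
    position permutation, each corrupted ciphertext pixel damages exactly
    one plaintext pixel, so the damaged fraction tracks the noise density
    and the content survives. Returns PSNR of the recovered image against
    the plaintext and the fraction of differing pixels.
    """
    cipher = encrypt_image(img, key, cfg)
    noisy = salt_pepper(cipher, density, seed)
    recovered = decrypt_image(noisy, key, cfg)
    return {
        "density": float(density),
        "psnr_db": psnr(recovered, img),
        "damaged_fraction": float(np.mean(recovered != np.asarray(img))),
    }
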