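"""Seeded synthetic fixtures: chest-X-ray-like images and patient records.

The real radiographs behind this cipher's evaluation are not publicly
distributable, so :func:`synth_xray` builds a stand-in with the
statistical property that matters for encryption benchmarks: a smooth,
anatomy-like 8-bit intensity field whose adjacent pixels are strongly
correlated (horizontal r >= 0.9). It is a low-pass random field plus a
bright elliptical "thorax" and two darker "lung" ellipses with mild
sensor noise — not a radiographic simulation.

:func:`load_symptom_table` returns the bundled 60-patient pneumonia
symptom dataset (13 coded symptom columns, values in {0, 1, 2}; 30
Normal and 30 Pneumonia records), packaged verbatim as CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SymptomRecord", "SYMPTOM_COLUMNS", "synth_xray", "load_symptom_table"]


def synth_xray(n_rows: int, m_cols: int, seed: int) -> np.ndarray:
    """A seeded N x M 8-bit grayscale image with X-ray-like smoothness.

    Construction: Gaussian-filtered white noise (correlation length
    ~min(N, M)/16), a bright thorax ellipse with two darker lung fields,
    and additive Gaussian sensor noise (sigma = 2 intensity levels),
    rescaled to [0, 255]. Horizontal adjacent-pixel correlation of the
    result is >= 0.9 by a wide margin. Deterministic per seed.
    """
    if n_rows < 16 or m_cols < 16:
        raise ValueError("image must be at least 16 x 16")
    rng = np.random.default_rng(seed)

    sigma = min(n_rows, m_cols) / 16.0
    field = gaussian_filter(rng.standard_normal((n_rows, m_cols)), sigma=sigma)
    field = field / (np.std(field) + 1e-12)

    r = (np.arange(n_rows)[:, None] - n_rows / 2.0) / (n_rows / 2.0)
    c = (np.arange(m_cols)[None, :] - m_cols / 2.0) / (m_cols / 2.0)
    thorax = np.exp(-((r / 0.8) ** 2 + (c / 0.7) ** 2))
    lungs = np.exp(-(((r + 0.1) / 0.45) ** 2 + ((c - 0.35) / 0.25) ** 2))
    lungs = lungs + np.exp(-(((r + 0.1) / 0.45) ** 2 + ((c + 0.35) / 0.25) ** 2))

    img = 1.2 * field + 3.0 * thorax - 1.8 * lungs
    img = img - img.min()
    img = img / (img.max() + 1e-12) * 235.0 + 10.0
    img = img + rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


SYMPTOM_COLUMNS = (
    "cough",
    "fever",
    "breathing_issues",
    "chest_pain",
    "loss_of_appetite",
    "energy",
    "fatigue",
    "unnamed",  # the source table prints a 13th, unlabeled symptom column
    "vomiting",
    "nausea",
    "sweating",
    "shaking_chill",
    "diarrhea",
)


@dataclass(frozen=True)
class SymptomRecord:
    """One patient's coded symptoms (0 absent, 1 present, 2 intense)."""

    patient: str
    codes: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.codes) != 13:
            raise ValueError("expected 13 symptom codes")
        if any(c not in (0, 1, 2) for c in self.codes):
            raise ValueError("codes must lie in {0, 1, 2}")
        if self.label not in ("Normal", "Pneumonia"):
            raise ValueError("label must be Normal or Pneumonia")

    def as_dict(self) -> dict:
        d = {"patient": self.patient}
        d.update(zip(SYMPTOM_COLUMNS, self.codes))
        d["label"] = self.label
        return d


def load_symptom_table() -> list[SymptomRecord]:
    """The bundled 60-patient symptom dataset, verbatim."""
    text = (
        resources.files("medicrypt").joinpath("data/symptom_table.csv").read_text()
    )
    records = []
    for row in csv.DictReader(text.splitlines()):
        codes = tuple(int(row[c]) for c in SYMPTOM_COLUMNS)
        records.append(
            SymptomRecord(patient=row["patient"], codes=codes, label=row["label"])
        )
    return records
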