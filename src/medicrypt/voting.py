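"""Ensemble voting rules: hard (majority) and soft (mean probability).

Data-agnostic aggregation for a two-class ensemble of K models. Hard
voting picks the modal predicted label; soft voting averages each
model's predicted probability of class A and assigns the class with the
larger mean. Percentages are reported to one decimal and ties break
toward class A (the lexicographically smallest label).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = ["VoteResult", "hard_vote", "soft_vote"]


@dataclass(frozen=True)
class VoteResult:
    """Winning label plus per-class percentage scores (one decimal)."""

    winner: str
    percents: dict[str, float]

    def to_dict(self) -> dict:
        return {"class": self.winner, **{
            f"percent_{k.lower()}": v for k, v in self.percents.items()
        }}


def hard_vote(labels: Sequence[str]) -> VoteResult:
    """Majority vote over predicted labels.

    The winner is the modal label; a tie goes to the smallest label in
    sort order (class "A" before "B").
    """
    if len(labels) == 0:
        raise ValueError("need at least one label")
    counts = Counter(str(lab) for lab in labels)
    top = max(counts.values())
    winner = min(lab for lab, c in counts.items() if c == top)
    n = len(labels)
    percents = {lab: round(100.0 * c / n, 1) for lab, c in sorted(counts.items())}
    return VoteResult(winner=winner, percents=percents)


def soft_vote(
    probs_a: Sequence[float], labels: tuple[str, str] = ("A", "B")
) -> VoteResult:
    """Mean-probability vote over per-model probabilities of class A.

    Class A's score is ``100 * mean(p)``; class B's is the complement
    ``100 * mean(1 - p)``. The larger mean wins, ties to class A.
    """
    if len(probs_a) == 0:
        raise ValueError("need at least one probability")
    p = [float(v) for v in probs_a]
    if any(v < 0.0 or v > 1.0 for v in p):
        raise ValueError("probabilities must lie in [0, 1]")
    mean_a = sum(p) / len(p)
    pct_a = round(100.0 * mean_a, 1)
    pct_b = round(100.0 * (1.0 - mean_a), 1)
    a, b = labels
    winner = a if pct_a >= pct_b else b
    return VoteResult(winner=winner, percents={a: pct_a, b: pct_b})
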