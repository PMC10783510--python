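"""G4Hunter base-wise scoring.

The G4Hunter score of a DNA sequence is the arithmetic mean of per-base
scores: every guanine in a maximal G-run of length ``L`` contributes
``+min(L, 4)``, every cytosine in a maximal C-run of length ``L``
contributes ``-min(L, 4)``, and A/T/N contribute 0.  Positive means favour
G-quadruplex formation on the given strand; negative means favour it on the
complementary strand.

Besides the classic rule this module implements a *softened* C-run penalty
in which every cytosine inside a C-run of length >= 3 contributes a fixed
``-soft_penalty`` (e.g. 2 or 1.5) instead of the capped run length.  The
rationale: a C-run penalises the score because it enables a competing
hairpin, not because cytosines impede quartet formation, and the classic
-3 per C can be too severe for sequences that still fold into a G4 at
physiological potassium.  Shorter C-runs (1 or 2) are scored classically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import groupby
from typing import Literal

import numpy as np

from .records import SequenceRecord

__all__ = [
    "ScoringScheme",
    "BaseScoreVector",
    "WindowScanResult",
    "score_bases",
    "g4hunter_score",
    "window_scan",
    "round_score",
]


def round_score(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation rounding for scores)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoringScheme:
    """Parameters of the per-base scoring rule.

    ``mode="classic"`` is the original G4Hunter rule.  ``mode="soft"``
    replaces the per-C penalty with ``-soft_penalty`` for every C in a
    maximal C-run of length >= 3; runs of 1 or 2 cytosines keep their
    classic -1/-2 scores.  ``g_run_cap`` caps the per-base magnitude
    (4 in classic G4Hunter).
    """

    mode: Literal["classic", "soft"] = "classic"
    soft_penalty: float = 2.0
    g_run_cap: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("classic", "soft"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.mode == "soft" and not (0 < self.soft_penalty <= 4):
            raise ValueError("soft_penalty must lie in (0, 4]")
        if self.g_run_cap < 1:
            raise ValueError("g_run_cap must be >= 1")

    @classmethod
    def from_string(cls, text: str) -> "ScoringScheme":
        """Parse ``"classic"`` or ``"soft:<penalty>"`` (CLI convention)."""
        text = text.strip().lower()
        if text == "classic":
            return cls(mode="classic")
        if text == "soft":
            return cls(mode="soft")
        if text.startswith("soft:"):
            return cls(mode="soft", soft_penalty=float(text.split(":", 1)[1]))
        raise ValueError(f"cannot parse scoring scheme {text!r}")

    def label(self) -> str:
        if self.mode == "classic":
            return "classic"
        return f"soft:{self.soft_penalty:g}"


@dataclass(frozen=True)
class BaseScoreVector:
    """Per-base G4Hunter scores for one sequence plus their mean."""

    record: SequenceRecord
    scores: np.ndarray
    scheme: ScoringScheme

    @property
    def mean_score(self) -> float:
        """The G4Hunter score: mean of per-base scores, full precision."""
        return float(self.scores.sum() / len(self.scores))

    @property
    def rounded(self) -> float:
        """Presentation value, rounded half away from zero to 2 decimals."""
        return round_score(self.mean_score)


@dataclass(frozen=True)
class WindowScanResult:
    """Sliding-window G4Hunter scan over one record.

    ``windows`` holds ``(start, end, mean)`` triples with 0-based half-open
    coordinates on the forward strand; ``hits`` is the subset whose
    ``|mean| >= threshold``, with strand '+' for positive windows and '-'
    for negative ones (a strongly negative window is a G4 candidate on the
    reverse strand).
    """

    record_id: str
    window: int
    step: int
    threshold: float
    scheme: ScoringScheme
    windows: list[tuple[int, int, float]]
    hits: list[tuple[int, int, float, str]] = field(default_factory=list)


def _runs(seq: str):
    """Maximal homopolymer runs as (base, start, length)."""
    pos = 0
    for base, group in groupby(seq):
        length = sum(1 for _ in group)
        yield base, pos, length
        pos += length


def score_bases(record: SequenceRecord, scheme: ScoringScheme | None = None) -> BaseScoreVector:
    """Score every base of ``record`` under ``scheme``.

    Pure function of ``(record.seq, scheme)``.  N breaks runs and scores 0.
    """
    scheme = scheme or ScoringScheme()
    scores = np.zeros(record.length, dtype=float)
    cap = scheme.g_run_cap
    for base, start, length in _runs(record.seq):
        if base == "G":
            scores[start : start + length] = min(length, cap)
        elif base == "C":
            if scheme.mode == "soft" and length >= 3:
                scores[start : start + length] = -scheme.soft_penalty
            else:
                scores[start : start + length] = -min(length, cap)
    return BaseScoreVector(record=record, scores=scores, scheme=scheme)


def g4hunter_score(record: SequenceRecord, scheme: ScoringScheme | None = None) -> float:
    """Mean per-base score of the whole sequence (full precision).

    Round with :func:`round_score` for presentation; under the classic
    scheme that 2-decimal value is the conventional published score.
    """
    return score_bases(record, scheme).mean_score


def window_scan(
    record: SequenceRecord,
    scheme: ScoringScheme | None = None,
    window: int = 25,
    step: int = 1,
    threshold: float = 1.2,
) -> WindowScanResult:
    """Sliding-window mean scores over ``record``.

    Windows with ``|mean| >= threshold`` are flagged as hits; negative-mean
    windows are reverse-strand candidates.
    """
    scheme = scheme or ScoringScheme()
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > record.length:
        raise ValueError(
            f"window {window} exceeds sequence length {record.length}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    base = score_bases(record, scheme).scores
    csum = np.concatenate([[0.0], np.cumsum(base)])
    starts = np.arange(0, record.length - window + 1, step)
    means = (csum[starts + window] - csum[starts]) / window
    windows = [(int(s), int(s + window), float(m)) for s, m in zip(starts, means)]
    if math.isinf(threshold):
        hits = []
    else:
        hits = [
            (s, e, m, "+" if m > 0 else "-")
            for s, e, m in windows
            if abs(m) >= threshold
        ]
    return WindowScanResult(
        record_id=record.id,
        window=window,
        step=step,
        threshold=threshold,
        scheme=scheme,
        windows=windows,
        hits=hits,
    )
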