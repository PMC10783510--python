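"""Hairpin/G-quadruplex phase-regime classification.

A G/C-rich PQS sits in one of three regimes with respect to the Na+/K+
balance of its buffer:

* ``g4_locked``      — the quadruplex predominates at any Na+/K+ ratio,
  including potassium-free sodium buffer;
* ``switchable``     — a hairpin predominates at low [K+] and the G4 takes
  over once a sequence-dependent potassium threshold is reached;
* ``hairpin_locked`` — the hairpin predominates regardless of potassium.

The default rule table keys on the cytosine content of the motif: a
sequence whose cytosines amount to at most one CCC equivalent (n_stat <= 1)
cannot build a competitive stem and is G4-locked; three or more discrete
CCC runs lock the hairpin in at every ionic condition; anything in between
is switchable, with the predominance threshold [K+] interpolated from a
calibration ladder (n_stat 4/3 -> 15 mM, 5/3 -> 25 mM, 2 -> 40 mM).  The
ladder and cut-offs live in a plain-text (JSON) rule table so they can be
re-calibrated without touching code.

This is an equilibrium call only.  Conversion between a pre-formed hairpin
and the G4 can be very slow (hours to days — the hairpin acts as a kinetic
trap), so a switchable call carries a caveat string to that effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .crun import CRunProfile, c_profile
from .hairpin import HairpinFold, max_hairpin_pairs
from .pqs import PqsHit
from .records import SequenceRecord, reverse_complement
from .scoring import BaseScoreVector, ScoringScheme, score_bases

__all__ = [
    "BufferCondition",
    "NAMED_BUFFERS",
    "RuleTable",
    "SwitchCall",
    "classify",
    "classify_record",
    "predict_fold",
]

KINETIC_CAVEAT = (
    "equilibrium call only: hairpin-to-G4 conversion can take hours to days "
    "(the pre-formed hairpin is a kinetic trap)"
)


@dataclass(frozen=True)
class BufferCondition:
    """An ionic condition: sodium and potassium concentrations in mM."""

    na_mM: float
    k_mM: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.na_mM < 0 or self.k_mM < 0:
            raise ValueError("ion concentrations must be >= 0")


#: The B1-B9 ladder: 140 mM total monovalent cation, sodium traded for
#: potassium.  B1 approximates extracellular and B9 intracellular ionics.
NAMED_BUFFERS: dict[str, BufferCondition] = {
    label: BufferCondition(na, k, label)
    for label, na, k in [
        ("B1", 140, 0),
        ("B2", 135, 5),
        ("B3", 125, 15),
        ("B4", 115, 25),
        ("B5", 100, 40),
        ("B6", 80, 60),
        ("B7", 70, 70),
        ("B8", 20, 120),
        ("B9", 0, 140),
    ]
}


@dataclass(frozen=True)
class RuleTable:
    """Tunable thresholds of the regime classifier.

    ``g4_locked_max_n`` — largest n_stat still called G4-locked.
    ``g4_locked_max_pairs`` — a G4-locked call additionally requires the
    G-C hairpin capacity to stay below this many pairs.
    ``hairpin_locked_min_ccc`` — smallest ccc_runs called hairpin-locked.
    ``ladder`` — (n_stat, K+ mM) calibration points for the switchable
    threshold; linear interpolation between points, clamped outside.
    """

    g4_locked_max_n: float = 1.0
    g4_locked_max_pairs: int = 6
    hairpin_locked_min_ccc: int = 3
    ladder: tuple[tuple[float, float], ...] = (
        (4 / 3, 15.0),  # low-confidence point: partial G4 signal at 15 mM
        (5 / 3, 25.0),
        (2.0, 40.0),
    )

    def k_threshold(self, n_stat: float) -> float:
        """Interpolated [K+] (mM) above which the G4 predominates."""
        pts = sorted(self.ladder)
        if n_stat <= pts[0][0]:
            return pts[0][1]
        if n_stat >= pts[-1][0]:
            return pts[-1][1]
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 <= n_stat <= x1:
                return y0 + (y1 - y0) * (n_stat - x0) / (x1 - x0)
        raise AssertionError("unreachable")

    def to_file(self, path: str | Path) -> None:
        data = {
            "g4_locked_max_n": self.g4_locked_max_n,
            "g4_locked_max_pairs": self.g4_locked_max_pairs,
            "hairpin_locked_min_ccc": self.hairpin_locked_min_ccc,
            "ladder": [list(point) for point in self.ladder],
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleTable":
        data = json.loads(Path(path).read_text())
        return cls(
            g4_locked_max_n=data["g4_locked_max_n"],
            g4_locked_max_pairs=data["g4_locked_max_pairs"],
            hairpin_locked_min_ccc=data["hairpin_locked_min_ccc"],
            ladder=tuple(tuple(point) for point in data["ladder"]),
        )


@dataclass(frozen=True)
class SwitchCall:
    """Phase classification of one sequence/hit."""

    record_id: str
    regime: str  # g4_locked | switchable | hairpin_locked
    k_threshold_mM: float  # 0 for g4_locked, inf for hairpin_locked
    drivers: dict = field(default_factory=dict)
    caveat: str | None = None


def classify(
    hit: PqsHit | None,
    profile: CRunProfile,
    fold: HairpinFold,
    score: BaseScoreVector,
    rules: RuleTable | None = None,
) -> SwitchCall:
    """Assign a phase regime from precomputed features.

    All features must describe the same sequence; ``hit`` may be None for
    arbitrary-sequence mode (the classification uses only cytosine and
    pairing features, but the hit is carried for provenance).
    """
    for name, value in (("profile", profile), ("fold", fold), ("score", score)):
        if value is None:
            raise ValueError(f"missing feature: {name}")
    rules = rules or RuleTable()
    drivers = {
        "ccc_runs": profile.ccc_runs,
        "n_stat": profile.n_stat,
        "max_gc_pairs": fold.max_pairs,
        "g4hunter": score.mean_score,
    }
    rid = hit.chrom if hit is not None else profile.record_id
    if profile.ccc_runs >= rules.hairpin_locked_min_ccc:
        return SwitchCall(rid, "hairpin_locked", math.inf, drivers)
    if profile.n_stat <= rules.g4_locked_max_n and fold.max_pairs < rules.g4_locked_max_pairs:
        return SwitchCall(rid, "g4_locked", 0.0, drivers)
    return SwitchCall(
        rid, "switchable", rules.k_threshold(profile.n_stat), drivers, KINETIC_CAVEAT
    )


def classify_record(
    record: SequenceRecord,
    rules: RuleTable | None = None,
    scheme: ScoringScheme | None = None,
) -> SwitchCall:
    """Convenience wrapper: compute all features of ``record`` and classify."""
    return classify(
        None,
        c_profile(record),
        max_hairpin_pairs(record, min_loop=1),
        score_bases(record, scheme),
        rules,
    )


def classify_hit(hit: PqsHit, rules: RuleTable | None = None) -> SwitchCall:
    """Classify a PQS hit from its motif-strand sequence."""
    seq = hit.seq if hit.strand == "+" else reverse_complement(hit.seq)
    rec = SequenceRecord(hit.chrom, seq)
    return classify(
        hit,
        c_profile(rec),
        max_hairpin_pairs(rec, min_loop=1),
        score_bases(rec),
        rules,
    )


def predict_fold(call: SwitchCall, buffer: BufferCondition) -> str:
    """Predominant low-temperature fold in ``buffer``: 'G4' or 'Hairpin'.

    Monotone in potassium: the fold can switch Hairpin -> G4 with rising
    [K+], never the reverse.
    """
    return "G4" if buffer.k_mM >= call.k_threshold_mM else "Hairpin"
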