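"""Cytosine-run decomposition and the N statistic.

Two distinct cytosine statistics are used when judging hairpin competition:

* ``n_stat`` — total cytosines divided by 3, i.e. the number of
  three-cytosine equivalents the sequence carries.  This is the fractional
  "N" reported for oligonucleotide series (a sequence with 4 C has
  N = 1.33).
* ``ccc_runs`` — the count of discrete maximal C-runs of length >= 3.
  Genome censuses of CCC-containing PQS filter on this integer.

Both are computed here and kept separate; conflating them changes which
sequences pass an ``N >= 2`` filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .records import SequenceRecord
from .scoring import round_score

__all__ = ["CRunProfile", "c_profile", "pairing_capacity_flags"]


@dataclass(frozen=True)
class CRunProfile:
    """Maximal C-run decomposition of one sequence."""

    record_id: str
    runs: tuple[tuple[int, int], ...]  # (start, length), maximal, disjoint
    total_c: int
    ccc_runs: int

    @property
    def n_stat(self) -> float:
        """total_c / 3 at full precision."""
        return self.total_c / 3

    @property
    def n_stat_rounded(self) -> float:
        """Presentation value: 2 decimals, half away from zero."""
        return round_score(self.n_stat)


def c_profile(record: SequenceRecord) -> CRunProfile:
    """Decompose ``record`` into maximal cytosine runs."""
    runs = []
    pos = 0
    for base, group in groupby(record.seq):
        length = sum(1 for _ in group)
        if base == "C":
            runs.append((pos, length))
        pos += length
    total_c = sum(length for _, length in runs)
    ccc = sum(1 for _, length in runs if length >= 3)
    return CRunProfile(
        record_id=record.id, runs=tuple(runs), total_c=total_c, ccc_runs=ccc
    )


def pairing_capacity_flags(record: SequenceRecord, profile: CRunProfile | None = None) -> list[bool]:
    """Per-C-run flag: can the run form three consecutive G-C pairs?

    A maximal C-run of length >= 3 is flagged ``True`` iff a G-run of
    length >= 3 exists elsewhere in the sequence (outside the C-run); such
    a run can zip up with a quartet-forming G-tract and seed a competing
    hairpin stem.  Runs shorter than 3 are always ``False``.  Inside a
    valid PQS every long C-run is flagged, since the motif guarantees
    G-tracts; the flag is informative for arbitrary sequences.
    """
    if profile is None:
        profile = c_profile(record)
    g_runs = []
    pos = 0
    for base, group in groupby(record.seq):
        length = sum(1 for _ in group)
        if base == "G" and length >= 3:
            g_runs.append((pos, length))
        pos += length
    flags = []
    for start, length in profile.runs:
        if length < 3:
            flags.append(False)
            continue
        end = start + length
        flags.append(any(ge <= start or gs >= end for gs, gl in g_runs for ge in [gs + gl]))
    return flags
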