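"""Maximal intramolecular base pairing — the competing-hairpin capacity.

A G/C-rich sequence that can zip its C-runs onto its G-tracts may fold into
a hairpin instead of a quadruplex.  This module quantifies that potential
as the maximum number of Watson-Crick G-C pairs (optionally also A-T)
attainable in a *nested* (non-crossing, pseudoknot-free) intramolecular
pairing with a minimum hairpin-loop length — a Nussinov-style
maximum-cardinality dynamic program with traceback to dot-bracket.

Only pair counting is done; there is no nearest-neighbour thermodynamic
model.  With ``min_loop=1`` the result is a pure pairing *capacity* (an
upper bound on stem content); ``min_loop=3`` is the sterically realistic
default for fold reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import SequenceRecord

__all__ = ["HairpinFold", "Stem", "max_hairpin_pairs", "stem_report"]

_GC = {("G", "C"), ("C", "G")}
_AT = {("A", "T"), ("T", "A")}


@dataclass(frozen=True)
class HairpinFold:
    """A maximum-cardinality nested pairing of one sequence."""

    record_id: str
    seq: str
    pairing: tuple[tuple[int, int], ...]  # (i, j) index pairs, i < j
    min_loop: int
    count_at: bool

    @property
    def max_pairs(self) -> int:
        return len(self.pairing)

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.seq)
        for i, j in self.pairing:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class Stem:
    """A run of consecutively stacked pairs (i, j), (i+1, j-1), ..."""

    outer: tuple[int, int]
    length: int

    @property
    def inner(self) -> tuple[int, int]:
        i, j = self.outer
        return (i + self.length - 1, j - self.length + 1)


def _pairable(a: str, b: str, count_at: bool) -> bool:
    return (a, b) in _GC or (count_at and (a, b) in _AT)


def max_hairpin_pairs(
    record: SequenceRecord, min_loop: int = 3, count_at: bool = False
) -> HairpinFold:
    """Maximum nested pairing of ``record`` under a minimum loop length.

    The recurrence over intervals [i, j] is::

        N[i, j] = max( N[i+1, j],
                       max over k: i+min_loop < k <= j, (i, k) pairable
                           of 1 + N[i+1, k-1] + N[k+1, j] )

    Among co-optimal solutions the traceback is deterministic: at each
    interval it prefers pairing the left end, and pairs it with the
    rightmost compatible partner (outermost pair first).
    """
    if min_loop < 1:
        raise ValueError("min_loop must be >= 1")
    seq = record.seq
    n = len(seq)
    N = np.zeros((n + 2, n + 2), dtype=np.int32)  # padded for k+1 > n
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(seq[i], seq[k], count_at):
                    cand = 1 + N[i + 1, k - 1] + N[k + 1, j]
                    if cand > best:
                        best = cand
            N[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop or N[i, j] == 0:
            continue
        paired = False
        for k in range(j, i + min_loop, -1):  # outermost partner first
            if _pairable(seq[i], seq[k], count_at) and N[i, j] == 1 + N[i + 1, k - 1] + N[k + 1, j]:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    pairs.sort()
    return HairpinFold(
        record_id=record.id,
        seq=seq,
        pairing=tuple(pairs),
        min_loop=min_loop,
        count_at=count_at,
    )


def stem_report(fold: HairpinFold) -> dict:
    """Descriptive decomposition of a fold's pairing.

    Returns stems (maximal runs of stacked pairs), hairpin-loop sizes (the
    unpaired span enclosed by a stem with nothing inside it), and the
    dangling-end lengths (unpaired bases outside the outermost pair).
    """
    pairs = sorted(fold.pairing)
    stems: list[Stem] = []
    used = set()
    pair_set = set(pairs)
    for i, j in pairs:
        if (i, j) in used:
            continue
        length = 1
        while (i + length, j - length) in pair_set:
            used.add((i + length, j - length))
            length += 1
        stems.append(Stem(outer=(i, j), length=length))

    loops = []
    for stem in stems:
        inner_i, inner_j = stem.inner
        enclosed = [p for p in pairs if inner_i < p[0] and p[1] < inner_j]
        if not enclosed:
            loops.append(inner_j - inner_i - 1)

    if pairs:
        first = min(i for i, _ in pairs)
        last = max(j for _, j in pairs)
        dangles = (first, len(fold.seq) - 1 - last)
    else:
        dangles = (0, 0)
    return {"stems": stems, "hairpin_loops": loops, "dangling_ends": dangles}
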