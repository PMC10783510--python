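"""Putative quadruplex sequence (PQS) detection.

Four motif classes are recognised, all built from four G-tracts that can
supply the strands of a three-quartet core:

* ``classical``  — four tracts of >= 3 G, all three loops 1-7 nt;
* ``long_loop``  — as classical but exactly one loop of 8-15 nt;
* ``bulged``     — one tract is a G-triplet interrupted by a single
  1-7 nt non-G bulge (G·GG or GG·G), the other three tracts intact;
* ``vacancy``    — one tract carries only two guanines (a G-vacancy),
  the other three >= 3 G, loops 1-7 nt.

Detection is run-based rather than regex-based: the sequence is decomposed
into maximal G-runs, candidate tract units are assembled from those runs,
and hits are built by a greedy left-to-right walk that takes the shortest
motif satisfying the class at each anchor (minimal loops, minimal tracts).
Overlapping hits of one class collapse to the leftmost representative, and
a locus satisfying several classes is reported once under the precedence
classical > long_loop > bulged > vacancy (``report_all`` disables both
reductions).  Minus-strand hits are C-motifs on the forward strand whose
reverse complement satisfies the class; their coordinates are reported on
the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import groupby

from .records import SequenceRecord, reverse_complement
from .crun import c_profile

__all__ = [
    "MotifClassConfig",
    "PqsHit",
    "CensusSummary",
    "DEFAULT_CLASSES",
    "CLASS_PRECEDENCE",
    "find_pqs",
    "census",
]

CLASS_PRECEDENCE = ("classical", "long_loop", "bulged", "vacancy")


@dataclass(frozen=True)
class MotifClassConfig:
    """Grammar parameters of one motif class."""

    name: str
    tract_min_g: int = 3
    short_loop: tuple[int, int] = (1, 7)
    long_loop: tuple[int, int] = (8, 15)
    bulge_len: tuple[int, int] = (1, 7)

    def __post_init__(self) -> None:
        if self.name not in CLASS_PRECEDENCE:
            raise ValueError(f"unknown motif class {self.name!r}")


DEFAULT_CLASSES: dict[str, MotifClassConfig] = {
    name: MotifClassConfig(name=name) for name in CLASS_PRECEDENCE
}


@dataclass(frozen=True)
class PqsHit:
    """One detected PQS interval with its tract/loop decomposition.

    Coordinates are 0-based half-open on the forward strand.  ``tracts``
    and ``loops`` are intervals in forward-strand coordinates, ordered
    5'->3' on the forward strand; ``seq`` is the forward-strand slice.
    """

    chrom: str
    start: int
    end: int
    strand: str
    motif_class: str
    tracts: tuple[tuple[int, int], ...]
    loops: tuple[tuple[int, int], ...]
    seq: str

    @property
    def loop_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.loops)

    def overlaps(self, other: "PqsHit") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def validate(self, config: MotifClassConfig | None = None) -> None:
        """Re-check that the hit satisfies its class grammar (self-audit)."""
        cfg = config or DEFAULT_CLASSES[self.motif_class]
        motif = self.seq if self.strand == "+" else reverse_complement(self.seq)
        hits = _scan_strand(motif, cfg, report_all=True)
        span = (0, len(motif))
        if not any((h[0], h[1]) == span for h in hits):
            raise AssertionError(
                f"hit {self.chrom}:{self.start}-{self.end} ({self.strand}) does "
                f"not re-match class {self.motif_class}"
            )
        covered = sum(e - s for s, e in self.tracts) + sum(e - s for s, e in self.loops)
        if covered != self.end - self.start:
            raise AssertionError("tracts and loops do not tile the hit interval")


# ---------------------------------------------------------------------------
# single-strand scanning


def _g_runs(seq: str) -> list[tuple[int, int]]:
    runs, pos = [], 0
    for base, group in groupby(seq):
        length = sum(1 for _ in group)
        if base == "G":
            runs.append((pos, length))
        pos += length
    return runs


@dataclass(frozen=True)
class _Unit:
    start: int
    end: int
    kind: str       # intact | bulged | gg
    first_run: int  # index of first constituent maximal G-run
    last_run: int


def _units_for_class(runs: list[tuple[int, int]], cfg: MotifClassConfig) -> list[_Unit]:
    units: list[_Unit] = []
    for i, (s, ln) in enumerate(runs):
        if ln >= cfg.tract_min_g:
            units.append(_Unit(s, s + ln, "intact", i, i))
        elif cfg.name == "vacancy" and ln == 2:
            units.append(_Unit(s, s + ln, "gg", i, i))
    if cfg.name == "bulged":
        lo, hi = cfg.bulge_len
        for i in range(len(runs) - 1):
            (s1, l1), (s2, l2) = runs[i], runs[i + 1]
            if l1 + l2 == cfg.tract_min_g and lo <= s2 - (s1 + l1) <= hi:
                units.append(_Unit(s1, s2 + l2, "bulged", i, i + 1))
    units.sort(key=lambda u: (u.start, u.end))
    return units


def _scan_strand(
    seq: str, cfg: MotifClassConfig, report_all: bool
) -> list[tuple[int, int, tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]]:
    """All (or greedy-per-anchor) motif matches of one class on one strand.

    Returns (start, end, tracts, loops) tuples in local coordinates.
    """
    runs = _g_runs(seq)
    units = _units_for_class(runs, cfg)
    lo, hi = cfg.short_loop
    long_lo, long_hi = cfg.long_loop
    max_gap = long_hi if cfg.name == "long_loop" else hi
    out = []

    def specials(chosen: list[_Unit]) -> int:
        return sum(1 for u in chosen if u.kind != "intact")

    def walk(chosen: list[_Unit], long_used: bool) -> bool:
        """Extend ``chosen`` to 4 tracts; returns True once a hit is taken
        (greedy mode stops the anchor's search there)."""
        if len(chosen) == 4:
            if cfg.name == "long_loop" and not long_used:
                return False
            if cfg.name in ("bulged", "vacancy") and specials(chosen) != 1:
                return False
            tracts = tuple((u.start, u.end) for u in chosen)
            loops = tuple(
                (chosen[k].end, chosen[k + 1].start) for k in range(3)
            )
            out.append((chosen[0].start, chosen[-1].end, tracts, loops))
            return not report_all
        prev = chosen[-1]
        for u in units:
            if u.first_run <= prev.last_run:
                continue
            gap = u.start - prev.end
            if gap < 1:
                continue
            if gap > max_gap:
                break  # units sorted by start: every later unit is farther
            if u.kind != "intact" and specials(chosen) >= 1:
                continue
            if lo <= gap <= hi:
                if walk(chosen + [u], long_used):
                    return True
            elif cfg.name == "long_loop" and not long_used and long_lo <= gap <= long_hi:
                if walk(chosen + [u], True):
                    return True
        return False

    for anchor in units:
        walk([anchor], False)
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def _merge_leftmost(hits: list[PqsHit]) -> list[PqsHit]:
    """Collapse overlapping same-class/strand hits to the leftmost one."""
    kept: list[PqsHit] = []
    for hit in sorted(hits, key=lambda h: (h.start, h.end)):
        if any(
            hit.overlaps(k) and k.strand == hit.strand and k.motif_class == hit.motif_class
            for k in kept
        ):
            continue
        kept.append(hit)
    return kept


def find_pqs(
    record: SequenceRecord,
    classes: dict[str, MotifClassConfig] | list[str] | None = None,
    both_strands: bool = True,
    report_all: bool = False,
) -> list[PqsHit]:
    """Detect PQS of the requested motif classes in ``record``.

    Hits come back sorted leftmost-first.  Unless ``report_all`` is set,
    overlapping same-class hits collapse to the leftmost representative and
    multi-class loci are resolved by class precedence.
    """
    if classes is None:
        configs = dict(DEFAULT_CLASSES)
    elif isinstance(classes, dict):
        configs = classes
    else:
        configs = {name: DEFAULT_CLASSES[name] for name in classes}

    length = record.length
    strands = [("+", record.seq)]
    if both_strands:
        strands.append(("-", reverse_complement(record.seq)))

    per_class: dict[str, list[PqsHit]] = {}
    for name in CLASS_PRECEDENCE:
        if name not in configs:
            continue
        cfg = configs[name]
        found: list[PqsHit] = []
        for strand, seq in strands:
            for s, e, tracts, loops in _scan_strand(seq, cfg, report_all):
                if strand == "+":
                    hit = PqsHit(record.id, s, e, "+", name, tracts, loops, record.seq[s:e])
                else:
                    flip = lambda iv: (length - iv[1], length - iv[0])
                    hit = PqsHit(
                        record.id,
                        length - e,
                        length - s,
                        "-",
                        name,
                        tuple(flip(t) for t in reversed(tracts)),
                        tuple(flip(l) for l in reversed(loops)),
                        record.seq[length - e : length - s],
                    )
                found.append(hit)
        per_class[name] = found if report_all else _merge_leftmost(found)

    if report_all:
        all_hits = [h for hits in per_class.values() for h in hits]
        return sorted(all_hits, key=lambda h: (h.start, h.end, h.strand, h.motif_class))

    kept: list[PqsHit] = []
    for name in CLASS_PRECEDENCE:
        for hit in per_class.get(name, []):
            if any(
                hit.overlaps(k) and k.strand == hit.strand and k.motif_class != name
                for k in kept
            ):
                continue
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.start, h.end, h.strand))


# ---------------------------------------------------------------------------
# census


@dataclass(frozen=True)
class CensusSummary:
    """Counts of PQS and of their cytosine-run content."""

    total_pqs: int
    with_ccc_ge1: int
    with_ccc_ge2: int
    passing_threshold: int
    n_threshold: float
    filter_on: str
    frequency_per_kb: float | None = None
    feature_counts: dict[str, int] | None = None


def census(
    hits: list[PqsHit],
    profiles=None,
    n_threshold: float = 1,
    filter_on: str = "ccc_runs",
    total_bases: int | None = None,
    annotation: list[tuple[str, int, int, str]] | None = None,
) -> CensusSummary:
    """Summarise a hit list by cytosine-run content.

    ``profiles`` are :class:`~g4switch.crun.CRunProfile` objects aligned to
    ``hits`` (computed from the hit slices when omitted); the motif-strand
    sequence is used, so minus-strand hits count the C-runs that their
    G-motif faces.  ``filter_on`` selects whether ``n_threshold`` applies
    to the integer ``ccc_runs`` or to the fractional ``n_stat``.
    ``annotation`` is a list of (chrom, start, end, feature) intervals for
    the per-feature breakdown.
    """
    if filter_on not in ("ccc_runs", "n_stat"):
        raise ValueError("filter_on must be 'ccc_runs' or 'n_stat'")
    if profiles is None:
        profiles = [
            c_profile(
                SequenceRecord(
                    h.chrom,
                    h.seq if h.strand == "+" else reverse_complement(h.seq),
                )
            )
            for h in hits
        ]
    if len(profiles) != len(hits):
        raise ValueError("profiles must align one-to-one with hits")

    ge1 = sum(1 for p in profiles if p.ccc_runs >= 1)
    ge2 = sum(1 for p in profiles if p.ccc_runs >= 2)
    key = (lambda p: p.ccc_runs) if filter_on == "ccc_runs" else (lambda p: p.n_stat)
    passing = sum(1 for p in profiles if key(p) >= n_threshold)

    freq = None
    if total_bases:
        freq = len(hits) / total_bases * 1000

    feature_counts = None
    if annotation is not None:
        ann_chroms = {a[0] for a in annotation}
        hit_chroms = {h.chrom for h in hits}
        if hits and not (ann_chroms & hit_chroms):
            warnings.warn(
                "annotation chromosome names match no hit; feature breakdown skipped",
                stacklevel=2,
            )
        else:
            feature_counts = {}
            for h in hits:
                for chrom, s, e, feature in annotation:
                    if chrom == h.chrom and h.start < e and s < h.end:
                        feature_counts[feature] = feature_counts.get(feature, 0) + 1
    return CensusSummary(
        total_pqs=len(hits),
        with_ccc_ge1=ge1,
        with_ccc_ge2=ge2,
        passing_threshold=passing,
        n_threshold=n_threshold,
        filter_on=filter_on,
        frequency_per_kb=freq,
        feature_counts=feature_counts,
    )
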