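"""Deterministic fixtures: the CEB oligonucleotide family and synthetic
genomes with planted PQS motifs.

The CEB family is the ten-member mutational series built on the human
minisatellite CEB25 quadruplex (CEBwt), a parallel G4 with two 1-nt loops
and a 9-nt central loop.  The mutants progressively replace central-loop
bases with cytosines (CEBm1..CEBm4) and append 3' C-rich extensions
(CEBm5..CEBm7); CEBm0A/CEBm0T are loop-composition controls with the loop
rewritten in adenines/thymines.  The family is constructed here
programmatically from the wild-type scaffold and self-checked for length
and composition, so every scorer and classifier can be exercised without
any external download.

Synthetic genomes carry planted motifs on an i.i.d. background whose G/C
runs are capped at length 2, so the planted motifs are, by construction,
the only PQS present — which makes recall and false-positive audits exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SequenceRecord

__all__ = ["FixtureSpec", "build_ceb_family", "synth_genome", "CEB_IDS"]

# CEBwt scaffold: 5' flank + G-tract block, central loop, G-tract block.
_PREFIX = "AAGGGTGGGT"      # A-A, tract 1, 1-nt loop, tract 2, loop start
_WT_CORE = "GTAAGTGT"       # remainder of the 9-nt central loop
_SUFFIX = "GGGTGGGT"        # tract 3, 1-nt loop, tract 4, 3' T

# (acronym, central-loop replacement, 3' extension)
_FAMILY_EDITS = [
    ("CEBwt", _WT_CORE, ""),
    ("CEBm0A", "AAAAAAA" + _WT_CORE[7:], ""),   # first 7 loop bases -> A
    ("CEBm0T", "TTTATTTT", ""),
    ("CEBm1", "CCCAGTGT", ""),
    ("CEBm2", "CCCACTGT", ""),
    ("CEBm3", "CCCACCGT", ""),
    ("CEBm4", "CCCACCCT", ""),
    ("CEBm5", "CCCACCCT", "CCCA"),
    ("CEBm6", "CCCAGTGT", "CCCACCCA"),
    ("CEBm7", "CCCACCCT", "CCCACCCA"),
]

CEB_IDS = tuple(name for name, _, _ in _FAMILY_EDITS)


def build_ceb_family() -> list[SequenceRecord]:
    """Construct CEBwt and its nine mutants from the wild-type scaffold.

    Self-checks: every member keeps the four intact GGG tracts of the
    scaffold, loop edits preserve length, and extensions only append.
    """
    records = []
    for name, core, extension in _FAMILY_EDITS:
        if len(core) != len(_WT_CORE):
            raise AssertionError(f"{name}: central-loop edit changes length")
        seq = _PREFIX + core + _SUFFIX + extension
        if seq.count("GGGT") < 4:
            raise AssertionError(f"{name}: G-tract scaffold damaged")
        records.append(SequenceRecord(name, seq))
    return records


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a planted-motif synthetic genome.

    ``planted`` lists (motif_class, count) pairs; ``background_gc`` is the
    G+C fraction of the background, generated i.i.d. but with G/C runs
    capped at length 2 so no background PQS can arise.  ``seed`` fully
    determines the output.
    """

    genome_length: int
    planted: tuple[tuple[str, int], ...] = field(default_factory=tuple)
    background_gc: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not (0 <= self.background_gc <= 1):
            raise ValueError("background_gc must lie in [0, 1]")
        object.__setattr__(self, "planted", tuple(tuple(p) for p in self.planted))


_BASES = np.array(list("ACGT"))


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. background with maximal G/C runs capped at 2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = rng.choice(4, size=length, p=p)
    # resample third base of any G/C run of 3: scan and fix forward
    for i in range(2, length):
        b = out[i]
        if b in (1, 2) and out[i - 1] == b and out[i - 2] == b:
            others = [x for x in range(4) if x != b]
            q = p[others] / p[others].sum()
            out[i] = rng.choice(others, p=q)
    return _BASES[out]


def _loop(rng: np.random.Generator, lo: int, hi: int) -> str:
    """A/T-only loop (keeps planted motifs free of extra G/C runs)."""
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(["A", "T"], size=n))


def _motif(motif_class: str, rng: np.random.Generator) -> str:
    g3 = "GGG"
    if motif_class == "classical":
        loops = [_loop(rng, 1, 7) for _ in range(3)]
        tracts = [g3] * 4
    elif motif_class == "long_loop":
        loops = [_loop(rng, 1, 7) for _ in range(3)]
        loops[int(rng.integers(0, 3))] = _loop(rng, 8, 15)
        tracts = [g3] * 4
    elif motif_class == "bulged":
        split = ("G", "GG") if rng.integers(0, 2) else ("GG", "G")
        bulged = split[0] + _loop(rng, 1, 7) + split[1]
        tracts = [g3] * 4
        tracts[int(rng.integers(0, 4))] = bulged
        loops = [_loop(rng, 1, 7) for _ in range(3)]
    elif motif_class == "vacancy":
        tracts = [g3] * 4
        tracts[int(rng.integers(0, 4))] = "GG"
        loops = [_loop(rng, 1, 7) for _ in range(3)]
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    parts = [tracts[0]]
    for loop, tract in zip(loops, tracts[1:]):
        parts.append(loop)
        parts.append(tract)
    return "".join(parts)


def synth_genome(spec: FixtureSpec) -> tuple[SequenceRecord, list[tuple[str, int, int, str]]]:
    """Generate a planted-motif genome and its truth intervals.

    Returns the genome record and a truth list of BED-style tuples
    (chrom, start, end, motif_class).  Planted motifs never overlap; each
    is flanked by a 16-nt A/T guard zone so background G/C runs can
    neither extend a planted tract nor combine with plant tracts into a
    spurious cross-motif hit (every motif loop is capped at 15 nt).
    """
    guard = 16  # > longest permitted loop
    rng = np.random.default_rng(spec.seed)
    genome = _background(spec.genome_length, spec.background_gc, rng)

    motifs: list[str] = []
    classes: list[str] = []
    for motif_class, count in spec.planted:
        for _ in range(count):
            motifs.append(_motif(motif_class, rng))
            classes.append(motif_class)

    occupied: list[tuple[int, int]] = []  # guard-padded intervals
    truth: list[tuple[str, int, int, str]] = []
    chrom = f"synth_{spec.seed}"
    for motif, motif_class in zip(motifs, classes):
        need = len(motif) + 2 * guard
        if spec.genome_length < need:
            raise ValueError(
                f"cannot place a {motif_class} motif: genome shorter than {need} bp"
            )
        placed = False
        for _ in range(10000):
            start = int(rng.integers(guard, spec.genome_length - len(motif) - guard + 1))
            pad = (start - guard, start + len(motif) + guard)
            if all(pad[0] >= e or pad[1] <= s for s, e in occupied):
                occupied.append(pad)
                genome[start : start + len(motif)] = list(motif)
                genome[pad[0] : start] = rng.choice(["A", "T"], size=guard)
                genome[start + len(motif) : pad[1]] = rng.choice(["A", "T"], size=guard)
                truth.append((chrom, start, start + len(motif), motif_class))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place a {motif_class} motif: genome too full"
            )
    truth.sort(key=lambda t: t[1])
    return SequenceRecord(chrom, "".join(genome)), truth
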