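"""DNA sequence records and small sequence utilities.

The whole toolkit operates on plain DNA strings over the alphabet
``{A, C, G, T, N}``.  :class:`SequenceRecord` is the validated unit that
every scanner and scorer consumes; it normalizes case on construction and
rejects anything that is not DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SequenceRecord", "reverse_complement", "DNA_ALPHABET"]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence.

    Parameters
    ----------
    id : str
        Record label (FASTA header up to the first whitespace).
    seq : str
        DNA over ``{A, C, G, T, N}``; lowercase input is upper-cased.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-DNA character; the
        message names the first offending position (1-based).
    """

    id: str
    seq: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        normalized = self.seq.upper()
        if not normalized:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, base in enumerate(normalized, start=1):
            if base not in DNA_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid character {base!r} at "
                    f"position {pos} (expected A/C/G/T/N)"
                )
        object.__setattr__(self, "seq", normalized)
        object.__setattr__(self, "length", len(normalized))

    def __len__(self) -> int:
        return self.length

    def reverse_complement(self, id_suffix: str = "_rc") -> "SequenceRecord":
        return SequenceRecord(self.id + id_suffix, reverse_complement(self.seq))

    def slice(self, start: int, end: int, id_suffix: str | None = None) -> "SequenceRecord":
        """Sub-record over 0-based half-open coordinates."""
        if not (0 <= start < end <= self.length):
            raise ValueError(f"invalid slice [{start}, {end}) for length {self.length}")
        suffix = id_suffix if id_suffix is not None else f":{start}-{end}"
        return SequenceRecord(self.id + suffix, self.seq[start:end])
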