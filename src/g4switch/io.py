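"""File I/O: FASTA in, BED/TSV out, annotation intervals in.

FASTA reading goes through Biopython; plain and gzip-compressed files are
both accepted.  Interval annotations (for census feature breakdowns) are
read from BED or GFF3 via pandas.  Coordinates are 0-based half-open in
BED and internally; GFF3 input is converted from 1-based closed.
"""

from __future__ import annotations

import gzip
import warnings
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .crun import CRunProfile
from .pqs import PqsHit
from .records import SequenceRecord
from .scoring import BaseScoreVector, round_score

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "hits_to_bed",
    "write_bed",
    "scores_to_tsv",
]


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA.

    Record ids are headers up to the first whitespace; sequences are
    validated and upper-cased.  An empty file yields an empty list with a
    warning; a malformed file raises with the offending line number.
    """
    with _open_text(path) as handle:
        first_line = None
        lines = handle.readlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            first_line = (lineno, line)
            break
    if first_line is None:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    if not first_line[1].startswith(">"):
        raise ValueError(
            f"{path}: malformed FASTA at line {first_line[0]}: expected '>' header"
        )
    records = []
    for rec in SeqIO.parse(StringIO("".join(lines)), "fasta"):
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_annotation(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED or GFF3 intervals as (chrom, start, end, feature) tuples.

    BED features come from the name column (4th); GFF3 features from the
    type column.  All output coordinates are 0-based half-open.
    """
    path = Path(path)
    suffix = path.suffixes[0].lower() if path.suffixes else ""
    if suffix in (".gff", ".gff3", ".gtf"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS
        )
        return [
            (str(row.seqid), int(row.start) - 1, int(row.end), str(row.type))
            for row in df.itertuples()
        ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = df[3] if df.shape[1] >= 4 else pd.Series(["region"] * len(df))
    return [
        (str(c), int(s), int(e), str(n))
        for c, s, e, n in zip(df[0], df[1], df[2], names)
    ]


def hits_to_bed(hits: Iterable[PqsHit], scores: Iterable[float] | None = None) -> pd.DataFrame:
    """BED6 table for PQS hits: name = motif class, score = mean x 100."""
    hits = list(hits)
    if scores is None:
        score_col = [0] * len(hits)
    else:
        score_col = [int(round_score(s * 100, 0)) for s in scores]
    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [h.motif_class for h in hits],
            "score": score_col,
            "strand": [h.strand for h in hits],
        }
    )


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def scores_to_tsv(
    vectors: Iterable[BaseScoreVector],
    profiles: Iterable[CRunProfile] | None = None,
) -> pd.DataFrame:
    """Scoring table: id, length, scheme, score (+ C-run columns if given)."""
    vectors = list(vectors)
    df = pd.DataFrame(
        {
            "id": [v.record.id for v in vectors],
            "length": [v.record.length for v in vectors],
            "scheme": [v.scheme.label() for v in vectors],
            "score": [v.rounded for v in vectors],
        }
    )
    if profiles is not None:
        profiles = list(profiles)
        df["total_c"] = [p.total_c for p in profiles]
        df["n_stat"] = [p.n_stat_rounded for p in profiles]
        df["ccc_runs"] = [p.ccc_runs for p in profiles]
    return df
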