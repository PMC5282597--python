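"""Input/output for the standard formats the pipeline touches.

Sequences come in as FASTA, intervals as BED (0-based half-open, the
internal convention throughout), per-base conservation scores as bedGraph or
fixed-step wiggle.  Also implements the promoter-signal orientation rule:
the gene end with the higher aggregate H3K4me3-style signal is declared the
putative transcription start site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._alphabet import encode

VALID_LABELS = ("positive", "negative", "unlabelled")


@dataclass
class SequenceRecord:
    """One DNA sequence with an optional group label."""

    id: str
    sequence: str
    group_label: str = "unlabelled"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.group_label not in VALID_LABELS:
            raise ValueError(
                f"record {self.id!r}: group_label must be one of {VALID_LABELS}"
            )
        self.sequence = self.sequence.upper()
        try:
            encode(self.sequence)
        except ValueError as exc:
            raise ValueError(f"record {self.id!r}: {exc}") from None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally scored."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class TssCall(enum.Enum):
    FIRST_END_IS_TSS = "first_end_is_tss"
    SECOND_END_IS_TSS = "second_end_is_tss"
    AMBIGUOUS = "ambiguous"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (order preserved, upper-cased).

    Characters outside {A,C,G,T,N}, empty sequences and duplicate ids raise
    ValueError naming the record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sequence id -> group label."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected id<TAB>label")
            if parts[1] not in VALID_LABELS:
                raise ValueError(f"{path}:{ln}: unknown label {parts[1]!r}")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.group_label}\n")


def apply_labels(records: Sequence[SequenceRecord],
                 labels: dict[str, str]) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, r.sequence, labels.get(r.id, r.group_label))
        for r in records
    ]


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file; input order preserved (sorting is the
    caller's concern)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{ln}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 else None
            out.append(GenomicInterval(chrom, start, end, score, name, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED (3 to 6 columns depending on populated fields)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
                cols.append(
                    format(iv.score, "g") if iv.score is not None else "0"
                )
                if iv.strand is not None:
                    cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


class ScoreTrack:
    """Per-base score track; positions without a record score 0.

    Stored as sorted, non-overlapping (start, end, score) runs per chromosome
    (or per sequence id, when scoring pipeline-internal coordinates).
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._pending: dict[str, list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, score: float) -> None:
        if start >= end:
            raise ValueError(f"invalid run {chrom}:{start}-{end}")
        self._pending.setdefault(chrom, []).append((start, end, float(score)))
        self._runs.pop(chrom, None)

    def _compiled(self, chrom: str):
        if chrom not in self._runs:
            runs = sorted(self._pending.get(chrom, []))
            for (s0, e0, _), (s1, e1, _) in zip(runs, runs[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping score records on {chrom}: "
                        f"[{s0},{e0}) and [{s1},{e1})"
                    )
            starts = np.array([r[0] for r in runs], dtype=np.int64)
            ends = np.array([r[1] for r in runs], dtype=np.int64)
            scores = np.array([r[2] for r in runs], dtype=float)
            self._runs[chrom] = (starts, ends, scores)
        return self._runs[chrom]

    def value(self, chrom: str, pos: int) -> float:
        starts, ends, scores = self._compiled(chrom)
        if starts.size == 0:
            return 0.0
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(scores[i])
        return 0.0

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered bases are 0."""
        starts, ends, scores = self._compiled(chrom)
        out = np.zeros(end - start, dtype=float)
        if starts.size == 0:
            return out
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start:b - start] = scores[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base score over [start, end), counting uncovered as 0."""
        return float(self.values(chrom, start, end).mean())

    def chroms(self) -> list[str]:
        return sorted(self._pending)


def read_score_track(path: str | Path, dialect: str = "bedgraph") -> ScoreTrack:
    """Read a bedGraph or fixed-step wiggle file into a ScoreTrack.

    Overlapping records raise ValueError.  Fixed-step wiggle uses the UCSC
    1-based start convention, converted internally to 0-based.
    """
    track = ScoreTrack()
    if dialect == "bedgraph":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: need 4 bedGraph columns")
                track.add(parts[0], int(parts[1]), int(parts[2]),
                          float(parts[3]))
    elif dialect in ("wig", "fixedstep", "fixed-step wig"):
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(
                        kv.split("=") for kv in line.split()[1:]
                    )
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    continue
                if line.startswith("variableStep"):
                    raise ValueError(f"{path}:{ln}: variableStep unsupported")
                if chrom is None:
                    raise ValueError(f"{path}:{ln}: data before fixedStep")
                track.add(chrom, pos, pos + span, float(line))
                pos += step
    else:
        raise ValueError(f"unknown score-track dialect {dialect!r}")
    # force overlap validation now so errors carry the file name
    for chrom in track.chroms():
        try:
            track._compiled(chrom)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return track


def infer_tss_orientation(end5_signal: float, end3_signal: float) -> TssCall:
    """Declare the gene end with the higher promoter-mark signal the TSS.

    Equal signals return AMBIGUOUS; the caller keeps the annotated
    orientation in that case.
    """
    if end5_signal < 0 or end3_signal < 0:
        raise ValueError("signal intensities must be nonnegative")
    if end5_signal > end3_signal:
        return TssCall.FIRST_END_IS_TSS
    if end3_signal > end5_signal:
        return TssCall.SECOND_END_IS_TSS
    return TssCall.AMBIGUOUS
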