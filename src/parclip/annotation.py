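"""Transcriptome data model and annotation operations.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open, matching BED/bedGraph. A transcript
occupies the genomic span ``[min(tss, pa), max(tss, pa))``. On the plus
strand ``tss < pa``: the TSS is the first transcribed base and ``pa`` is the
first base after the transcript in the direction of transcription. On the
minus strand ``tss > pa``: transcription runs right-to-left, the first
transcribed base is ``tss - 1`` (``tss`` is the exclusive span bound) and
``pa`` is the span start. Transcript-oriented index ``i`` (0 at the TSS)
therefore maps to genomic position ``tss + i`` on plus and ``tss - 1 - i``
on minus; index ``length`` is the first base past the cleavage site on
either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-")
TRANSCRIPT_CLASSES = ("mRNA", "CUT", "snoRNA")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def _normalize_strand(s: str) -> str:
    s = s.strip()
    if s in ("+",):
        return "+"
    if s in ("-", "−"):  # accept the unicode minus sign
        return "-"
    raise AnnotationError(f"invalid strand {s!r}; expected '+' or '-'")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (nt)."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) == 0:
            raise AnnotationError("GenomeLayout needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise AnnotationError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class Transcript:
    """One annotated transcription unit.

    ``introns`` are genomic half-open ``(start, end)`` intervals, strictly
    inside the transcript span, stored sorted by start.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    pa: int
    klass: str = "mRNA"
    introns: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        if self.klass not in TRANSCRIPT_CLASSES:
            raise AnnotationError(
                f"transcript {self.id!r}: unknown class {self.klass!r}"
            )
        if self.strand == "+" and not self.tss < self.pa:
            raise AnnotationError(
                f"transcript {self.id!r}: plus strand requires tss < pa "
                f"(got tss={self.tss}, pa={self.pa})"
            )
        if self.strand == "-" and not self.tss > self.pa:
            raise AnnotationError(
                f"transcript {self.id!r}: minus strand requires tss > pa "
                f"(got tss={self.tss}, pa={self.pa})"
            )
        if min(self.tss, self.pa) < 0:
            raise AnnotationError(f"transcript {self.id!r}: negative coordinate")
        introns = tuple(sorted((int(a), int(b)) for a, b in self.introns))
        object.__setattr__(self, "introns", introns)
        for a, b in introns:
            if not (self.start <= a < b <= self.end):
                raise AnnotationError(
                    f"transcript {self.id!r}: intron ({a},{b}) outside span "
                    f"[{self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return abs(self.pa - self.tss)

    @property
    def start(self) -> int:
        """Genomic span start (inclusive)."""
        return min(self.tss, self.pa)

    @property
    def end(self) -> int:
        """Genomic span end (exclusive)."""
        return max(self.tss, self.pa)

    def position(self, i: int | np.ndarray) -> int | np.ndarray:
        """Genomic position of transcript-oriented offset ``i`` from the TSS.

        ``i`` may be negative (upstream) or >= length (past the pA site).
        """
        if self.strand == "+":
            return self.tss + i
        return self.tss - 1 - i

    def intron_five_prime_index(self, intron: tuple[int, int]) -> int:
        """Transcript-oriented index of the first intronic base (the 5'SS)."""
        a, b = intron
        if self.strand == "+":
            return a - self.tss
        return self.tss - b


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TSV_HEADER = ["chrom", "start", "end", "id", "class", "strand", "introns"]


def _parse_introns_field(txt: str, line_no: int) -> tuple[tuple[int, int], ...]:
    txt = txt.strip()
    if not txt or txt == ".":
        return ()
    out = []
    for piece in txt.split(","):
        try:
            a, b = piece.split("-")
            out.append((int(a), int(b)))
        except ValueError:
            raise AnnotationError(
                f"line {line_no}: malformed intron field {piece!r}"
            ) from None
    return tuple(out)


def read_transcripts(path: str | Path) -> list[Transcript]:
    """Read transcripts from the 6/7-column TSV or from BED12.

    The native format is whitespace-separated columns
    ``chrom start end id class strand [introns]`` where introns are written
    as ``start-end,start-end`` in genomic coordinates ('.' or empty = none).
    BED12 rows (12 columns, class carried as an ``id|class`` name suffix,
    blocks = exons) are also accepted; introns are the gaps between blocks.
    """
    path = Path(path)
    out: list[Transcript] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if f[0] == "chrom" and line_no == 1:  # optional header
                continue
            if len(f) >= 12:
                out.append(_transcript_from_bed12(f, line_no))
                continue
            if len(f) < 6:
                raise AnnotationError(
                    f"line {line_no}: expected >=6 columns, got {len(f)}"
                )
            chrom, start_s, end_s, tid, klass, strand = f[:6]
            if "|" in tid:
                tid, klass = tid.rsplit("|", 1)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"line {line_no}: non-integer coordinates"
                ) from None
            if start >= end:
                raise AnnotationError(
                    f"line {line_no}: start {start} >= end {end}"
                )
            introns = _parse_introns_field(f[6], line_no) if len(f) >= 7 else ()
            strand = _normalize_strand(strand)
            tss, pa = (start, end) if strand == "+" else (end, start)
            out.append(
                Transcript(id=tid, chrom=chrom, strand=strand, tss=tss, pa=pa,
                           klass=klass, introns=introns)
            )
    return out


def _transcript_from_bed12(f: Sequence[str], line_no: int) -> Transcript:
    chrom, start_s, end_s, name = f[0], f[1], f[2], f[3]
    strand = _normalize_strand(f[5])
    start, end = int(start_s), int(end_s)
    if start >= end:
        raise AnnotationError(f"line {line_no}: start {start} >= end {end}")
    if "|" in name:
        tid, klass = name.rsplit("|", 1)
    else:
        tid, klass = name, "mRNA"
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(f"line {line_no}: BED12 block count mismatch")
    introns = []
    for i in range(n_blocks - 1):
        a = start + starts[i] + sizes[i]
        b = start + starts[i + 1]
        if a < b:
            introns.append((a, b))
    tss, pa = (start, end) if strand == "+" else (end, start)
    return Transcript(id=tid, chrom=chrom, strand=strand, tss=tss, pa=pa,
                      klass=klass, introns=tuple(introns))


def write_transcripts(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write the 7-column TSV that :func:`read_transcripts` reads back."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            introns = ",".join(f"{a}-{b}" for a, b in t.introns) or "."
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t{t.klass}\t"
                f"{t.strand}\t{introns}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and promoter selection
# ---------------------------------------------------------------------------

def filter_transcripts(
    transcripts: Iterable[Transcript],
    min_len: int,
    max_len: int,
    min_gap: int = 150,
    klass: str | None = None,
) -> list[Transcript]:
    """Select transcripts by length and same-strand isolation.

    A transcript is kept iff ``min_len <= length <= max_len`` and the gap
    between its genomic span and the span of every other transcript on the
    same chromosome and strand (any class) is at least ``min_gap`` nt.
    Overlapping same-strand neighbors have negative gap and always fail a
    positive ``min_gap``. Result order follows genomic position.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    ts = list(transcripts)
    by_cs: dict[tuple[str, str], list[Transcript]] = {}
    for t in ts:
        by_cs.setdefault((t.chrom, t.strand), []).append(t)

    kept: list[Transcript] = []
    for group in by_cs.values():
        group.sort(key=lambda t: (t.start, t.end, t.id))
        for i, t in enumerate(group):
            if not (min_len <= t.length <= max_len):
                continue
            if klass is not None and t.klass != klass:
                continue
            gap_ok = True
            for j, other in enumerate(group):
                if j == i:
                    continue
                gap = max(other.start - t.end, t.start - other.end)
                if gap < min_gap:
                    gap_ok = False
                    break
            if gap_ok:
                kept.append(t)
    kept.sort(key=lambda t: (t.chrom, t.start, t.id))
    return kept


def _downstream_window(t: Transcript, length: int) -> tuple[int, int]:
    """Genomic half-open span of [TSS, TSS+length) in transcription direction."""
    if t.strand == "+":
        return t.tss, t.tss + length
    return t.tss - length, t.tss


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def select_bidirectional_promoters(
    transcripts: Iterable[Transcript],
    max_tss_distance: int = 350,
    clear_window: int = 400,
) -> list[tuple[Transcript, Transcript]]:
    """Find divergent mRNA/CUT pairs sharing a bidirectional promoter.

    A pair qualifies when the mRNA and CUT sit on opposite strands in
    divergent orientation, their TSS distance is strictly smaller than
    ``max_tss_distance``, and neither member's window from its TSS to
    ``clear_window`` nt downstream (in transcription direction) overlaps any
    other same-strand transcript.
    """
    ts = list(transcripts)
    pairs: list[tuple[Transcript, Transcript]] = []
    mrnas = [t for t in ts if t.klass == "mRNA"]
    cuts = [t for t in ts if t.klass == "CUT"]
    for m in mrnas:
        for c in cuts:
            if c.chrom != m.chrom or c.strand == m.strand:
                continue
            # divergent: the CUT transcribes away from the mRNA
            if m.strand == "+" and not c.tss <= m.tss:
                continue
            if m.strand == "-" and not c.tss >= m.tss:
                continue
            if abs(m.tss - c.tss) >= max_tss_distance:
                continue
            clear = True
            for member in (m, c):
                win = _downstream_window(member, clear_window)
                for other in ts:
                    if other is m or other is c:
                        continue
                    if other.chrom == member.chrom and other.strand == member.strand \
                            and _overlaps(win, (other.start, other.end)):
                        clear = False
                        break
                if not clear:
                    break
            if clear:
                pairs.append((m, c))
    pairs.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].id))
    return pairs


def to_transcript_coords(signal, t: Transcript) -> np.ndarray:
    """Extract a transcript-oriented vector (index 0 = TSS) from a signal.

    ``signal`` is either a dict ``(chrom, strand) -> per-base array`` or an
    object exposing ``.dense(chrom, strand)`` (a :class:`CoverageTrack`).
    Raises if the transcript span extends past the chromosome.
    """
    arr = signal.dense(t.chrom, t.strand) if hasattr(signal, "dense") \
        else signal[(t.chrom, t.strand)]
    if t.start < 0 or t.end > len(arr):
        raise AnnotationError(
            f"transcript {t.id!r} span [{t.start},{t.end}) exceeds chromosome "
            f"length {len(arr)}"
        )
    body = np.asarray(arr[t.start:t.end], dtype=float)
    return body if t.strand == "+" else body[::-1]
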