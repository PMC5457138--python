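"""Strand-specific coverage tracks and per-U-site transition tables.

Coverage is held densely, one non-negative float vector per (chromosome,
strand), and serialized as bedGraph with one file per strand
(``.plus.bedgraph`` / ``.minus.bedgraph``). The U-site table is a pandas
DataFrame with columns ``chrom pos strand coverage transitions``
(0-based positions), serialized as TSV with that header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationError, GenomeLayout, STRANDS

USITE_COLUMNS = ["chrom", "pos", "strand", "coverage", "transitions"]

_STRAND_SUFFIX = {"+": ".plus.bedgraph", "-": ".minus.bedgraph"}


class CoverageTrack:
    """Per-base, strand-specific, non-negative coverage over a genome."""

    def __init__(self, data: Mapping[tuple[str, str], np.ndarray]):
        clean: dict[tuple[str, str], np.ndarray] = {}
        for (chrom, strand), values in data.items():
            if strand not in STRANDS:
                raise AnnotationError(
                    f"coverage track for {chrom!r} has invalid strand {strand!r}; "
                    "unstranded input is rejected"
                )
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise AnnotationError("coverage vectors must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise AnnotationError(f"non-finite coverage on {chrom} {strand}")
            if np.any(arr < 0):
                raise AnnotationError(f"negative coverage on {chrom} {strand}")
            clean[(chrom, strand)] = arr
        self._data = clean

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "CoverageTrack":
        return cls({
            (chrom, strand): np.zeros(length)
            for chrom, length in layout.chrom_lengths.items()
            for strand in STRANDS
        })

    def keys(self):
        return self._data.keys()

    def dense(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._data:
            raise AnnotationError(f"no coverage for chromosome {chrom!r} strand {strand!r}")
        return self._data[key]

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.dense(*key)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._data

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({k: v * factor for k, v in self._data.items()})

    def total(self) -> float:
        return float(sum(v.sum() for v in self._data.values()))


def write_bedgraph(track: CoverageTrack, prefix: str | Path) -> list[Path]:
    """Write one bedGraph per strand, run-length collapsing equal values.

    Zero runs are omitted, as is conventional for sparse bedGraph.
    """
    prefix = Path(prefix)
    written = []
    for strand, suffix in _STRAND_SUFFIX.items():
        path = prefix.parent / (prefix.name + suffix)
        with open(path, "w") as fh:
            for (chrom, s), values in sorted(track._data.items()):
                if s != strand:
                    continue
                for start, end, value in _runs(values):
                    if value != 0:
                        fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
        written.append(path)
    return written


def _runs(values: np.ndarray):
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    for a, b in zip(starts, ends):
        yield int(a), int(b), float(values[a])


def read_bedgraph(prefix: str | Path, layout: GenomeLayout) -> CoverageTrack:
    """Read the strand pair written by :func:`write_bedgraph`."""
    prefix = Path(prefix)
    data = {
        (chrom, strand): np.zeros(length)
        for chrom, length in layout.chrom_lengths.items()
        for strand in STRANDS
    }
    for strand, suffix in _STRAND_SUFFIX.items():
        path = prefix.parent / (prefix.name + suffix)
        if not path.exists():
            raise AnnotationError(
                f"missing strand file {path}; strand-specific tracks are mandatory"
            )
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                f = line.split()
                if len(f) != 4:
                    raise AnnotationError(f"{path}:{line_no}: expected 4 columns")
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
                if chrom not in layout.chrom_lengths:
                    raise AnnotationError(f"{path}:{line_no}: unknown chromosome {chrom!r}")
                if not 0 <= start < end <= layout.length_of(chrom):
                    raise AnnotationError(f"{path}:{line_no}: interval out of bounds")
                data[(chrom, strand)][start:end] = value
    return CoverageTrack(data)


# ---------------------------------------------------------------------------
# U-site tables
# ---------------------------------------------------------------------------

def validate_usites(df: pd.DataFrame) -> pd.DataFrame:
    """Check U-site table invariants; returns the frame (sorted)."""
    missing = [c for c in USITE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"U-site table missing columns {missing}")
    df = df[USITE_COLUMNS].copy()
    if np.any(df["transitions"] > df["coverage"]):
        raise AnnotationError("U-site table has transitions > coverage")
    if np.any(df["coverage"] < 0):
        raise AnnotationError("U-site table has negative coverage")
    if not set(df["strand"]).issubset(STRANDS):
        raise AnnotationError("U-site strand values must be '+' or '-'")
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        raise AnnotationError("duplicate U-site positions per (chrom, strand)")
    return df.sort_values(["chrom", "strand", "pos"], ignore_index=True)


def read_usites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return validate_usites(df)


def write_usites(df: pd.DataFrame, path: str | Path) -> None:
    validate_usites(df).to_csv(path, sep="\t", index=False)


def usites_to_dense(
    df: pd.DataFrame,
    layout: GenomeLayout,
    column: str = "transitions",
) -> dict[tuple[str, str], np.ndarray]:
    """Scatter a U-site column into NaN-initialized per-base vectors.

    Positions without a U site stay NaN so downstream averaging can
    distinguish 'no site' from 'zero signal'.
    """
    dense = {
        (chrom, strand): np.full(length, np.nan)
        for chrom, length in layout.chrom_lengths.items()
        for strand in STRANDS
    }
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
        dense[(chrom, strand)][grp["pos"].to_numpy()] = grp[column].to_numpy(float)
    return dense
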