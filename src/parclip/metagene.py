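"""Anchored averaging, smoothing, length scaling and heat-map binning.

Transcript signals are aligned at an anchor (TSS, pA site, or the 5'
splice site of introns) or linearly rescaled to a common length, averaged
position-wise over transcripts ignoring missing values, smoothed with a
sliding window, and min-max rescaled — either per factor or jointly over
the profiles being compared. Missing (masked) positions are excluded from
every mean, never imputed as zero: zeros would fabricate occupancy dips
at masked U sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import Transcript

log = logging.getLogger(__name__)

ANCHORS = ("tss", "pa", "ss5")


@dataclass(frozen=True)
class MetaProfile:
    anchor: str
    values: np.ndarray        # averaged (smoothed, rescaled) signal
    n_transcripts: np.ndarray  # contributors per position
    window: tuple[int, int] | None = None  # (upstream, downstream) or None if scaled


@dataclass(frozen=True)
class HeatMatrix:
    matrix: np.ndarray
    bin_x: int
    bin_y: int
    saturation_quantile: float


def smooth(values: np.ndarray, window: int = 61) -> np.ndarray:
    """Sliding-window mean over defined values; the default 61-nt window
    reaches 30 nt to either side. Edges use the truncated window (the mean
    over however much of the window lies inside the vector)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    if window == 1:
        return v.copy()
    finite = np.isfinite(v)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(np.where(finite, v, 0.0))))
    ccnt = np.concatenate(([0.0], np.cumsum(finite.astype(float))))
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, v.size)
    sums = csum[hi] - csum[lo]
    counts = ccnt[hi] - ccnt[lo]
    out = np.full_like(v, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def _anchor_index(t: Transcript, anchor: str) -> list[int]:
    """Transcript-oriented indices of the anchor(s); 'ss5' yields one per
    intron."""
    if anchor == "tss":
        return [0]
    if anchor == "pa":
        return [t.length]
    if anchor == "ss5":
        return [t.intron_five_prime_index(i) for i in t.introns]
    raise ValueError(f"anchor must be one of {ANCHORS}")


def anchor_matrix(
    signal,
    transcripts: list[Transcript],
    anchor: str = "tss",
    up: int = 150,
    down: int = 400,
    clip_to_transcript: bool = False,
) -> np.ndarray:
    """Rows = anchors (one per transcript, or per intron for 'ss5'),
    columns = offsets -up .. down-1 in transcription direction.

    Positions off the chromosome are NaN; with ``clip_to_transcript``,
    positions outside the transcript body are NaN as well.
    """
    offsets = np.arange(-up, down)
    rows = []
    for t in transcripts:
        arr = signal.dense(t.chrom, t.strand) if hasattr(signal, "dense") \
            else signal[(t.chrom, t.strand)]
        for a in _anchor_index(t, anchor):
            idx = a + offsets
            gpos = np.asarray(t.position(idx))
            row = np.full(len(offsets), np.nan)
            ok = (gpos >= 0) & (gpos < len(arr))
            if clip_to_transcript:
                ok &= (idx >= 0) & (idx < t.length)
            row[ok] = np.asarray(arr, dtype=float)[gpos[ok]]
            rows.append(row)
    if not rows:
        raise ValueError("no eligible transcripts for anchoring")
    return np.vstack(rows)


def length_scale_matrix(
    signal,
    transcripts: list[Transcript],
    target_len: int | None = None,
) -> np.ndarray:
    """Resample each TSS->pA vector onto ``target_len`` points (default:
    the median transcript length) by linear interpolation between its
    defined values; endpoints map to endpoints. All-missing transcripts
    yield all-NaN rows."""
    from .annotation import to_transcript_coords

    if not transcripts:
        raise ValueError("no transcripts to scale")
    if any(t.length < 2 for t in transcripts):
        raise ValueError("length scaling requires transcript length >= 2")
    if target_len is None:
        target_len = int(np.median([t.length for t in transcripts]))
    target_len = max(int(target_len), 2)
    grid = np.linspace(0.0, 1.0, target_len)
    rows = []
    for t in transcripts:
        v = to_transcript_coords(signal, t)
        finite = np.isfinite(v)
        if finite.sum() == 0:
            rows.append(np.full(target_len, np.nan))
            continue
        xp = np.flatnonzero(finite) / (t.length - 1)
        rows.append(np.interp(grid, xp, v[finite]))
    return np.vstack(rows)


def average_and_rescale(
    matrices: np.ndarray | dict[str, np.ndarray],
    smooth_window: int = 61,
    smooth_first: bool = False,
    anchor: str = "tss",
    window: tuple[int, int] | None = None,
) -> MetaProfile | dict[str, MetaProfile]:
    """Column-wise mean over rows (ignoring missing values), smoothing,
    then min-max rescaling to [0, 1].

    A single matrix gives one per-factor profile. A dict of matrices (e.g.
    one per transcript class) is rescaled *jointly*: the shared minimum
    maps to 0 and the shared maximum to 1, preserving relative signal
    strength between the profiles being compared. By default smoothing
    follows averaging; ``smooth_first`` smooths each row before the mean.
    A constant profile rescales degenerately and maps to all zeros.
    """
    single = not isinstance(matrices, dict)
    named = {"profile": matrices} if single else matrices

    averaged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, m in named.items():
        m = np.asarray(m, dtype=float)
        if m.size == 0:
            raise ValueError(f"matrix {name!r} is empty")
        if smooth_first:
            m = np.vstack([smooth(row, smooth_window) for row in m])
        finite = np.isfinite(m)
        n = finite.sum(axis=0)
        sums = np.where(finite, m, 0.0).sum(axis=0)
        mean = np.full(m.shape[1], np.nan)
        np.divide(sums, n, out=mean, where=n > 0)
        if not smooth_first:
            mean = smooth(mean, smooth_window)
        averaged[name] = (mean, n)

    pool = np.concatenate([v for v, _ in averaged.values()])
    pool = pool[np.isfinite(pool)]
    lo, hi = (float(pool.min()), float(pool.max())) if pool.size else (0.0, 0.0)
    out: dict[str, MetaProfile] = {}
    for name, (mean, n) in averaged.items():
        if hi == lo:
            log.warning("profile %r is constant; rescaled to all zeros", name)
            scaled = np.where(np.isfinite(mean), 0.0, np.nan)
        else:
            scaled = (mean - lo) / (hi - lo)
        out[name] = MetaProfile(anchor=anchor, values=scaled, n_transcripts=n,
                                window=window)
    return out["profile"] if single else out


def heat_bin(
    matrix: np.ndarray,
    bin_x: int = 20,
    bin_y: int = 10,
    q: float = 0.97,
) -> HeatMatrix:
    """Bin a (transcripts x positions) matrix — rows pre-sorted by
    transcript length, aligned at the 5' end — into cells of ``bin_x``
    positions by ``bin_y`` transcripts (cell = mean of its defined
    values), then scale the ``q`` quantile of the cell values to 1 and
    clip above."""
    if bin_x < 1 or bin_y < 1:
        raise ValueError("bin sizes must be >= 1")
    m = np.asarray(matrix, dtype=float)
    n_rows = -(-m.shape[0] // bin_y)
    n_cols = -(-m.shape[1] // bin_x)
    cells = np.full((n_rows, n_cols), np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            block = m[r * bin_y:(r + 1) * bin_y, c * bin_x:(c + 1) * bin_x]
            if np.any(np.isfinite(block)):
                cells[r, c] = np.nanmean(block)
    defined = cells[np.isfinite(cells)]
    if defined.size:
        ref = float(np.quantile(defined, q))
        if ref > 0:
            cells = np.clip(cells / ref, 0.0, 1.0)
    return HeatMatrix(matrix=cells, bin_x=bin_x, bin_y=bin_y, saturation_quantile=q)
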