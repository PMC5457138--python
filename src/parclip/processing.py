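"""Pre-mRNA processing index (PI).

Factor read counts downstream of a pA site can only come from uncleaved
pre-mRNA, while counts upstream mix pre-mRNA and cleaved, mature mRNA.
Averaging read counts in windows on either side of the pA site
(upstream pA-75..pA-25, downstream pA+25..pA+75, both inclusive and in
transcript orientation) and pooling over an annotation A gives the log2
odds of binding uncleaved versus cleaved RNA:

    PI = log2( N_down / max(1, N_up - N_down) )

Positive PI indicates preferential pre-mRNA binding. The inputs are raw
read-coverage tracks, not crosslink-site occupancies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .annotation import Transcript
from .tracks import CoverageTrack

log = logging.getLogger(__name__)

UP_WINDOW = (-75, -25)   # offsets from the pA site, inclusive
DOWN_WINDOW = (25, 75)


@dataclass(frozen=True)
class WindowMeans:
    transcript_id: str
    n_up: float
    n_down: float


@dataclass(frozen=True)
class PIResult:
    na_up: float
    na_down: float
    pi: float  # -inf sentinel when na_down == 0
    n_transcripts: int


def _window_mean(readcounts: CoverageTrack, t: Transcript,
                 lo: int, hi: int, literal_50: bool) -> float:
    idx = np.arange(t.length + lo, t.length + hi + 1)  # offsets from pA
    gpos = np.asarray(t.position(idx))
    arr = readcounts.dense(t.chrom, t.strand)
    if gpos.min() < 0 or gpos.max() >= len(arr):
        raise ValueError(f"window off chromosome for transcript {t.id!r}")
    total = float(arr[gpos].sum())
    return total / 50.0 if literal_50 else total / len(idx)


def window_means(readcounts: CoverageTrack, t: Transcript,
                 literal_50: bool = False) -> WindowMeans:
    """Mean read counts over the 51-nt windows flanking the pA site.

    With ``literal_50`` the window sums are divided by the constant 50
    instead of the number of included positions; the PI is insensitive to
    this choice since both windows share the divisor.
    """
    return WindowMeans(
        transcript_id=t.id,
        n_up=_window_mean(readcounts, t, *UP_WINDOW, literal_50),
        n_down=_window_mean(readcounts, t, *DOWN_WINDOW, literal_50),
    )


def processing_index(
    readcounts: CoverageTrack,
    transcripts: list[Transcript],
    literal_50: bool = False,
    pseudocount: float = 0.0,
) -> PIResult:
    """Annotation-level PI over all usable transcripts.

    Transcripts whose windows fall off the chromosome are skipped with a
    warning. ``pseudocount`` (off by default) is added to both window
    averages for plotting convenience; N_down = 0 otherwise yields the
    -inf sentinel, never a silent floor.
    """
    per_t: list[WindowMeans] = []
    skipped = 0
    for t in transcripts:
        try:
            per_t.append(window_means(readcounts, t, literal_50))
        except ValueError:
            skipped += 1
    if skipped:
        log.warning("skipped %d transcripts with off-chromosome pA windows", skipped)
    if not per_t:
        raise ValueError("no usable transcripts for the processing index")
    na_up = float(np.mean([w.n_up for w in per_t])) + pseudocount
    na_down = float(np.mean([w.n_down for w in per_t])) + pseudocount
    if na_down == 0.0:
        log.warning("N_down = 0: PI is -inf (factor shows no post-pA signal)")
        pi = -math.inf
    else:
        pi = math.log2(na_down / max(1.0, na_up - na_down))
    return PIResult(na_up=na_up, na_down=na_down, pi=pi, n_transcripts=len(per_t))
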