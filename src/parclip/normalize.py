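"""Occupancy normalization of raw T-to-C transition counts.

The transition count at a U site is proportional to factor occupancy times
the concentration of RNA covering the site. Dividing by a per-position
estimate of that concentration — RNA-Seq coverage, or Pol II PAR-CLIP
coverage for nascent RNA — yields relative occupancy. Sites whose
denominator falls below ``min_denominator`` are masked (excluded), never
clamped or zero-filled, so they cannot fabricate signal downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeLayout, Transcript, to_transcript_coords
from .tracks import CoverageTrack, usites_to_dense, validate_usites

log = logging.getLogger(__name__)

DENOMINATOR_KINDS = ("raw", "rnaseq", "polII")


@dataclass(frozen=True)
class OccupancyTrack:
    """Sparse occupancy defined only at (unmasked) U-site positions."""

    table: pd.DataFrame  # chrom pos strand occupancy
    denominator_kind: str
    min_denominator: float
    n_masked: int = 0

    def values(self) -> np.ndarray:
        return self.table["occupancy"].to_numpy(float)

    def to_dense(self, layout: GenomeLayout) -> dict[tuple[str, str], np.ndarray]:
        """NaN-filled per-base vectors; NaN marks 'no U site / masked'."""
        return usites_to_dense(
            self.table.rename(columns={"occupancy": "transitions"})
            .assign(coverage=np.inf),
            layout, column="transitions",
        )


def occupancy(
    usites: pd.DataFrame,
    denom: CoverageTrack | None = None,
    kind: str = "raw",
    min_denominator: float = 1.0,
) -> OccupancyTrack:
    """occ(pos) = transitions(pos) / denominator(pos); ``raw`` keeps the
    transition counts unchanged."""
    if kind not in DENOMINATOR_KINDS:
        raise ValueError(f"kind must be one of {DENOMINATOR_KINDS}")
    usites = validate_usites(usites)
    out = usites[["chrom", "pos", "strand"]].copy()
    if kind == "raw":
        out["occupancy"] = usites["transitions"].to_numpy(float)
        return OccupancyTrack(out, "raw", min_denominator, n_masked=0)
    if denom is None:
        raise ValueError(f"kind={kind!r} requires a denominator track")

    d = np.full(len(usites), np.nan)
    for (chrom, strand), grp in usites.groupby(["chrom", "strand"], sort=False):
        if (chrom, strand) not in denom:
            continue
        arr = denom.dense(chrom, strand)
        pos = grp["pos"].to_numpy()
        ok = pos < len(arr)
        d[grp.index[ok]] = arr[pos[ok]]
    defined = np.isfinite(d) & (d >= min_denominator)
    n_masked = int((~defined).sum())
    if n_masked:
        log.info("masked %d / %d U sites (denominator < %g or missing)",
                 n_masked, len(usites), min_denominator)
    out = out.loc[defined].copy()
    out["occupancy"] = usites.loc[defined, "transitions"].to_numpy(float) / d[defined]
    return OccupancyTrack(out.reset_index(drop=True), kind, min_denominator,
                          n_masked=n_masked)


def compare_normalizations(
    usites: pd.DataFrame,
    rnaseq: CoverageTrack,
    polII: CoverageTrack,
    transcripts: list[Transcript],
    layout: GenomeLayout,
    min_denominator: float = 1.0,
) -> pd.DataFrame:
    """Transcript-averaged occupancy per (scheme, transcript class).

    For each normalization scheme the occupancy is averaged within each
    transcript (defined U sites only), then unweighted-averaged over the
    transcripts of each class. Empty classes are omitted with a warning.
    """
    schemes = {
        "raw": occupancy(usites, None, "raw"),
        "rnaseq": occupancy(usites, rnaseq, "rnaseq", min_denominator),
        "polII": occupancy(usites, polII, "polII", min_denominator),
    }
    rows = []
    classes = sorted({t.klass for t in transcripts})
    for scheme, occ in schemes.items():
        dense = occ.to_dense(layout)
        for klass in classes:
            members = [t for t in transcripts if t.klass == klass]
            per_t = []
            for t in members:
                v = to_transcript_coords(dense, t)
                if np.any(np.isfinite(v)):
                    per_t.append(float(np.nanmean(v)))
            if not per_t:
                log.warning("class %s: no transcript with defined %s occupancy",
                            klass, scheme)
                continue
            rows.append({"scheme": scheme, "klass": klass,
                         "mean_occupancy": float(np.mean(per_t)),
                         "n_transcripts": len(per_t)})
    return pd.DataFrame(rows)
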