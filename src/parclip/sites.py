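"""Crosslink-site calling and factor enrichment classification.

The null hypothesis at each U site is that its T-to-C transitions arise
from a uniform background mismatch rate p0 (sequencing errors, SNPs)
rather than crosslinking. Sites are tested with the exact one-sided
binomial upper tail P(K >= k | n, p0) and kept at a raw p-value cutoff
(default 0.005) and a minimum coverage (default 2 reads). No
multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Transcript
from .tracks import validate_usites

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrosslinkSiteSet:
    """Called sites plus the parameters that produced them."""

    sites: pd.DataFrame  # chrom pos strand coverage transitions p_value
    alpha: float
    min_cov: int
    p0: float

    def __len__(self) -> int:
        return len(self.sites)


def estimate_error_rate(usites: pd.DataFrame, transcripts: list[Transcript]) -> float:
    """Pooled k/n over U sites outside every annotated transcript span
    (same strand). Raises if no background site carries coverage."""
    usites = validate_usites(usites)
    outside = np.ones(len(usites), dtype=bool)
    pos = usites["pos"].to_numpy()
    for t in transcripts:
        inside = (
            (usites["chrom"].to_numpy() == t.chrom)
            & (usites["strand"].to_numpy() == t.strand)
            & (pos >= t.start) & (pos < t.end)
        )
        outside &= ~inside
    bg = usites.loc[outside]
    n_total = int(bg["coverage"].sum())
    if n_total == 0:
        raise ValueError(
            "no non-transcribed U sites with coverage; supply p0 explicitly"
        )
    p0 = float(bg["transitions"].sum()) / n_total
    log.info("estimated p0=%.3g from %d background sites (%d reads)",
             p0, len(bg), n_total)
    return p0


def binomial_upper_tail(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Exact P(K >= k | n, p0); 1 where k == 0, and for p0 == 0 it is 0
    for k > 0 (any transition contradicts a zero null)."""
    k = np.asarray(k)
    n = np.asarray(n)
    return stats.binom.sf(k - 1, n, p0)


def call_sites(
    usites: pd.DataFrame,
    p0: float,
    alpha: float = 0.005,
    min_cov: int = 2,
    p0_floor: float = 1e-3,
    bh_correct: bool = False,
) -> CrosslinkSiteSet:
    """Keep U sites with exact binomial p-value strictly below ``alpha``
    and coverage >= ``min_cov``.

    ``p0`` is floored at ``p0_floor`` (set 0 to disable) so that a zero
    background estimate cannot declare every transition significant.
    With ``bh_correct`` the cutoff is applied to Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p0 < 0 or p0 >= 1:
        raise ValueError("p0 must be in [0, 1)")
    usites = validate_usites(usites)
    if p0 == 0.0 and p0_floor == 0.0:
        log.warning("p0 = 0: every site with k > 0 gets p-value 0")
    p0_eff = max(p0, p0_floor)
    if p0_eff != p0:
        log.info("p0 floored: %.3g -> %.3g", p0, p0_eff)
    pvals = binomial_upper_tail(usites["transitions"].to_numpy(),
                                usites["coverage"].to_numpy(), p0_eff)
    test_p = pvals
    if bh_correct:
        test_p = _benjamini_hochberg(pvals)
    keep = (test_p < alpha) & (usites["coverage"].to_numpy() >= min_cov) \
        & (usites["transitions"].to_numpy() > 0)
    out = usites.loc[keep].copy()
    out["p_value"] = pvals[keep]
    log.info("called %d / %d sites (alpha=%g, min_cov=%d, p0=%g)",
             len(out), len(usites), alpha, min_cov, p0_eff)
    return CrosslinkSiteSet(sites=out.reset_index(drop=True), alpha=alpha,
                            min_cov=min_cov, p0=p0_eff)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# Enrichment over a background factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentClass:
    factor: str
    fold: float
    label: str  # high (>4), moderate (>2), background

    @property
    def log2_fold(self) -> float:
        return float(np.log2(self.fold))


def _transcript_mean_signal(signal, transcripts: list[Transcript]) -> float:
    """Mean over transcripts of the per-transcript mean signal (defined
    positions only)."""
    from .annotation import to_transcript_coords

    per_t = []
    for t in transcripts:
        v = to_transcript_coords(signal, t)
        if np.any(np.isfinite(v)):
            per_t.append(float(np.nanmean(v)))
    if not per_t:
        raise ValueError("no transcript carries defined signal")
    return float(np.mean(per_t))


def classify_enrichment(
    factor_signal,
    background_signal,
    transcripts: list[Transcript],
    factor_id: str = "factor",
) -> EnrichmentClass:
    """Fold enrichment of transcript-averaged signal over a background
    factor (e.g. an initiation factor), with >4 = high, >2 = moderate."""
    f = _transcript_mean_signal(factor_signal, transcripts)
    b = _transcript_mean_signal(background_signal, transcripts)
    if b == 0:
        raise ValueError("background factor has zero transcript-averaged signal")
    fold = f / b
    label = "high" if fold > 4 else ("moderate" if fold > 2 else "background")
    return EnrichmentClass(factor=factor_id, fold=float(fold), label=label)
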