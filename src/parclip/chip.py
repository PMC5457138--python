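"""ChIP-Seq IP/Input normalization and qPCR percent-input arithmetic.

IP and Input libraries differ in depth and signal-to-noise; a global
ratio of totals over-corrects because enriched regions inflate the IP
total. Signal extraction scaling (SES) instead matches the *background*:
bin both tracks, sort bins by IP signal, and find the rank k* maximizing
the gap between the cumulative Input and IP fractions — bins up to k* are
background-dominated, and the ratio of their IP to Input sums is the
scale applied to Input. Enrichment is then log2((IP+pc)/(scale*Input+pc)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import CoverageTrack


@dataclass(frozen=True)
class SESFactor:
    scale: float
    k_star: int      # argmax rank of the cumulative-difference curve
    bin_len: int
    n_bins: int


@dataclass(frozen=True)
class QPCRSample:
    ct_ip: float
    ct_input_raw: float
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.ct_ip <= 0 or self.ct_input_raw <= 0:
            raise ValueError("Ct values must be > 0")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


def _binned_sums(track: CoverageTrack, starts_by_key, bin_len: int) -> np.ndarray:
    out = []
    for key, starts in starts_by_key:
        arr = track.dense(*key)
        cum = np.concatenate(([0.0], np.cumsum(arr)))
        ends = np.minimum(starts + bin_len, len(arr))
        out.append(cum[ends] - cum[starts])
    return np.concatenate(out)


def ses_factor(
    ip: CoverageTrack,
    input_: CoverageTrack,
    bin_len: int = 100,
    n_bins: int = 100_000,
    seed: int = 0,
) -> SESFactor:
    """Estimate the SES background-matching scale from sampled bins.

    Bin start positions are drawn uniformly (deterministically from
    ``seed``), with replacement when the genome holds fewer than
    ``n_bins`` disjoint bins. Ties in the cumulative-difference curve
    resolve to the lowest rank.
    """
    keys = sorted(set(ip.keys()) & set(input_.keys()))
    if not keys:
        raise ValueError("IP and Input tracks share no (chromosome, strand)")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(ip.dense(*k)) for k in keys], dtype=float)
    total_len = lengths.sum()
    picks = rng.choice(len(keys), size=n_bins, p=lengths / total_len)
    starts_by_key = []
    for i, key in enumerate(keys):
        count = int((picks == i).sum())
        if count == 0:
            continue
        max_start = max(int(lengths[i]) - bin_len, 1)
        starts_by_key.append((key, rng.integers(0, max_start, size=count)))

    ip_sums = _binned_sums(ip, starts_by_key, bin_len)
    in_sums = _binned_sums(input_, starts_by_key, bin_len)
    if ip_sums.sum() == 0 or in_sums.sum() == 0:
        raise ValueError("zero total signal in IP or Input over sampled bins")

    order = np.lexsort((np.arange(len(ip_sums)), in_sums, ip_sums))
    cum_ip = np.cumsum(ip_sums[order])
    cum_in = np.cumsum(in_sums[order])
    diff = cum_in / cum_in[-1] - cum_ip / cum_ip[-1]
    k_star = int(np.argmax(diff))
    if cum_in[k_star] == 0:  # degenerate: background bins carry no input
        nz = np.flatnonzero(cum_in > 0)
        k_star = int(nz[0])
    scale = float(cum_ip[k_star] / cum_in[k_star])
    if scale <= 0:
        raise ValueError("SES scale collapsed to zero; tracks look signal-free")
    return SESFactor(scale=scale, k_star=k_star, bin_len=bin_len, n_bins=n_bins)


def enrichment(
    ip: CoverageTrack,
    input_: CoverageTrack,
    ses: SESFactor,
    pseudocount: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-position log2((IP + pc) / (scale * Input + pc)) signal, keyed
    like a coverage track; feeds metagene anchoring directly."""
    out = {}
    for key in sorted(set(ip.keys()) & set(input_.keys())):
        a = ip.dense(*key)
        b = input_.dense(*key) * ses.scale
        out[key] = np.log2((a + pseudocount) / (b + pseudocount))
    return out


def percent_input(sample: QPCRSample) -> float:
    """ChIP-qPCR percent input.

    The input Ct is first adjusted for the fraction of chromatin used as
    input (dilution to 100%: subtract log2(1/fraction) cycles); percent
    input is then 100 * 2^(adjusted_input - ct_ip).
    """
    adjusted = sample.ct_input_raw - np.log2(1.0 / sample.input_fraction)
    return float(100.0 * 2.0 ** (adjusted - sample.ct_ip))
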