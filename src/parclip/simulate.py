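"""Synthetic annotations, U-site tables, coverage tracks and titrations.

The generator emulates the statistical structure the pipeline assumes:

* transcripts packed on one chromosome with isolation gaps, including
  divergent mRNA/CUT promoter pairs and a fraction of intron-containing
  mRNAs;
* a uniform background T-to-C error rate at every U site, with crosslinked
  sites raised toward a factor-specific crosslink rate following a
  per-class occupancy profile;
* nascent transcription (Pol II) covering all transcribed bases plus a
  post-pA run-through window, with CUTs transcribed at a reduced rate;
* RNA-Seq coverage additionally depleted on unstable RNA: CUT bodies and
  the region downstream of the pA site;
* noisy two-fold titration series from the quadratic (ligand-depletion)
  binding model.

All draws are pure functions of (config, seed): each operation derives its
own stream from ``(seed, operation-name)`` so adding operations never
perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .annotation import GenomeLayout, Transcript, STRANDS
from .binding import TitrationCurve, binding_model
from .tracks import CoverageTrack, validate_usites


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Rates mirror the data the pipeline targets: a ~0.5% background
    T-to-C error rate, mean read depth 30 per transcribed base, five-fold
    RNA-Seq depletion of CUT bodies and post-pA regions, and two-fold lower
    transcription of CUTs relative to mRNAs.
    """

    seed: int = 0
    n_mrna: int = 40
    n_cut: int = 12
    chrom: str = "chrSim"
    chrom_length: int = 300_000
    error_rate: float = 0.005          # background T-to-C probability per read
    crosslink_rate: float = 0.20       # T-to-C probability at fully bound U sites
    depth: float = 30.0                # mean reads per transcribed base
    dispersion: float = 10.0           # negative-binomial size parameter
    cut_rnaseq_factor: float = 0.2     # RNA-Seq depletion on CUT bodies
    postpa_rnaseq_factor: float = 0.2  # RNA-Seq depletion downstream of pA
    cut_transcription_factor: float = 0.5  # nascent abundance of CUTs vs mRNAs
    u_density: float = 0.25            # fraction of transcribed bases that are U sites
    runthrough: int = 200              # nt of post-pA nascent transcription
    mrna_len_range: tuple[int, int] = (800, 5000)
    cut_len_range: tuple[int, int] = (350, 1500)
    min_gap: int = 200                 # placement gap between neighboring units
    frac_bidirectional: float = 0.3    # mRNAs given a divergent CUT partner
    frac_intronic: float = 0.25        # mRNAs given one intron (150-650 nt)
    background_depth: float = 5.0      # read depth at non-transcribed U sites
    background_u_density: float = 0.05
    chip_background: float = 10.0      # mean input coverage per base
    chip_enrichment: float = 4.0       # IP fold enrichment over enriched spans
    chip_span_offset: int = 200        # enrichment starts this far into gene bodies

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < self.crosslink_rate <= 1:
            raise ValueError("need 0 <= error_rate < crosslink_rate <= 1")
        for name in ("cut_rnaseq_factor", "postpa_rnaseq_factor",
                     "cut_transcription_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


class PackingError(RuntimeError):
    """Requested transcripts do not fit on the chromosome."""


# ---------------------------------------------------------------------------
# Occupancy profiles (values in [0, 1] along a transcript)
# ---------------------------------------------------------------------------

def uniform_profile(level: float = 1.0) -> Callable[[int], np.ndarray]:
    return lambda length: np.full(length, level)


def five_prime_decay(decay_nt: float, level: float = 1.0) -> Callable[[int], np.ndarray]:
    """Occupancy peaking at the TSS, decaying exponentially along the body."""
    return lambda length: level * np.exp(-np.arange(length) / decay_nt)


def three_prime_rise(rise_nt: float, level: float = 1.0) -> Callable[[int], np.ndarray]:
    """Occupancy rising toward the pA site."""
    return lambda length: level * np.exp(-(length - 1 - np.arange(length)) / rise_nt)


PROFILE_SHAPES = {
    "uniform": uniform_profile,
    "five_prime_decay": five_prime_decay,
    "three_prime_rise": three_prime_rise,
}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> tuple[GenomeLayout, list[Transcript]]:
    """Pack mRNAs (some with divergent CUTs, some intronic) onto one chromosome.

    Generated mRNAs pass the standard length/isolation filter by
    construction: lengths stay inside ``mrna_len_range`` and neighboring
    units (any strand) are separated by at least ``min_gap`` nt.
    """
    rng = _stream(cfg.seed, "annotation")
    layout = GenomeLayout({cfg.chrom: cfg.chrom_length})
    transcripts: list[Transcript] = []
    cursor = 1000  # keep upstream metagene windows on-chromosome
    n_pairs = int(round(cfg.frac_bidirectional * cfg.n_mrna))
    n_pairs = min(n_pairs, cfg.n_cut)
    extra_cuts = cfg.n_cut - n_pairs

    def advance(span_end: int, pad: int) -> int:
        return span_end + pad + int(rng.integers(0, 300))

    for i in range(cfg.n_mrna):
        paired = i < n_pairs
        m_len = int(rng.integers(cfg.mrna_len_range[0], cfg.mrna_len_range[1] + 1))
        if paired:
            c_len = int(rng.integers(cfg.cut_len_range[0], cfg.cut_len_range[1] + 1))
            tss_dist = int(rng.integers(40, 330))
            cut_start = cursor
            cut = Transcript(id=f"cut{i}", chrom=cfg.chrom, strand="-",
                             tss=cut_start + c_len, pa=cut_start, klass="CUT")
            m_start = cut.tss + tss_dist
            transcripts.append(cut)
        else:
            m_start = cursor
        strand = "+" if paired else ("+", "-")[int(rng.integers(0, 2))]
        if strand == "+":
            tss, pa = m_start, m_start + m_len
        else:
            tss, pa = m_start + m_len, m_start
        introns: tuple[tuple[int, int], ...] = ()
        if m_len >= 1000 and rng.random() < cfg.frac_intronic:
            i_len = int(rng.integers(150, 651))
            lo, hi = m_start + 100, m_start + m_len - i_len - 100
            if hi > lo:
                a = int(rng.integers(lo, hi))
                introns = ((a, a + i_len),)
        transcripts.append(Transcript(id=f"mrna{i}", chrom=cfg.chrom, strand=strand,
                                      tss=tss, pa=pa, klass="mRNA", introns=introns))
        # pairs need a clear 400-nt window downstream of each TSS
        cursor = advance(m_start + m_len, max(cfg.min_gap, 450 if paired else cfg.min_gap))

    for j in range(extra_cuts):
        c_len = int(rng.integers(cfg.cut_len_range[0], cfg.cut_len_range[1] + 1))
        strand = ("+", "-")[int(rng.integers(0, 2))]
        tss, pa = (cursor, cursor + c_len) if strand == "+" else (cursor + c_len, cursor)
        transcripts.append(Transcript(id=f"cutx{j}", chrom=cfg.chrom, strand=strand,
                                      tss=tss, pa=pa, klass="CUT"))
        cursor = advance(cursor + c_len, cfg.min_gap)

    if cursor + cfg.runthrough + 1000 > cfg.chrom_length:
        raise PackingError(
            f"needs ~{cursor + cfg.runthrough + 1000} nt, chromosome is "
            f"{cfg.chrom_length}; raise chrom_length or request fewer transcripts"
        )
    return layout, transcripts


# ---------------------------------------------------------------------------
# U-site tables
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if np.any(pos):
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def _nascent_abundance(cfg: SimConfig, t: Transcript) -> float:
    return cfg.cut_transcription_factor if t.klass == "CUT" else 1.0


def simulate_usite_counts(
    cfg: SimConfig,
    layout: GenomeLayout,
    transcripts: list[Transcript],
    profiles: Mapping[str, Callable[[int], np.ndarray]] | Callable[[int], np.ndarray] | float = 1.0,
    include_background: bool = True,
    stream: str = "usites",
) -> pd.DataFrame:
    """Draw per-U-site coverage and T-to-C transition counts.

    U sites occupy a random ``u_density`` fraction of transcribed bases. At
    each site coverage n is negative-binomial with mean depth x nascent
    abundance, and transitions are Binomial(n, p) with
    ``p = error_rate + occupancy * (crosslink_rate - error_rate)``, the
    occupancy following the per-class profile. Non-transcribed background
    sites (error rate only) are added unless disabled. Sites with zero
    coverage are unobservable and dropped.
    """
    if isinstance(profiles, (int, float)):
        profiles = uniform_profile(float(profiles))
    if callable(profiles):
        profiles = {k: profiles for k in ("mRNA", "CUT", "snoRNA")}
    rng = _stream(cfg.seed, stream)
    rows = []
    transcribed = {
        (chrom, strand): np.zeros(length, dtype=bool)
        for chrom, length in layout.chrom_lengths.items()
        for strand in STRANDS
    }
    for t in transcripts:
        transcribed[(t.chrom, t.strand)][t.start:t.end] = True
        idx = np.flatnonzero(rng.random(t.length) < cfg.u_density)
        if len(idx) == 0:
            continue
        occ = np.clip(profiles.get(t.klass, uniform_profile(0.0))(t.length)[idx], 0.0, 1.0)
        n = _nb_draw(rng, np.full(len(idx), cfg.depth * _nascent_abundance(cfg, t)),
                     cfg.dispersion)
        p = cfg.error_rate + occ * (cfg.crosslink_rate - cfg.error_rate)
        k = rng.binomial(n, p)
        pos = np.asarray(t.position(idx))
        keep = n > 0
        rows.append(pd.DataFrame({
            "chrom": t.chrom, "pos": pos[keep], "strand": t.strand,
            "coverage": n[keep], "transitions": k[keep],
        }))

    if include_background:
        for (chrom, strand), mask in transcribed.items():
            free = np.flatnonzero(~mask)
            sel = free[rng.random(len(free)) < cfg.background_u_density]
            if len(sel) == 0:
                continue
            n = _nb_draw(rng, np.full(len(sel), cfg.background_depth), cfg.dispersion)
            k = rng.binomial(n, cfg.error_rate)
            keep = n > 0
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": sel[keep], "strand": strand,
                "coverage": n[keep], "transitions": k[keep],
            }))

    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "coverage", "transitions"])
    df = pd.concat(rows, ignore_index=True)
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    return validate_usites(df)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

COVERAGE_KINDS = ("rnaseq", "polII", "chip_ip", "chip_input")


def simulate_coverage(
    cfg: SimConfig,
    layout: GenomeLayout,
    transcripts: list[Transcript],
    kind: str,
) -> CoverageTrack:
    """Draw a strand-specific read-coverage track of the requested kind.

    ``polII`` covers every transcribed base (CUTs at the reduced
    transcription rate) plus a full-depth post-pA run-through window.
    ``rnaseq`` is the same nascent signal multiplied by stability:
    ``cut_rnaseq_factor`` on CUT bodies, ``postpa_rnaseq_factor`` on
    run-through regions. ChIP kinds are unstranded: a near-uniform
    background (``chip_input``), with ``chip_ip`` adding enrichment over
    gene bodies starting ``chip_span_offset`` nt after the TSS; both strand
    vectors carry the same values.
    """
    if kind not in COVERAGE_KINDS:
        raise ValueError(f"unknown coverage kind {kind!r}; one of {COVERAGE_KINDS}")
    rng = _stream(cfg.seed, f"coverage:{kind}")
    mean = {
        (chrom, strand): np.zeros(length)
        for chrom, length in layout.chrom_lengths.items()
        for strand in STRANDS
    }

    if kind in ("rnaseq", "polII"):
        for t in transcripts:
            nascent = cfg.depth * _nascent_abundance(cfg, t)
            stability = cfg.cut_rnaseq_factor if (kind == "rnaseq" and t.klass == "CUT") else 1.0
            arr = mean[(t.chrom, t.strand)]
            arr[t.start:t.end] += nascent * stability
            # post-pA run-through (nascent at full rate; unstable in RNA-Seq)
            run = np.asarray(t.position(np.arange(t.length, t.length + cfg.runthrough)))
            run = run[(run >= 0) & (run < len(arr))]
            post = nascent * (cfg.postpa_rnaseq_factor if kind == "rnaseq" else 1.0)
            arr[run] += post
        counts = {key: _nb_draw(rng, m, cfg.dispersion).astype(float)
                  for key, m in mean.items()}
        return CoverageTrack(counts)

    # ChIP kinds: unstranded, duplicated onto both strand vectors
    counts = {}
    for chrom, length in layout.chrom_lengths.items():
        m = np.full(length, cfg.chip_background)
        if kind == "chip_ip":
            for t in transcripts:
                if t.klass != "mRNA":
                    continue
                span = np.asarray(t.position(np.arange(cfg.chip_span_offset, t.length)))
                span = span[(span >= 0) & (span < length)]
                m[span] += cfg.chip_background * (cfg.chip_enrichment - 1.0)
        drawn = _nb_draw(rng, m, cfg.dispersion).astype(float)
        for strand in STRANDS:
            counts[(chrom, strand)] = drawn
    return CoverageTrack(counts)


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

def simulate_titration(
    kd_nM: float,
    bmax: float,
    L_nM: float = 8.0,
    top_nM: float = 5800.0,
    n_dilutions: int = 13,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate: str = "sim",
) -> TitrationCurve:
    """A two-fold serial dilution from ``top_nM`` plus a zero point, with
    Gaussian measurement noise on the quadratic binding model."""
    x = np.concatenate(([0.0], top_nM / 2.0 ** np.arange(n_dilutions)[::-1]))
    y = binding_model(x, L_nM, kd_nM, bmax)
    if noise_sd > 0:
        y = y + _stream(seed, "titration").normal(0.0, noise_sd, size=len(x))
    return TitrationCurve(x=x, y=y, L=L_nM, replicate=replicate)
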